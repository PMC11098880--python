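"""Domain types, vocabularies, validation and JSON serialization for
operating-room semantic scene graphs.

A scene graph describes one time point of a surgery at 1 Hz: typed nodes
(staff, patient, equipment, a virtual ``instrument``) and directed labeled
edges such as ``(head surgeon, Sawing, patient)``.  This module is the
exchange format every other part of the toolkit consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

__all__ = [
    "NONE_RELATION",
    "RelationVocabulary",
    "EntityVocabulary",
    "ClinicalRole",
    "SurgicalPhase",
    "Entity",
    "SceneGraph",
    "SceneSequence",
    "VocabularyError",
    "GraphValidationError",
    "SequenceParseError",
    "validate_graph",
    "has_triplet",
    "graph_to_triplets",
    "graph_from_triplets",
    "sequence_io",
    "read_sequence",
    "write_sequence",
]

#: Reserved background label for the relation classifier.  It is a class the
#: relation head can predict ("no relation between this ordered pair") but is
#: never stored as a graph edge.
NONE_RELATION = "None"

_DEFAULT_RELATIONS = [
    "Assisting",
    "Cementing",
    "Cleaning",
    "CloseTo",
    "Cutting",
    "Drilling",
    "Hammering",
    "Holding",
    "LyingOn",
    "Operating",
    "Preparing",
    "Sawing",
    "Suturing",
    "Touching",
]

_DEFAULT_ENTITIES = [
    "patient",
    "head surgeon",
    "assistant surgeon",
    "circulating nurse",
    "anaesthetist",
    "human",
    "operating table",
    "anesthesia equipment",
    "instrument table",
    "secondary table",
    "instrument",
    "drill",
    "saw",
    "hammer",
]

#: Entity classes that may carry a clinical role.
HUMAN_CLASSES = frozenset(
    {
        "patient",
        "head surgeon",
        "assistant surgeon",
        "circulating nurse",
        "anaesthetist",
        "human",
    }
)

#: Entity classes flagged virtual: no geometry is required for them.
VIRTUAL_CLASSES = frozenset({"instrument"})


class VocabularyError(KeyError):
    """A label is not part of the active vocabulary."""


class GraphValidationError(ValueError):
    """A graph violating its invariants was passed where a valid one is required."""


class SequenceParseError(ValueError):
    """A scene-sequence JSON file could not be parsed."""


@dataclass(frozen=True)
class RelationVocabulary:
    """Ordered relation labels; the reserved background label is always last.

    The classifier scores ``len(self)`` classes (14 semantic relations plus
    the background class), matching the 15-column evaluation protocol.
    """

    names: tuple[str, ...] = tuple(_DEFAULT_RELATIONS) + (NONE_RELATION,)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("relation labels must be unique")
        if not self.names or self.names[-1] != NONE_RELATION:
            raise ValueError(f"{NONE_RELATION!r} must be the last relation label")

    @property
    def semantic(self) -> tuple[str, ...]:
        """All labels that may appear on an edge (background excluded)."""
        return self.names[:-1]

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, label: str) -> bool:
        return label in self.names

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise VocabularyError(f"unknown relation label {label!r}") from None


@dataclass(frozen=True)
class EntityVocabulary:
    """Ordered entity class labels.  Configurable; defaults cover a knee-surgery OR."""

    names: tuple[str, ...] = tuple(_DEFAULT_ENTITIES)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("entity labels must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, label: str) -> bool:
        return label in self.names

    def __iter__(self) -> Iterator[str]:
        return iter(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise VocabularyError(f"unknown entity label {label!r}") from None

    def is_virtual(self, label: str) -> bool:
        return label in VIRTUAL_CLASSES

    def is_human(self, label: str) -> bool:
        return label in HUMAN_CLASSES


class ClinicalRole(str, Enum):
    PATIENT = "patient"
    HEAD_SURGEON = "head surgeon"
    ASSISTANT_SURGEON = "assistant surgeon"
    CIRCULATING_NURSE = "circulating nurse"
    ANAESTHETIST = "anaesthetist"


class SurgicalPhase(str, Enum):
    OR_PREPARATION = "OR Preparation"
    PATIENT_ROLL_IN = "Patient Roll-In"
    PATIENT_PREPARATION = "Patient Preparation"
    SURGERY_1 = "Surgery 1: Implant Placement Preparation"
    SURGERY_2 = "Surgery 2: Implant Placement"
    SURGERY_3 = "Surgery 3: Conclusion"
    PATIENT_ROLL_OUT = "Patient Roll-Out"
    OR_CLEANUP = "OR Cleanup"


#: Canonical workflow order of the eight phases.
PHASE_ORDER: tuple[SurgicalPhase, ...] = tuple(SurgicalPhase)

assert len(list(ClinicalRole)) == 5
assert len(PHASE_ORDER) == 8


@dataclass
class Entity:
    """One graph node: an entity instance observed (or virtual) at a time point.

    ``centroid`` is a 3D position in meters (right-handed, z-up) or ``None``
    for virtual nodes.  ``role`` may only be set on human-class nodes.
    """

    node_id: str
    class_name: str
    centroid: Optional[tuple[float, float, float]] = None
    role: Optional[ClinicalRole] = None

    def __post_init__(self) -> None:
        if self.centroid is not None:
            self.centroid = tuple(float(c) for c in self.centroid)
            if len(self.centroid) != 3:
                raise ValueError("centroid must be a 3-vector")

    def copy(self) -> "Entity":
        return replace(self)


Triplet = tuple[str, str, str]  # (subject_id, relation, object_id)


class SceneGraph:
    """Directed labeled graph over entities for one frame.

    Invariants (checked by :func:`validate_graph`, enforced on mutation):
    edge endpoints exist, no self-loops, at most one relation per ordered
    pair, relation labels are semantic (never the background label).
    """

    def __init__(
        self,
        frame_id: int,
        nodes: Iterable[Entity] = (),
        edges: Iterable[Triplet] = (),
    ) -> None:
        self.frame_id = int(frame_id)
        self.nodes: dict[str, Entity] = {}
        self.edges: set[Triplet] = set()
        for node in nodes:
            self.add_node(node)
        for subj, rel, obj in edges:
            self.add_edge(subj, rel, obj)

    def add_node(self, entity: Entity) -> None:
        if entity.node_id in self.nodes:
            raise GraphValidationError(f"duplicate node id {entity.node_id!r}")
        self.nodes[entity.node_id] = entity

    def add_edge(self, subject_id: str, relation: str, object_id: str) -> None:
        if subject_id not in self.nodes:
            raise GraphValidationError(f"edge subject {subject_id!r} not in graph")
        if object_id not in self.nodes:
            raise GraphValidationError(f"edge object {object_id!r} not in graph")
        if subject_id == object_id:
            raise GraphValidationError(f"self-loop on {subject_id!r}")
        if relation == NONE_RELATION:
            raise GraphValidationError(
                f"reserved label {NONE_RELATION!r} cannot be stored as an edge"
            )
        if self.relation_between(subject_id, object_id) is not None:
            raise GraphValidationError(
                f"ordered pair ({subject_id!r}, {object_id!r}) already has a relation"
            )
        self.edges.add((subject_id, relation, object_id))

    def relation_between(self, subject_id: str, object_id: str) -> Optional[str]:
        for subj, rel, obj in self.edges:
            if subj == subject_id and obj == object_id:
                return rel
        return None

    def class_of(self, node_id: str) -> str:
        return self.nodes[node_id].class_name

    def nodes_of_class(self, class_name: str) -> list[Entity]:
        return [n for n in self.nodes.values() if n.class_name == class_name]

    def human_nodes(self) -> list[Entity]:
        return [n for n in self.nodes.values() if n.class_name in HUMAN_CLASSES]

    def edges_incident(self, node_id: str) -> list[Triplet]:
        return [e for e in self.edges if node_id in (e[0], e[2])]

    def copy(self) -> "SceneGraph":
        return SceneGraph(
            self.frame_id,
            nodes=[n.copy() for n in self.nodes.values()],
            edges=set(self.edges),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SceneGraph):
            return NotImplemented
        return (
            self.frame_id == other.frame_id
            and self.edges == other.edges
            and {k: (v.class_name, v.centroid, v.role) for k, v in self.nodes.items()}
            == {k: (v.class_name, v.centroid, v.role) for k, v in other.nodes.items()}
        )

    def __repr__(self) -> str:
        return (
            f"SceneGraph(frame_id={self.frame_id}, "
            f"|nodes|={len(self.nodes)}, |edges|={len(self.edges)})"
        )


@dataclass
class SceneSequence:
    """A take: scene graphs ordered by strictly increasing frame id."""

    take_id: str
    graphs: list[SceneGraph] = field(default_factory=list)
    fps: float = 1.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        ids = [g.frame_id for g in self.graphs]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame_ids must be strictly increasing")

    def __len__(self) -> int:
        return len(self.graphs)

    def __iter__(self) -> Iterator[SceneGraph]:
        return iter(self.graphs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SceneSequence):
            return NotImplemented
        return (
            self.take_id == other.take_id
            and self.fps == other.fps
            and self.graphs == other.graphs
        )


# ---------------------------------------------------------------------------
# Operations


def validate_graph(
    graph: SceneGraph,
    entities: EntityVocabulary | None = None,
    relations: RelationVocabulary | None = None,
) -> list[str]:
    """Return a list of human-readable invariant violations (empty == valid).

    Violations are returned, never raised, so callers can report all problems
    of a file at once.
    """
    entities = entities or EntityVocabulary()
    relations = relations or RelationVocabulary()
    violations: list[str] = []

    for node_id, node in graph.nodes.items():
        if node.node_id != node_id:
            violations.append(f"node key {node_id!r} != node_id {node.node_id!r}")
        if node.class_name not in entities:
            violations.append(
                f"node {node_id!r} has unknown class {node.class_name!r}"
            )
        if node.role is not None and node.class_name not in HUMAN_CLASSES:
            violations.append(
                f"node {node_id!r} of class {node.class_name!r} carries a role"
            )
        if node.centroid is not None and not np.all(np.isfinite(node.centroid)):
            violations.append(f"node {node_id!r} has non-finite centroid")

    seen_pairs: set[tuple[str, str]] = set()
    for subj, rel, obj in sorted(graph.edges):
        if subj not in graph.nodes:
            violations.append(f"edge ({subj!r}, {rel!r}, {obj!r}): subject {subj!r} absent")
        if obj not in graph.nodes:
            violations.append(f"edge ({subj!r}, {rel!r}, {obj!r}): object {obj!r} absent")
        if subj == obj:
            violations.append(f"edge ({subj!r}, {rel!r}, {obj!r}): self-loop")
        if rel == NONE_RELATION:
            violations.append(
                f"edge ({subj!r}, {rel!r}, {obj!r}): reserved label {NONE_RELATION!r}"
            )
        elif rel not in relations:
            violations.append(f"edge ({subj!r}, {rel!r}, {obj!r}): unknown relation")
        if (subj, obj) in seen_pairs:
            violations.append(
                f"ordered pair ({subj!r}, {obj!r}) has more than one relation"
            )
        seen_pairs.add((subj, obj))

    return violations


def has_triplet(
    graph: SceneGraph,
    subject_class: str,
    relation: str,
    object_class: str,
    entities: EntityVocabulary | None = None,
    relations: RelationVocabulary | None = None,
) -> bool:
    """Class-level triplet query, e.g. ``(head surgeon, Sawing, patient)``.

    Matches on entity classes, not node ids; edges are directed.
    """
    entities = entities or EntityVocabulary()
    relations = relations or RelationVocabulary()
    if subject_class not in entities:
        raise VocabularyError(f"unknown entity label {subject_class!r}")
    if object_class not in entities:
        raise VocabularyError(f"unknown entity label {object_class!r}")
    if relation not in relations:
        raise VocabularyError(f"unknown relation label {relation!r}")
    for subj, rel, obj in graph.edges:
        if (
            rel == relation
            and graph.nodes[subj].class_name == subject_class
            and graph.nodes[obj].class_name == object_class
        ):
            return True
    return False


def graph_to_triplets(graph: SceneGraph) -> list[tuple[str, str, str, str, str]]:
    """Flatten a valid graph to ``(subject_id, subject_class, relation,
    object_id, object_class)`` rows, sorted for reproducibility."""
    violations = validate_graph(graph)
    if violations:
        raise GraphValidationError("; ".join(violations))
    return sorted(
        (subj, graph.nodes[subj].class_name, rel, obj, graph.nodes[obj].class_name)
        for subj, rel, obj in graph.edges
    )


def graph_from_triplets(
    frame_id: int, rows: Sequence[tuple[str, str, str, str, str]]
) -> SceneGraph:
    """Inverse of :func:`graph_to_triplets` (nodes recovered from endpoint columns)."""
    graph = SceneGraph(frame_id)
    for subj_id, subj_cls, _rel, obj_id, obj_cls in rows:
        for node_id, cls in ((subj_id, subj_cls), (obj_id, obj_cls)):
            if node_id not in graph.nodes:
                graph.add_node(Entity(node_id, cls))
            elif graph.nodes[node_id].class_name != cls:
                raise GraphValidationError(
                    f"node {node_id!r} listed with conflicting classes"
                )
    for subj_id, _sc, rel, obj_id, _oc in rows:
        graph.add_edge(subj_id, rel, obj_id)
    return graph


# ---------------------------------------------------------------------------
# Serialization

_SCHEMA_KEYS = {"take_id", "fps", "frames"}


def _graph_to_dict(graph: SceneGraph) -> dict:
    return {
        "frame_id": graph.frame_id,
        "nodes": [
            {
                "id": n.node_id,
                "class": n.class_name,
                "centroid": list(n.centroid) if n.centroid is not None else None,
                "role": n.role.value if n.role is not None else None,
            }
            for n in sorted(graph.nodes.values(), key=lambda n: n.node_id)
        ],
        "edges": [list(e) for e in sorted(graph.edges)],
    }


def _graph_from_dict(
    payload: dict,
    index: int,
    entities: EntityVocabulary,
    relations: RelationVocabulary,
) -> SceneGraph:
    try:
        graph = SceneGraph(int(payload["frame_id"]))
        for node in payload.get("nodes", []):
            cls = node["class"]
            if cls not in entities:
                raise VocabularyError(f"unknown entity label {cls!r}")
            role = node.get("role")
            graph.add_node(
                Entity(
                    node_id=str(node["id"]),
                    class_name=cls,
                    centroid=tuple(node["centroid"]) if node.get("centroid") else None,
                    role=ClinicalRole(role) if role else None,
                )
            )
        for subj, rel, obj in payload.get("edges", []):
            if rel not in relations or rel == NONE_RELATION:
                raise VocabularyError(f"unknown relation label {rel!r}")
            graph.add_edge(subj, rel, obj)
    except VocabularyError:
        raise
    except (KeyError, TypeError, ValueError, GraphValidationError) as exc:
        raise SequenceParseError(f"frame index {index}: {exc}") from exc
    return graph


def write_sequence(path, sequence: SceneSequence) -> None:
    """Write a sequence as UTF-8 JSON (schema: take_id, fps, frames[])."""
    for i, graph in enumerate(sequence.graphs):
        violations = validate_graph(graph)
        if violations:
            raise GraphValidationError(f"frame index {i}: {violations[0]}")
    payload = {
        "take_id": sequence.take_id,
        "fps": sequence.fps,
        "frames": [_graph_to_dict(g) for g in sequence.graphs],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_sequence(
    path,
    entities: EntityVocabulary | None = None,
    relations: RelationVocabulary | None = None,
) -> SceneSequence:
    entities = entities or EntityVocabulary()
    relations = relations or RelationVocabulary()
    with open(path, "r", encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SequenceParseError(str(exc)) from exc
    if not isinstance(payload, dict) or not _SCHEMA_KEYS <= set(payload):
        raise SequenceParseError(
            f"expected keys {sorted(_SCHEMA_KEYS)}, got {sorted(payload) if isinstance(payload, dict) else type(payload)}"
        )
    graphs = [
        _graph_from_dict(frame, i, entities, relations)
        for i, frame in enumerate(payload["frames"])
    ]
    seen: set[int] = set()
    for i, g in enumerate(graphs):
        if g.frame_id in seen:
            raise SequenceParseError(f"frame index {i}: duplicate frame_id {g.frame_id}")
        seen.add(g.frame_id)
    try:
        return SceneSequence(
            take_id=str(payload["take_id"]),
            graphs=graphs,
            fps=float(payload["fps"]),
        )
    except ValueError as exc:
        raise SequenceParseError(str(exc)) from exc


def sequence_io(path, mode: str, sequence: SceneSequence | None = None) -> SceneSequence | None:
    """Single entry point for sequence file I/O (``mode`` = 'read' | 'write')."""
    if mode == "read":
        return read_sequence(path)
    if mode == "write":
        if sequence is None:
            raise ValueError("write mode requires a sequence")
        write_sequence(path, sequence)
        return None
    raise ValueError(f"mode must be 'read' or 'write', got {mode!r}")
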