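"""Person tracking and clinical-role assignment.

Tracks are built by per-frame-pair Hungarian matching on mean joint
distance.  Each track is scored against the five clinical roles either by a
relation-frequency heuristic or by a learned target-marked graph encoder,
and unique roles are then assigned with a greedy bijective procedure:
repeatedly take the globally most probable (track, role) cell, remove that
role everywhere else and renormalize the remaining rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ClinicalRole, RelationVocabulary, SceneGraph, SceneSequence
from .instances import HumanPose
from .nn import MLP, Adam, Module, Tensor, concat, softmax_cross_entropy

__all__ = [
    "Track",
    "RoleScoreMatrix",
    "ROLES",
    "build_tracks",
    "tracks_from_sequence",
    "select_graphs",
    "heuristic_role_scores",
    "RoleModel",
    "train_role_model",
    "learned_role_scores",
    "assign_roles",
]

ROLES: tuple[ClinicalRole, ...] = tuple(ClinicalRole)

TOOL_USE_RELATIONS = (
    "Sawing",
    "Drilling",
    "Hammering",
    "Cutting",
    "Suturing",
    "Cementing",
    "Operating",
)

#: Heuristic scoring table: role -> ((direction, relation, object_class|None), weight).
#: direction 'subject' counts edges where the track's node is the subject;
#: an object_class restricts the match to edges whose other endpoint has
#: that (predicted) class.
DEFAULT_ROLE_WEIGHTS: dict[ClinicalRole, tuple[tuple[str, str, Optional[str], float], ...]] = {
    ClinicalRole.HEAD_SURGEON: tuple(
        ("subject", rel, None, 3.0) for rel in TOOL_USE_RELATIONS
    ),
    ClinicalRole.PATIENT: (("subject", "LyingOn", None, 3.0),)
    + tuple(("object", rel, None, 1.0) for rel in TOOL_USE_RELATIONS),
    ClinicalRole.ASSISTANT_SURGEON: (
        ("subject", "Assisting", None, 3.0),
        ("subject", "Holding", None, 0.5),
        ("subject", "Preparing", None, 1.0),
    ),
    ClinicalRole.CIRCULATING_NURSE: (
        ("subject", "Cleaning", None, 3.0),
        ("subject", "Touching", "instrument table", 1.0),
        ("subject", "CloseTo", "instrument table", 1.0),
    ),
    ClinicalRole.ANAESTHETIST: (
        ("subject", "Touching", "anesthesia equipment", 3.0),
        ("subject", "CloseTo", "anesthesia equipment", 1.0),
    ),
}


@dataclass
class Track:
    """One person followed across frames; the unit of role prediction."""

    track_id: int
    frames: dict[int, str]  # frame_id -> human node id
    K: int = 0
    selected_graphs: list[SceneGraph] = field(default_factory=list)
    target_nodes: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RoleScoreMatrix:
    """tracks x 5 roles; rows are nonnegative and sum to one."""

    track_ids: list[int]
    scores: np.ndarray  # (T, 5)
    roles: tuple[ClinicalRole, ...] = ROLES

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.track_ids), len(self.roles)):
            raise ValueError("score matrix shape mismatch")
        if np.any(self.scores < 0):
            raise ValueError("scores must be nonnegative")
        sums = self.scores.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")


# ---------------------------------------------------------------------------
# Tracking


def _pose_cost(a: HumanPose, b: HumanPose) -> float:
    return float(np.linalg.norm(a.joints - b.joints, axis=1).mean())


def build_tracks(
    poses_by_frame: Sequence[tuple[int, Sequence[HumanPose]]],
    gate: float = 0.8,
) -> list[Track]:
    """Hungarian matching between adjacent frames; matches above ``gate``
    (mean 14-joint distance, meters) are rejected, ending/birthing tracks.

    ``poses_by_frame`` is an ordered list of (frame_id, detections).  Output
    tracks partition all detections.
    """
    tracks: list[Track] = []
    active: list[tuple[Track, HumanPose]] = []
    for frame_id, detections in poses_by_frame:
        detections = list(detections)
        assigned = [False] * len(detections)
        next_active: list[tuple[Track, HumanPose]] = []
        if active and detections:
            cost = np.array(
                [[_pose_cost(last, det) for det in detections] for _, last in active]
            )
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] > gate:
                    continue
                track, _ = active[r]
                track.frames[frame_id] = detections[c].person_id
                next_active.append((track, detections[c]))
                assigned[c] = True
        for det, done in zip(detections, assigned):
            if not done:
                track = Track(track_id=len(tracks), frames={frame_id: det.person_id})
                tracks.append(track)
                next_active.append((track, det))
        active = next_active
    return tracks


def tracks_from_sequence(sequence: SceneSequence) -> list[Track]:
    """Identity-based tracks (one per human node id) when poses are absent."""
    frames_by_id: dict[str, dict[int, str]] = {}
    for graph in sequence:
        for node in graph.human_nodes():
            frames_by_id.setdefault(node.node_id, {})[graph.frame_id] = node.node_id
    return [
        Track(track_id=i, frames=frames)
        for i, (_nid, frames) in enumerate(sorted(frames_by_id.items()))
    ]


def select_graphs(
    track: Track, sequence: SceneSequence, max_graphs: int = 32
) -> Track:
    """Attach up to ``max_graphs`` scene graphs (uniformly spread along the
    track) and their target nodes to the track, in place."""
    by_id = {g.frame_id: g for g in sequence}
    frame_ids = sorted(fid for fid in track.frames if fid in by_id)
    if not frame_ids:
        track.K = 0
        track.selected_graphs = []
        track.target_nodes = []
        return track
    k = min(len(frame_ids), max_graphs)
    chosen = [frame_ids[int(round(i * (len(frame_ids) - 1) / max(k - 1, 1)))] for i in range(k)]
    chosen = sorted(dict.fromkeys(chosen))
    track.K = len(chosen)
    track.selected_graphs = [by_id[fid] for fid in chosen]
    track.target_nodes = [track.frames[fid] for fid in chosen]
    return track


# ---------------------------------------------------------------------------
# Role likelihoods


def heuristic_role_scores(
    track: Track,
    weights: Mapping[ClinicalRole, tuple] | None = None,
    epsilon: float = 1.0,
) -> np.ndarray:
    """Relation-frequency role likelihoods for one track (row sums to 1).

    Every edge incident to the track's target node in each selected graph
    adds the table weight to the matching roles; Laplace smoothing keeps the
    row well-defined for edgeless tracks.
    """
    if not track.selected_graphs:
        raise ValueError("track has no selected graphs; call select_graphs first")
    weights = weights or DEFAULT_ROLE_WEIGHTS
    row = np.zeros(len(ROLES))
    for graph, node_id in zip(track.selected_graphs, track.target_nodes):
        for subj, rel, obj in graph.edges_incident(node_id):
            for ri, role in enumerate(ROLES):
                for direction, relation, obj_class, weight in weights.get(role, ()):
                    if relation != rel:
                        continue
                    if direction == "subject" and subj == node_id:
                        other = obj
                    elif direction == "object" and obj == node_id:
                        other = subj
                    else:
                        continue
                    if obj_class is not None and graph.nodes[other].class_name != obj_class:
                        continue
                    row[ri] += weight
    row = row + epsilon
    return row / row.sum()


class RoleModel(Module):
    """Target-marked graph encoder scoring the five roles for a track.

    Node inputs are a class one-hot plus a binary target flag; two rounds of
    edge-conditioned message passing contextualize them; the target node's
    embeddings are averaged over the track's selected graphs and mapped to
    role logits by a linear head.
    """

    def __init__(
        self,
        entity_classes: Sequence[str],
        relations: RelationVocabulary | None = None,
        dim: int = 32,
        rounds: int = 2,
        seed: int = 0,
    ):
        relations = relations or RelationVocabulary()
        self.entity_classes = list(entity_classes)
        self.relations = relations
        self.dim = dim
        self.rounds = rounds
        rng = np.random.default_rng(seed)
        n_rel = len(relations.semantic)
        self.embed = MLP([len(self.entity_classes) + 1, dim], rng)
        self.message = [MLP([dim + n_rel + 1, dim], rng) for _ in range(rounds)]
        self.update = [MLP([2 * dim, dim], rng) for _ in range(rounds)]
        self.head = MLP([dim, len(ROLES)], rng)
        self.trained = False

    def _encode_target(self, graph: SceneGraph, target: str) -> Tensor:
        ids = sorted(graph.nodes)
        index = {nid: i for i, nid in enumerate(ids)}
        n = len(ids)
        n_rel = len(self.relations.semantic)
        x = np.zeros((n, len(self.entity_classes) + 1))
        for nid, i in index.items():
            cls = graph.nodes[nid].class_name
            if cls in self.entity_classes:
                x[i, self.entity_classes.index(cls)] = 1.0
        x[index[target], -1] = 1.0
        h = self.embed(Tensor(x)).relu()

        edges = sorted(graph.edges)
        if edges:
            other_sel = np.zeros((2 * len(edges), n))
            rel_feat = np.zeros((2 * len(edges), n_rel + 1))
            incidence = np.zeros((n, 2 * len(edges)))
            for k, (subj, rel, obj) in enumerate(edges):
                r = self.relations.index(rel)
                # message to the object from the subject (incoming)
                other_sel[2 * k, index[subj]] = 1.0
                rel_feat[2 * k, r] = 1.0
                rel_feat[2 * k, -1] = 1.0
                incidence[index[obj], 2 * k] = 1.0
                # message to the subject from the object (outgoing)
                other_sel[2 * k + 1, index[obj]] = 1.0
                rel_feat[2 * k + 1, r] = 1.0
                incidence[index[subj], 2 * k + 1] = 1.0
            incidence /= np.maximum(incidence.sum(axis=1, keepdims=True), 1.0)
            t_other, t_rel, t_inc = Tensor(other_sel), Tensor(rel_feat), Tensor(incidence)
            for msg, upd in zip(self.message, self.update):
                m = msg(concat([t_other @ h, t_rel], axis=1)).relu()
                h = upd(concat([h, t_inc @ m], axis=1)).relu()
        else:
            zeros = Tensor(np.zeros((n, self.dim)))
            for upd in self.update:
                h = upd(concat([h, zeros], axis=1)).relu()
        target_sel = np.zeros((1, n))
        target_sel[0, index[target]] = 1.0
        return Tensor(target_sel) @ h

    def track_logits(self, track: Track) -> Tensor:
        if track.K == 0:
            raise ValueError("track has no selected graphs")
        embeddings = [
            self._encode_target(g, t)
            for g, t in zip(track.selected_graphs, track.target_nodes)
        ]
        mean = concat(embeddings, axis=0).mean(axis=0).reshape(1, self.dim)
        return self.head(mean)


def train_role_model(
    labeled_tracks: Sequence[tuple[Track, ClinicalRole]],
    entity_classes: Sequence[str],
    epochs: int = 30,
    lr: float = 1e-2,
    seed: int = 0,
) -> tuple[RoleModel, list[float]]:
    """Cross-entropy training of the learned role scorer."""
    if not labeled_tracks:
        raise ValueError("no training tracks")
    model = RoleModel(entity_classes, seed=seed)
    opt = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    order = np.arange(len(labeled_tracks))
    history = []
    for _ in range(epochs):
        rng.shuffle(order)
        losses = []
        for i in order:
            track, role = labeled_tracks[i]
            logits = model.track_logits(track)
            loss = softmax_cross_entropy(logits, np.array([ROLES.index(role)]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    model.trained = True
    return model, history


def learned_role_scores(track: Track, model: RoleModel) -> np.ndarray:
    """Softmax role likelihood row from the trained graph encoder."""
    if not getattr(model, "trained", False):
        raise ValueError("role model is untrained")
    logits = model.track_logits(track).data[0]
    z = logits - logits.max()
    p = np.exp(z)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Unique-role assignment


def assign_roles(
    matrix: RoleScoreMatrix, method: str = "greedy"
) -> dict[int, ClinicalRole]:
    """Bijective (up to role count) track -> role assignment.

    Greedy (default): repeatedly pick the global maximum over unassigned
    (track, role) cells, assign it, delete the role for everyone else and
    renormalize the remaining rows.  Ties break on lower track index, then
    role order.  ``method='hungarian'`` solves the global optimum instead.
    """
    scores = matrix.scores.copy()
    n_tracks, n_roles = scores.shape
    if method == "hungarian":
        rows, cols = linear_sum_assignment(-scores)
        return {matrix.track_ids[r]: matrix.roles[c] for r, c in zip(rows, cols)}
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    assignment: dict[int, ClinicalRole] = {}
    open_tracks = list(range(n_tracks))
    open_roles = list(range(n_roles))
    while open_tracks and open_roles:
        best_value = -1.0
        best_cell: tuple[int, int] | None = None
        for t in open_tracks:
            for r in open_roles:
                if scores[t, r] > best_value + 1e-15:
                    best_value = scores[t, r]
                    best_cell = (t, r)
        if best_value <= 0.0:
            warnings.warn("all-zero scores among remaining tracks; tie-break assignment")
            best_cell = (open_tracks[0], open_roles[0])
        t, r = best_cell
        assignment[matrix.track_ids[t]] = matrix.roles[r]
        open_tracks.remove(t)
        open_roles.remove(r)
        for other in open_tracks:
            remaining = scores[other, open_roles].sum()
            if remaining > 0:
                scores[other, open_roles] /= remaining
            scores[other, r] = 0.0
    return assignment


def score_tracks(
    tracks: Sequence[Track],
    method: str = "heuristic",
    model: RoleModel | None = None,
) -> RoleScoreMatrix:
    rows = []
    for track in tracks:
        if method == "heuristic":
            rows.append(heuristic_role_scores(track))
        elif method == "learned":
            if model is None:
                raise ValueError("learned scoring needs a model")
            rows.append(learned_role_scores(track, model))
        else:
            raise ValueError(f"unknown scoring method {method!r}")
    return RoleScoreMatrix(
        track_ids=[t.track_id for t in tracks], scores=np.array(rows)
    )
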