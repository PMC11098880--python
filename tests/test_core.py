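import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orssg.core import (
    ClinicalRole,
    Entity,
    EntityVocabulary,
    GraphValidationError,
    NONE_RELATION,
    RelationVocabulary,
    SceneGraph,
    SceneSequence,
    SequenceParseError,
    SurgicalPhase,
    VocabularyError,
    graph_from_triplets,
    graph_to_triplets,
    has_triplet,
    read_sequence,
    sequence_io,
    validate_graph,
    write_sequence,
)


class TestVocabularies:
    def test_relation_vocab_has_15_classes_with_none_last(self):
        vocab = RelationVocabulary()
        assert len(vocab) == 15
        assert vocab.names[-1] == NONE_RELATION
        assert len(vocab.semantic) == 14
        assert len(set(vocab.names)) == 15

    def test_none_must_be_last(self):
        with pytest.raises(ValueError):
            RelationVocabulary(names=(NONE_RELATION, "Sawing"))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError):
            EntityVocabulary(names=("drill", "drill"))

    def test_unknown_label_raises_vocabulary_error(self):
        with pytest.raises(VocabularyError):
            RelationVocabulary().index("Welding")

    def test_entity_vocab_flags(self):
        vocab = EntityVocabulary()
        assert vocab.is_virtual("instrument")
        assert not vocab.is_virtual("drill")
        assert vocab.is_human("head surgeon")
        assert vocab.is_human("human")
        assert not vocab.is_human("saw")

    def test_enumerations(self):
        assert len(list(ClinicalRole)) == 5
        assert len(list(SurgicalPhase)) == 8


class TestGraphInvariants:
    def test_well_formed_graph_validates(self, small_graph):
        assert validate_graph(small_graph) == []

    def test_edge_to_absent_node_reported(self, small_graph):
        small_graph.edges.add(("hs1", "Touching", "x9"))
        violations = validate_graph(small_graph)
        assert len(violations) == 1
        assert "x9" in violations[0]

    def test_none_edge_reported(self, small_graph):
        small_graph.edges.add(("hs1", NONE_RELATION, "table"))
        assert any(NONE_RELATION in v for v in validate_graph(small_graph))

    def test_add_edge_enforces_invariants(self, small_graph):
        with pytest.raises(GraphValidationError):
            small_graph.add_edge("hs1", "Sawing", "hs1")  # self-loop
        with pytest.raises(GraphValidationError):
            small_graph.add_edge("hs1", NONE_RELATION, "table")
        with pytest.raises(GraphValidationError):
            small_graph.add_edge("hs1", "Cutting", "p1")  # pair already taken

    def test_role_on_non_human_reported(self, small_graph):
        small_graph.nodes["table"].role = ClinicalRole.PATIENT
        assert any("role" in v for v in validate_graph(small_graph))


class TestHasTriplet:
    def test_directed_class_level_query(self, small_graph):
        assert has_triplet(small_graph, "head surgeon", "Sawing", "patient")
        assert not has_triplet(small_graph, "patient", "Sawing", "head surgeon")

    def test_empty_graph(self):
        assert not has_triplet(SceneGraph(0), "head surgeon", "Sawing", "patient")

    def test_unknown_label_errors(self, small_graph):
        with pytest.raises(VocabularyError):
            has_triplet(small_graph, "janitor", "Sawing", "patient")
        with pytest.raises(VocabularyError):
            has_triplet(small_graph, "patient", "Welding", "patient")

    def test_monotone_under_edge_addition(self, small_graph):
        queries = [
            ("head surgeon", "Sawing", "patient"),
            ("patient", "LyingOn", "operating table"),
        ]
        before = [has_triplet(small_graph, *q) for q in queries]
        small_graph.add_edge("hs1", "CloseTo", "table")
        after = [has_triplet(small_graph, *q) for q in queries]
        assert all(a >= b for a, b in zip(after, before))


class TestTriplets:
    def test_lengths(self, small_graph):
        assert len(graph_to_triplets(small_graph)) == 2
        assert graph_to_triplets(SceneGraph(3)) == []

    def test_round_trip(self, small_graph):
        rows = graph_to_triplets(small_graph)
        rebuilt = graph_from_triplets(small_graph.frame_id, rows)
        assert sorted(graph_to_triplets(rebuilt)) == sorted(rows)
        assert rebuilt.edges == small_graph.edges

    def test_invalid_graph_rejected(self, small_graph):
        small_graph.edges.add(("hs1", "Touching", "ghost"))
        with pytest.raises(GraphValidationError):
            graph_to_triplets(small_graph)


class TestSequenceIO:
    def test_round_trip(self, small_sequence, tmp_path):
        path = tmp_path / "seq.json"
        write_sequence(path, small_sequence)
        back = read_sequence(path)
        assert back == small_sequence

    def test_sequence_io_dispatch(self, small_sequence, tmp_path):
        path = tmp_path / "seq.json"
        assert sequence_io(path, "write", small_sequence) is None
        assert sequence_io(path, "read") == small_sequence
        with pytest.raises(ValueError):
            sequence_io(path, "append")

    def test_duplicate_frame_id_rejected(self, small_sequence, tmp_path):
        path = tmp_path / "seq.json"
        write_sequence(path, small_sequence)
        payload = json.loads(path.read_text())
        payload["frames"][1]["frame_id"] = payload["frames"][0]["frame_id"]
        path.write_text(json.dumps(payload))
        with pytest.raises(SequenceParseError, match="frame index"):
            read_sequence(path)

    def test_empty_frames(self, tmp_path):
        path = tmp_path / "seq.json"
        path.write_text(json.dumps({"take_id": "t", "fps": 1.0, "frames": []}))
        assert len(read_sequence(path)) == 0

    def test_unknown_label_raises_vocabulary_error(self, tmp_path):
        path = tmp_path / "seq.json"
        payload = {
            "take_id": "t",
            "fps": 1.0,
            "frames": [
                {
                    "frame_id": 0,
                    "nodes": [{"id": "a", "class": "hoverboard", "centroid": None, "role": None}],
                    "edges": [],
                }
            ],
        }
        path.write_text(json.dumps(payload))
        with pytest.raises(VocabularyError):
            read_sequence(path)

    def test_malformed_json_names_frame(self, tmp_path):
        path = tmp_path / "seq.json"
        payload = {
            "take_id": "t",
            "fps": 1.0,
            "frames": [
                {"frame_id": 0, "nodes": [], "edges": []},
                {"nodes": [], "edges": []},  # missing frame_id
            ],
        }
        path.write_text(json.dumps(payload))
        with pytest.raises(SequenceParseError, match="frame index 1"):
            read_sequence(path)

    def test_roles_survive_round_trip(self, small_graph, tmp_path):
        small_graph.nodes["p1"].role = ClinicalRole.PATIENT
        seq = SceneSequence("t", [small_graph])
        path = tmp_path / "seq.json"
        write_sequence(path, seq)
        back = read_sequence(path)
        assert back.graphs[0].nodes["p1"].role == ClinicalRole.PATIENT


@settings(max_examples=25, deadline=None)
@given(
    n_frames=st.integers(0, 4),
    fps=st.floats(0.5, 30, allow_nan=False),
    data=st.data(),
)
def test_sequence_round_trip_property(tmp_path_factory, n_frames, fps, data):
    vocab = RelationVocabulary()
    graphs = []
    for i in range(n_frames):
        g = SceneGraph(i)
        node_ids = [f"n{k}" for k in range(data.draw(st.integers(1, 4)))]
        for nid in node_ids:
            cls = data.draw(st.sampled_from(list(EntityVocabulary().names)))
            g.add_node(Entity(nid, cls))
        for a in node_ids:
            for b in node_ids:
                if a != b and data.draw(st.booleans()):
                    rel = data.draw(st.sampled_from(list(vocab.semantic)))
                    g.add_edge(a, rel, b)
        graphs.append(g)
    seq = SceneSequence("take", graphs, fps=fps)
    path = tmp_path_factory.mktemp("io") / "seq.json"
    write_sequence(path, seq)
    assert read_sequence(path) == seq
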