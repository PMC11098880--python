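import numpy as np
import pytest

from orssg.core import ClinicalRole, PHASE_ORDER, SceneSequence, SurgicalPhase, validate_graph
from orssg.phases import recognize_phases
from orssg.synthetic import (
    NoiseConfig,
    SimConfig,
    attach_roles,
    default_layout,
    inject_noise,
    relations_from_geometry,
    simulate_timeline,
    write_take,
)


class TestConfig:
    def test_rates_validated(self):
        with pytest.raises(ValueError):
            NoiseConfig(relation_dropout_rate=1.5)
        with pytest.raises(ValueError):
            SimConfig(take_length_s=-1)
        with pytest.raises(ValueError):
            SimConfig(phase_duration_weights=(0.0,) * 8)
        with pytest.raises(ValueError):
            SimConfig(phase_duration_weights=(1.0, 1.0))

    def test_layout_instruments_share_shape(self):
        layout = default_layout()
        # static objects must not overlap: pairwise center distance exceeds
        # half-extent sums in at least one axis
        names = list(layout.placements)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                ca, sa, _ = layout.placements[a]
                cb, sb, _ = layout.placements[b]
                gap = [
                    abs(ca[k] - cb[k]) > (sa[k] + sb[k]) / 2 for k in range(3)
                ]
                assert any(gap), f"{a} overlaps {b}"


class TestTimeline:
    def test_default_length_and_order(self):
        bundles = simulate_timeline(SimConfig(seed=0, render=False))
        assert len(bundles) == 660
        seen = [b.gt_phase for b in bundles]
        # phases appear in canonical order, each exactly once as a block
        blocks = [seen[0]]
        for p in seen[1:]:
            if p != blocks[-1]:
                blocks.append(p)
        assert blocks == list(PHASE_ORDER)

    def test_durations_proportional_to_weights(self):
        weights = (0.5, 0.1, 0.05, 0.05, 0.05, 0.05, 0.1, 0.1)
        bundles = simulate_timeline(
            SimConfig(seed=0, take_length_s=200, phase_duration_weights=weights, render=False)
        )
        n_prep = sum(b.gt_phase == SurgicalPhase.OR_PREPARATION for b in bundles)
        assert n_prep == pytest.approx(100, abs=2)

    def test_seed_determinism(self):
        a = simulate_timeline(SimConfig(seed=9, take_length_s=30, render=True, points_per_entity=80))
        b = simulate_timeline(SimConfig(seed=9, take_length_s=30, render=True, points_per_entity=80))
        for x, y in zip(a, b):
            assert x.gt_graph == y.gt_graph
            assert x.gt_phase == y.gt_phase
            np.testing.assert_array_equal(x.cloud.points, y.cloud.points)
            np.testing.assert_array_equal(x.images, y.images)

    def test_concentrated_weights_mostly_patient_free(self):
        weights = (0.93,) + (0.01,) * 7
        bundles = simulate_timeline(
            SimConfig(seed=0, take_length_s=200, phase_duration_weights=weights, render=False)
        )
        frac_no_patient = np.mean(
            [all(b.gt_roles.get(nid) != ClinicalRole.PATIENT for nid in b.gt_graph.nodes)
             for b in bundles]
        )
        assert frac_no_patient >= 0.9

    def test_gt_graphs_valid_and_roles_constant(self, graph_take):
        roles = graph_take[0].gt_roles
        for b in graph_take:
            assert validate_graph(b.gt_graph) == []
            assert b.gt_roles == roles

    def test_phase_defining_triplets_present(self, graph_take):
        from orssg.core import has_triplet

        for b in graph_take:
            g = attach_roles(b.gt_graph, b.gt_roles)
            by_role = {
                r: nid for nid, r in b.gt_roles.items() if nid in g.nodes
            }
            if b.gt_phase == SurgicalPhase.SURGERY_2:
                assert g.relation_between(
                    by_role[ClinicalRole.HEAD_SURGEON], by_role[ClinicalRole.PATIENT]
                ) == "Hammering"
            if b.gt_phase == SurgicalPhase.SURGERY_3:
                assert g.relation_between(
                    by_role[ClinicalRole.HEAD_SURGEON], by_role[ClinicalRole.PATIENT]
                ) == "Cementing"
            if b.gt_phase == SurgicalPhase.OR_PREPARATION:
                assert ClinicalRole.PATIENT not in {
                    b.gt_roles.get(nid) for nid in g.nodes
                }

    def test_all_relations_covered(self, graph_take):
        from orssg.core import RelationVocabulary

        seen = {rel for b in graph_take for _, rel, _ in b.gt_graph.edges}
        assert seen == set(RelationVocabulary().semantic)

    def test_phase_self_consistency(self, graph_take):
        seq = SceneSequence("t", [attach_roles(b.gt_graph, b.gt_roles) for b in graph_take])
        predicted = recognize_phases(seq)
        assert all(p == b.gt_phase for p, b in zip(predicted, graph_take))


class TestGeometricRelations:
    def test_lying_on_predicate(self):
        table = default_layout().box("operating table")
        edges = relations_from_geometry(
            centroids={"h": np.array([0.2, 0.0, 1.0]), "operating table": table.center},
            torso_by_human={"h": np.array([0.2, 0.0, 1.05])},
            tables=[table],
            scripted=[],
        )
        assert ("h", "LyingOn", "operating table") in edges

    def test_no_close_to_beyond_threshold(self):
        edges = relations_from_geometry(
            centroids={"a": np.zeros(3), "b": np.array([3.0, 0, 0])},
            torso_by_human={},
            tables=[],
            scripted=[],
        )
        assert not edges

    def test_close_to_both_directions(self):
        edges = relations_from_geometry(
            centroids={"a": np.zeros(3), "b": np.array([1.0, 0, 0])},
            torso_by_human={},
            tables=[],
            scripted=[],
        )
        assert ("a", "CloseTo", "b") in edges and ("b", "CloseTo", "a") in edges

    def test_scripted_action_takes_precedence(self):
        edges = relations_from_geometry(
            centroids={"a": np.zeros(3), "b": np.array([1.0, 0, 0])},
            torso_by_human={},
            tables=[],
            scripted=[("a", "Sawing", "b")],
        )
        assert ("a", "Sawing", "b") in edges
        assert ("a", "CloseTo", "b") not in edges
        assert ("b", "CloseTo", "a") in edges

    def test_scripted_tool_points_at_hand(self, rendered_take):
        from orssg.core import has_triplet
        from orssg.instances import JOINT_NAMES

        for b in rendered_take:
            hammering = any(rel == "Hammering" for _, rel, _ in b.gt_graph.edges)
            if not hammering:
                continue
            subj = next(s for s, rel, _ in b.gt_graph.edges if rel == "Hammering")
            pose = next(p for p in b.poses if p.person_id == subj)
            wrist = pose.joint("right_wrist")
            tool_mask = b.cloud.points_of(f"instrument:{subj}")
            assert tool_mask.sum() > 0
            dists = np.linalg.norm(b.cloud.points[tool_mask] - wrist, axis=1)
            assert np.median(dists) < 0.4


class TestRendering:
    def test_lone_table_points_within_box(self, rng):
        from orssg.synthetic import RenderItem, render_frame

        cfg = SimConfig(seed=0, take_length_s=10)
        layout = default_layout()
        center, size, _ = layout.placements["operating table"]
        item = RenderItem(
            entity_id="operating table", kind="box",
            center=np.asarray(center), size=np.asarray(size),
            n_points=500,
        )
        cloud, images = render_frame(layout, [item], cfg, rng)
        assert len(cloud) == 500
        half = np.asarray(size) / 2 + 3 * cfg.render_jitter_sd_m
        offsets = np.abs(cloud.points - np.asarray(center))
        assert (offsets <= half + 1e-9).mean() > 0.995

    def test_empty_room(self, rng):
        from orssg.synthetic import render_frame

        cfg = SimConfig(seed=0, take_length_s=10)
        cloud, images = render_frame(default_layout(), [], cfg, rng)
        assert len(cloud) == 0
        assert images.shape == (cfg.n_views, cfg.image_size, cfg.image_size, 3)
        assert np.all(images == 0)

    def test_point_count_scales_linearly(self):
        small = simulate_timeline(SimConfig(seed=1, take_length_s=10, points_per_entity=100))
        big = simulate_timeline(SimConfig(seed=1, take_length_s=10, points_per_entity=200))
        ratio = np.mean([len(b2.cloud) / len(b1.cloud) for b1, b2 in zip(small, big)])
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_instance_labels_partition_cloud(self, rendered_take):
        for b in rendered_take:
            labels = b.cloud.labels
            assert labels is not None
            assert len(labels) == len(b.cloud)
            assert labels.min() >= -1
            assert labels.max() < len(b.cloud.entity_ids)

    def test_tool_colorless_in_cloud_colored_in_images(self, rendered_take):
        from orssg.synthetic import TOOL_CLOUD_COLOR

        b = next(
            b for b in rendered_take
            if any(e.startswith("instrument:") for e in b.cloud.entity_ids)
        )
        tool_id = next(e for e in b.cloud.entity_ids if e.startswith("instrument:"))
        mask = b.cloud.points_of(tool_id)
        mean_color = b.cloud.colors[mask].mean(axis=0)
        assert np.allclose(mean_color, TOOL_CLOUD_COLOR, atol=0.05)
        # the identifying color shows up in at least one rendered view
        assert b.images.max() > 0


class TestInjectNoise:
    def test_identity_when_rates_zero(self, graph_take):
        graphs = [b.gt_graph for b in graph_take[:10]]
        out = inject_noise(graphs, NoiseConfig(), seed=0)
        assert all(a.edges == b.edges for a, b in zip(out, graphs))

    def test_full_dropout(self, graph_take):
        graphs = [b.gt_graph for b in graph_take[:10]]
        out = inject_noise(graphs, NoiseConfig(relation_dropout_rate=1.0), seed=0)
        assert all(len(g.edges) == 0 for g in out)
        assert all(len(g.nodes) == len(s.nodes) for g, s in zip(out, graphs))

    def test_binomial_survival_three_sigma(self, graph_take):
        graphs = [b.gt_graph for b in graph_take]
        n_edges = sum(len(g.edges) for g in graphs)
        p = 0.3
        out = inject_noise(graphs, NoiseConfig(relation_dropout_rate=p), seed=1)
        survived = sum(len(g.edges) for g in out)
        expected = n_edges * (1 - p)
        sigma = np.sqrt(n_edges * p * (1 - p))
        assert abs(survived - expected) <= 3 * sigma

    def test_swap_changes_labels_only(self, graph_take):
        graphs = [b.gt_graph for b in graph_take[:20]]
        out = inject_noise(graphs, NoiseConfig(relation_swap_rate=1.0), seed=2)
        for g, s in zip(out, graphs):
            assert {(a, b) for a, _, b in g.edges} == {(a, b) for a, _, b in s.edges}
            for subj, rel, obj in g.edges:
                assert rel != s.relation_between(subj, obj)

    def test_seed_reproducible(self, graph_take):
        graphs = [b.gt_graph for b in graph_take[:20]]
        noise = NoiseConfig(relation_dropout_rate=0.4, relation_swap_rate=0.3)
        a = inject_noise(graphs, noise, seed=5)
        b = inject_noise(graphs, noise, seed=5)
        assert all(x.edges == y.edges for x, y in zip(a, b))


def test_write_take_plain_text_outputs(tmp_path):
    bundles = simulate_timeline(
        SimConfig(seed=3, take_length_s=8, render=True, points_per_entity=60, n_views=2, image_size=16)
    )
    root = write_take(bundles, tmp_path, take_id="t9")
    assert (root / "gt_graphs.json").exists()
    assert (root / "meta.json").exists()
    ply = root / "frame_00000.ply"
    assert ply.read_text().startswith("ply\nformat ascii 1.0")
    assert (root / "frame_00000_view0.png").exists()
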