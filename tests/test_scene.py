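import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegconn as ec
from eegconn.errors import DomainError, MontageLookupError
from eegconn.scene import MODES, T_MAX, T_MIN

from conftest import random_symmetric_cm


def cm_from_weights(pairs_weights, labels):
    n = len(labels)
    w = np.eye(n)
    k = 0
    for a in range(n):
        for b in range(a + 1, n):
            w[a, b] = w[b, a] = pairs_weights[k]
            k += 1
    return ec.ConnectivityMatrix(w, "pcc", tuple(labels))


class TestFractionalThreshold:
    def test_positive_mean_worked_example(self):
        # weights {0.9, 0.6, 0.4, 0.1}: mean 0.5 -> 1/2 keeps {0.9, 0.6};
        # next pass mean 0.75 -> 1/4 keeps {0.9}
        w = np.array([0.9, 0.6, 0.4, 0.1])
        assert sorted(w[ec.threshold_weights(w, "1/2")]) == [0.6, 0.9]
        assert list(w[ec.threshold_weights(w, "1/4")]) == [0.9]

    def test_negative_mean_branch(self):
        # weights {-0.5, -0.3, -0.1}: mean -0.3 < 0 -> keep below the mean
        cm = cm_from_weights([-0.5, -0.3, -0.1], ["a", "b", "c"])
        half = ec.fractional_threshold(cm, "1/2")
        assert [w for _, _, w in half.edges] == [-0.5]

    def test_all_equal_weights_keep_nothing(self):
        cm = cm_from_weights([0.4, 0.4, 0.4], ["a", "b", "c"])
        assert len(ec.fractional_threshold(cm, "1/2")) == 0
        # deeper modes stay empty, not an error
        assert len(ec.fractional_threshold(cm, "1/16")) == 0

    def test_zero_mean_keeps_strictly_positive(self):
        cm = cm_from_weights([0.5, -0.5, 0.2, -0.2, 0.0, 0.0],
                             ["a", "b", "c", "d"])
        kept = ec.fractional_threshold(cm, "1/2")
        assert sorted(w for _, _, w in kept.edges) == [0.2, 0.5]

    def test_full_mode_keeps_all_offdiagonal_pairs(self):
        cm = random_symmetric_cm(6, seed=0)
        assert len(ec.fractional_threshold(cm, "full")) == 15

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_modes_are_nested(self, seed):
        cm = random_symmetric_cm(8, seed=seed, metric="pcc", low=-1.0)
        sets = [ec.fractional_threshold(cm, m).pairs() for m in MODES]
        for smaller, larger in zip(sets[1:], sets[:-1]):
            assert smaller <= larger

    def test_invariant_to_enumeration_order(self):
        cm = random_symmetric_cm(6, seed=1, metric="pcc", low=-1.0)
        perm = ("ch3", "ch5", "ch0", "ch2", "ch4", "ch1")
        kept = {frozenset((a, b)) for a, b, _ in
                ec.fractional_threshold(cm, "1/4").edges}
        kept_perm = {frozenset((a, b)) for a, b, _ in
                     ec.fractional_threshold(cm.reorder(perm), "1/4").edges}
        assert kept == kept_perm

    def test_unknown_mode_rejected(self):
        cm = random_symmetric_cm(3, seed=2)
        with pytest.raises(DomainError):
            ec.fractional_threshold(cm, "1/3")

    def test_group_matrix_thresholds_by_same_rule(self, montage):
        labels = ("F3", "F4", "P3", "P4", "O1", "O2")
        rng = np.random.default_rng(5)
        w = rng.uniform(0, 1, (6, 6))
        w = (w + w.T) / 2
        cm = ec.ConnectivityMatrix(w, "pcc", labels)
        gm = ec.aggregate_groups(cm, montage, level="region")
        vals = gm.weights[np.triu_indices(len(gm.groups), 1)]
        kept = ec.fractional_threshold(gm, "1/2")
        expect = vals[vals > vals.mean()] if vals.mean() > 0 else vals[vals < vals.mean()]
        assert sorted(w for _, _, w in kept.edges) == sorted(expect)


class TestEdgeStyle:
    def test_positive_endpoint(self):
        st_ = ec.edge_style(0.8, 0.8)
        assert st_.color_class == "golden_red"
        assert st_.thickness == pytest.approx(T_MAX)
        assert st_.opacity == pytest.approx(1.0)

    def test_negative_same_magnitude(self):
        st_ = ec.edge_style(-0.8, 0.8)
        assert st_.color_class == "black_white"
        assert st_.thickness == pytest.approx(T_MAX)
        assert st_.opacity == pytest.approx(1.0)

    def test_monotone_in_magnitude(self):
        s1 = ec.edge_style(0.2, 1.0)
        s2 = ec.edge_style(-0.7, 1.0)
        assert s1.thickness < s2.thickness
        assert s1.opacity < s2.opacity
        assert s1.thickness >= T_MIN

    def test_pure_function(self):
        assert ec.edge_style(0.5, 2.0) == ec.edge_style(0.5, 2.0)

    def test_nonpositive_absmax_rejected(self):
        with pytest.raises(DomainError):
            ec.edge_style(0.1, 0.0)


class TestBuildScene:
    def test_channel_level_has_81_nodes_and_12_region_meshes(self, montage):
        cm = random_symmetric_cm(4, seed=3, metric="pcc", low=-1.0)
        cm = ec.ConnectivityMatrix(cm.weights, "pcc",
                                   ("F3", "F4", "P3", "P4"))
        scene = ec.build_scene(cm, montage, level="channel", mode="1/2")
        assert len(scene.nodes) == 81
        assert len(scene.region_meshes) == 12
        assert len(scene.hemisphere_meshes) == 2

    def test_midline_nodes_red_others_blue(self, montage):
        cm = ec.ConnectivityMatrix(np.eye(2), "pcc", ("F3", "F4"))
        scene = ec.build_scene(cm, montage)
        colors = {n["label"]: n["color"] for n in scene.nodes}
        assert colors["Cz"] == "red" and colors["Nz"] == "red"
        assert colors["F3"] == "blue"

    def test_zero_matrix_yields_no_edges(self, montage):
        cm = ec.ConnectivityMatrix(np.zeros((3, 3)), "pcc",
                                   ("F3", "Fz", "F4"))
        scene = ec.build_scene(cm, montage, mode="full")
        assert scene.styled_edges == []
        assert len(scene.region_meshes) == 12

    def test_unresolvable_label_listed(self, montage):
        cm = ec.ConnectivityMatrix(np.eye(2), "pcc", ("F3", "QQ7"))
        with pytest.raises(MontageLookupError, match="QQ7"):
            ec.build_scene(cm, montage)

    def test_region_level_edges_join_centroids(self, montage):
        labels = ("F3", "F4", "P3", "P4")
        w = np.eye(4)
        w[0, 2] = w[2, 0] = 0.9
        cm = ec.ConnectivityMatrix(w, "pcc", labels)
        gm = ec.aggregate_groups(cm, montage, level="region")
        scene = ec.build_scene(gm, montage, level="region", mode="full")
        f_centroid = montage.coords(montage.region_index["F"]).mean(axis=0)
        edge = next(e for e in scene.styled_edges
                    if {e["a"], e["b"]} == {"F", "P"})
        coord = edge["coord_a"] if edge["a"] == "F" else edge["coord_b"]
        np.testing.assert_allclose(coord, f_centroid)

    def test_two_block_recording_deep_mode_keeps_intra_edges(
            self, two_block_rec, two_block_spec):
        base = ec.connectivity_matrix(two_block_rec, "pcc")
        comp = ec.comprehensive_matrix(base)
        kept = ec.fractional_threshold(comp, "1/8")
        blocks = two_block_spec.block_assignment()
        labels = two_block_rec.labels
        assert len(kept) > 0
        for a, b, _ in kept.edges:
            ia, ib = labels.index(a), labels.index(b)
            assert any(ia in blk and ib in blk for blk in blocks)


class TestExport:
    def test_scene_json_round_trip(self, montage, tmp_path):
        cm = ec.ConnectivityMatrix(
            np.array([[1, 0.5, -0.2], [0.5, 1, 0.8], [-0.2, 0.8, 1.0]]),
            "pcc", ("F3", "Fz", "F4"))
        scene = ec.build_scene(cm, montage, mode="full")
        p = ec.export_scene(scene, tmp_path / "s.json")
        back = ec.load_scene(p)
        assert back.level == scene.level
        assert back.styled_edges == scene.styled_edges
        assert back.meta == scene.meta
        assert [m.name for m in back.region_meshes] == \
               [m.name for m in scene.region_meshes]

    def test_empty_edge_scene_exports(self, montage, tmp_path):
        cm = ec.ConnectivityMatrix(np.zeros((2, 2)), "pcc", ("F3", "F4"))
        scene = ec.build_scene(cm, montage)
        p = ec.export_scene(scene, tmp_path / "empty.json")
        assert ec.load_scene(p).styled_edges == []

    def test_dynamic_series_writes_frames_and_manifest(self, montage, tmp_path):
        rng = np.random.default_rng(6)
        rec = ec.Recording(rng.standard_normal((3, 4000)), fs=200,
                           labels=("F3", "Fz", "F4"))
        ds = ec.dynamic_series(rec, "pcc")
        scenes = [ec.build_scene(f, montage, mode="1/2") for f in ds.frames]
        manifest = ec.export_dynamic(scenes, tmp_path / "frames")
        import json
        doc = json.loads(manifest.read_text())
        assert doc["n_frames"] == 10
        assert doc["frames"] == [f"frame_T{t}.json" for t in range(10)]
        for name in doc["frames"]:
            assert (tmp_path / "frames" / name).exists()

    def test_static_image_renders(self, montage, tmp_path):
        cm = ec.ConnectivityMatrix(
            np.array([[1, 0.7], [0.7, 1.0]]), "pcc", ("F3", "F4"))
        scene = ec.build_scene(cm, montage, mode="full")
        p = ec.export_scene(scene, tmp_path / "s.png", format="static-image")
        assert p.exists() and p.stat().st_size > 0
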