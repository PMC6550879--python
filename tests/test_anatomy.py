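"""Overlap scores, core selection, cable-by-region, Strahler, supervoxels."""

import numpy as np
import pandas as pd
import pytest

from lhcoding import anatomy, synthetic
from lhcoding.anatomy import Box, DensityField
from lhcoding.datasets import SWC_AXON, SWC_DENDRITE, LabeledSkeleton
from tests.conftest import chain_skeleton


class TestOverlapScore:
    def test_coincident_points(self):
        assert anatomy.overlap_score([[0, 0, 0]], [[0, 0, 0]]) == pytest.approx(1.0)

    def test_unit_distance_closed_form(self):
        score = anatomy.overlap_score([[0, 0, 0]], [[1, 0, 0]], delta=1.0)
        assert score == pytest.approx(np.exp(-0.5))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(7, 3))
        assert anatomy.overlap_score(a, b) == pytest.approx(
            anatomy.overlap_score(b, a)
        )

    def test_duplication_doubles_score(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(4, 3)), rng.normal(size=(6, 3))
        base = anatomy.overlap_score(a, b)
        assert anatomy.overlap_score(np.vstack([a, a]), b) == pytest.approx(2 * base)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([4.0, -2.0, 1.0])
        assert anatomy.overlap_score(a @ rot.T + shift, b @ rot.T + shift) == (
            pytest.approx(anatomy.overlap_score(a, b))
        )

    def test_empty_cloud_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert anatomy.overlap_score(np.zeros((0, 3)), [[0, 0, 0]]) == 0.0


class TestCoreSelection:
    # a dense PN-axon reference cloud: 1 µm grid in a 20 µm cube of the LH
    def _pn_cloud(self):
        return np.stack(
            np.meshgrid(*[np.arange(10.0, 30.0, 1.0)] * 3), axis=-1
        ).reshape(-1, 3)

    def _dense_chain(self, shift=0.0):
        # a long dendrite threading the same cube (~1200 µm of cable)
        xs = np.arange(11.0, 29.0, 1.0)
        ys = np.arange(11.0, 29.0, 0.5)
        coords = [
            (x + shift, y, 20.0) for y in ys[:70] for x in xs
        ]
        return chain_skeleton(coords, labels=[SWC_DENDRITE] * len(coords))

    def test_threshold_logic(self, region_layout):
        lh = region_layout["LH"]
        inside = self._dense_chain()
        outside = self._dense_chain(shift=500.0)
        res = anatomy.select_core_lhons(
            {"in": inside, "out": outside}, self._pn_cloud(), lh
        )
        assert res.loc["in", "overlap"] >= 6000
        assert res.loc["in", "core"]
        assert res.loc["out", "overlap"] < 1e-6
        assert not res.loc["out", "core"]  # overlap 0 regardless of fraction

    def test_dendrite_fraction_below_half_excluded(self, region_layout):
        lh = region_layout["LH"]  # x spans [0, 40]
        # straight dendrite of length 40/0.49 with exactly 40 µm inside
        total = 40.0 / 0.49
        skel = chain_skeleton(
            [(40.0 - total, 20.0, 20.0), (40.0, 20.0, 20.0)],
            labels=[SWC_DENDRITE] * 2,
        )
        res = anatomy.select_core_lhons({"edge": skel}, self._pn_cloud(), lh)
        assert res.loc["edge", "dendrite_fraction"] == pytest.approx(0.49, abs=1e-6)
        assert not res.loc["edge", "core"]


class TestCableByRegion:
    def test_segment_split_at_boundary(self):
        box = Box("R", (0, -1, -1), (5, 1, 1))
        skel = chain_skeleton([(0, 0, 0), (10, 0, 0)], labels=[SWC_AXON] * 2)
        length = anatomy._segment_length_in_box(
            np.array([0.0, 0, 0]), np.array([10.0, 0, 0]), box
        )
        assert length == pytest.approx(5.0)
        df = anatomy.cable_by_region(
            {"n1": skel}, pd.Series({"n1": "t1"}), {"R": box}, SWC_AXON
        )
        assert df.loc["R", "region_total"] == pytest.approx(5.0)

    def test_mean_then_sum_rule(self):
        box = Box("R", (-1, -1, -1), (100, 1, 1))
        s2 = chain_skeleton([(0, 0, 0), (2, 0, 0)], labels=[SWC_AXON] * 2)
        s4 = chain_skeleton([(0, 0, 0), (4, 0, 0)], labels=[SWC_AXON] * 2)
        df = anatomy.cable_by_region(
            {"a": s2, "b": s4},
            pd.Series({"a": "t1", "b": "t1"}),
            {"R": box},
            SWC_AXON,
        )
        assert df.loc["R", "region_total"] == pytest.approx(3.0)

    def test_cable_conserved_under_partition(self, skeleton_set):
        skel = next(iter(skeleton_set.values()))
        total = skel.cable_length(SWC_AXON)
        big = 1e4
        left = Box("L", (-big, -big, -big), (50.0, big, big))
        right = Box("R", (50.0, -big, -big), (big, big, big))
        labels = pd.Series({skel.skeleton_id: "t"})
        df = anatomy.cable_by_region(
            {skel.skeleton_id: skel}, labels, {"L": left, "R": right}, SWC_AXON
        )
        assert df["region_total"].sum() == pytest.approx(total, rel=1e-6)


class TestStrahler:
    def test_path_graph_all_ones(self):
        skel = chain_skeleton([(i, 0, 0) for i in range(6)])
        assert set(anatomy.strahler_order(skel)) == {1}

    def test_balanced_binary_tree_root_order(self):
        """Depth-D balanced binary tree: root order D+1 (leaves = 1)."""
        rows = [(1, 3, 0.0, 0.0, 0.0, 0.5, -1)]
        next_id = 2
        frontier = [1]
        depth = 3
        for d in range(depth):
            new_frontier = []
            for parent in frontier:
                for _ in range(2):
                    rows.append(
                        (next_id, 3, float(next_id), float(d + 1), 0.0, 0.5, parent)
                    )
                    new_frontier.append(next_id)
                    next_id += 1
            frontier = new_frontier
        skel = LabeledSkeleton(
            pd.DataFrame(
                rows,
                columns=["node_id", "label", "x", "y", "z", "radius", "parent_id"],
            )
        )
        order = anatomy.strahler_order(skel)
        order.index = skel.nodes["node_id"].to_numpy()
        assert order.loc[1] == depth + 1
        leaves = set(skel.nodes["node_id"]) - set(
            skel.nodes.loc[skel.nodes["parent_id"] != -1, "parent_id"]
        )
        assert all(order.loc[leaf] == 1 for leaf in leaves)


class TestSupervoxels:
    def test_single_point_field_closed_form(self):
        field = DensityField(np.array([[0.0, 0.0, 0.0]]), bandwidth=2.0)
        at_center = field.evaluate(np.array([[0.0, 0.0, 0.0]]))[0]
        norm = (2 * np.pi) ** -1.5 * 2.0**-3
        assert at_center == pytest.approx(norm)
        at_d = field.evaluate(np.array([[2.0, 0.0, 0.0]]))[0]
        assert at_d == pytest.approx(norm * np.exp(-0.5))

    def test_two_point_arbor_inclusion_is_mean_kernel(self):
        field = DensityField(np.array([[0.0, 0.0, 0.0]]), bandwidth=1.0)
        sv = anatomy.SupervoxelSet([field])
        arbor = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        norm = (2 * np.pi) ** -1.5
        expected = 0.5 * (norm + norm * np.exp(-0.5))
        assert sv.inclusion(arbor)[0] == pytest.approx(expected)

    def test_weights_sum_to_one(self):
        field = DensityField(np.random.default_rng(4).normal(size=(17, 3)), 5.0)
        assert field.weights.sum() == pytest.approx(1.0)

    def test_far_arbor_inclusion_near_zero(self):
        field = DensityField(np.zeros((3, 3)), bandwidth=2.0)
        sv = anatomy.SupervoxelSet([field])
        far = np.array([[500.0, 0.0, 0.0]])
        assert sv.inclusion(far)[0] < 1e-12

    def test_build_supervoxels_and_own_cluster_max_inclusion(self, region_layout):
        skels = synthetic.gen_skeleton_set(
            4, 2, region_layout, seed=70, jitter=0.2
        )
        sv = anatomy.build_supervoxels(
            skels, SWC_DENDRITE, n_clusters=4, bandwidth=5.0, seed=71
        )
        assert len(sv.fields) == 4
        for f in sv.fields:
            assert f.weights.sum() == pytest.approx(1.0)
        # an arbor equal to a field's own points maximizes its inclusion
        field = sv.fields[0]
        own = sv.inclusion(field.points)
        ranked = np.argsort(own)[::-1]
        assert ranked[0] == 0 or own[0] >= 0.5 * own.max()

    def test_too_few_branches_rejected(self, region_layout):
        skels = synthetic.gen_skeleton_set(1, 1, region_layout, seed=72)
        with pytest.raises(ValueError, match="sub-branches"):
            anatomy.build_supervoxels(skels, SWC_DENDRITE, n_clusters=500)


class TestSupervoxelScores:
    def test_category_scores_average_member_types(self):
        f1 = DensityField(np.zeros((1, 3)), 1.0)
        f2 = DensityField(np.full((1, 3), 10.0), 1.0)
        lh = anatomy.SupervoxelSet([f1], space="lh")
        tgt = anatomy.SupervoxelSet([f2], space="target")
        arbors_d = {"A": np.zeros((2, 3)), "B": np.full((2, 3), 10.0)}
        arbors_a = {"A": np.full((2, 3), 10.0), "B": np.zeros((2, 3))}
        out = anatomy.supervoxel_scores(
            lh, tgt, arbors_d, arbors_a,
            category_per_type={"A": "amine", "B": "ester"},
        )
        cat = out["category_scores"]["lh"]
        assert cat.loc[0, "amine"] == pytest.approx(out["lh_inclusion"].loc["A", 0])
        assert cat.loc[0, "ester"] == pytest.approx(out["lh_inclusion"].loc["B", 0])
        # projection is the product of mean inclusions
        proj_a = out["projection"]["A"]
        assert proj_a[0, 0] == pytest.approx(
            out["lh_inclusion"].loc["A", 0] * out["target_inclusion"].loc["A", 0]
        )
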