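import math

import numpy as np
import pytest

from vesselreg.decomposition import (
    KIND_LEAF,
    KIND_SALIENT,
    Branch,
    annotate_features,
    decompose,
    forward_direction,
    sum_radius,
    tortuosity,
)
from vesselreg.nsi import compute_nsi, match_salient_points

from conftest import build_graph


class TestDecompose:
    def test_cross_center_gives_four_leaf_branches(self):
        # four arms around one salient center
        g = build_graph(
            [(0, 0), (1, 0), (2, 0), (-1, 0), (-2, 0), (0, 1), (0, 2), (0, -1), (0, -2)],
            [(0, 1), (1, 2), (0, 3), (3, 4), (0, 5), (5, 6), (0, 7), (7, 8)],
        )
        branches, residual = decompose(g, {0})
        assert len(branches) == 4
        assert all(b.kind == KIND_LEAF for b in branches)
        assert residual == set()

    def test_two_salients_one_path_single_kind1(self):
        g = build_graph(
            [(i, 0) for i in range(5)], [(i, i + 1) for i in range(4)]
        )
        branches, residual = decompose(g, {0, 4})
        assert len(branches) == 1
        (b,) = branches
        assert b.kind == KIND_SALIENT and b.nodes == [1, 2, 3]
        assert residual == set()

    def test_y_graph_edge_disjoint_leaf_branches(self):
        g = build_graph(
            [(0, 0), (0, 1), (1, 1), (-1, 1)], [(0, 1), (1, 2), (1, 3)]
        )
        branches, residual = decompose(g, {1})
        assert len(branches) == 3
        seen = set()
        for b in branches:
            assert not (b.edge_set & seen)
            seen |= b.edge_set
        assert residual == set()

    def test_branch_edges_plus_residual_partition_all_edges(self, tree):
        scores = compute_nsi(tree)
        pairs = match_salient_points(tree, tree, scores, scores)
        salient = {p.ref_id for p in pairs}
        branches, residual = decompose(tree, salient)
        claimed = [e for b in branches for e in b.edge_set]
        assert len(claimed) == len(set(claimed))  # pairwise edge-disjoint
        assert set(claimed) | residual == {frozenset(e) for e in tree.edges()}
        assert not (set(claimed) & residual)

    def test_no_salient_interior(self, tree):
        scores = compute_nsi(tree)
        pairs = match_salient_points(tree, tree, scores, scores)
        salient = {p.ref_id for p in pairs}
        branches, _ = decompose(tree, salient)
        for b in branches:
            assert not (set(b.nodes) & salient)

    def test_kind1_anchored_by_priority(self):
        g = build_graph([(i, 0) for i in range(5)], [(i, i + 1) for i in range(4)])
        hi_first, _ = decompose(g, {0, 4}, anchor_priority={0: 10.0, 4: 1.0})
        assert hi_first[0].anchor == 0 and hi_first[0].terminal == 4
        hi_last, _ = decompose(g, {0, 4}, anchor_priority={0: 1.0, 4: 10.0})
        assert hi_last[0].anchor == 4 and hi_last[0].nodes == [3, 2, 1]

    def test_empty_salient_set_rejected(self, path3):
        with pytest.raises(ValueError):
            decompose(path3, set())


class TestForwardDirection:
    @pytest.mark.parametrize(
        "first_pos,expected",
        [((1, 0), 0.0), ((0, 1), 90.0), ((-1, -1), 225.0)],
    )
    def test_ccw_angle_from_positive_x(self, first_pos, expected):
        g = build_graph([(0, 0), first_pos], [(0, 1)])
        b = Branch(0, [1], KIND_LEAF, anchor=0)
        assert forward_direction(g, b) == pytest.approx(expected)

    def test_3d_returns_unit_vector(self):
        g = build_graph([(0, 0, 0), (0, 3, 4)], [(0, 1)])
        v = forward_direction(g, Branch(0, [1], KIND_LEAF, anchor=0))
        assert np.allclose(v, [0, 0.6, 0.8])

    def test_coincident_anchor_rejected(self):
        g = build_graph([(0, 0), (0, 0)], [(0, 1)])
        with pytest.raises(ValueError, match="coincident"):
            forward_direction(g, Branch(0, [1], KIND_LEAF, anchor=0))

    def test_rotation_equivariance(self):
        g = build_graph([(0, 0), (1, 1)], [(0, 1)])
        b = Branch(0, [1], KIND_LEAF, anchor=0)
        base = forward_direction(g, b)
        a = math.radians(30)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        rot = build_graph([(0, 0), R @ [1, 1]], [(0, 1)])
        assert forward_direction(rot, b) == pytest.approx((base + 30) % 360)


class TestBranchFeatures:
    def test_sum_radius_is_plain_sum(self):
        g = build_graph([(0, 0), (1, 0), (2, 0), (3, 0)], [(0, 1), (1, 2), (2, 3)],
                        radii=[9, 1, 2, 3])
        b = Branch(0, [1, 2, 3], KIND_LEAF, anchor=0)
        assert sum_radius(b, g) == pytest.approx(6.0)
        doubled = build_graph([(0, 0), (1, 0), (2, 0), (3, 0)],
                              [(0, 1), (1, 2), (2, 3)], radii=[9, 2, 4, 6])
        assert sum_radius(b, doubled) == pytest.approx(12.0)

    def test_tortuosity_collinear_is_one(self):
        g = build_graph([(i, 0) for i in range(5)], [(i, i + 1) for i in range(4)])
        b = Branch(0, [1, 2, 3, 4], KIND_LEAF, anchor=0)
        assert tortuosity(b, g) == pytest.approx(1.0)

    def test_tortuosity_l_path(self):
        g = build_graph([(9, 9), (0, 0), (1, 0), (1, 1)], [(0, 1), (1, 2), (2, 3)])
        b = Branch(0, [1, 2, 3], KIND_LEAF, anchor=0)
        assert tortuosity(b, g) == pytest.approx(2 / math.sqrt(2))

    def test_tortuosity_semicircle_limit(self):
        n = 400
        ang = np.linspace(0, math.pi, n)
        pts = [(-2, 0)] + [(math.cos(a), math.sin(a)) for a in ang]
        g = build_graph(pts, [(i, i + 1) for i in range(n)])
        b = Branch(0, list(range(1, n + 1)), KIND_LEAF, anchor=0)
        assert tortuosity(b, g) == pytest.approx(math.pi / 2, rel=1e-4)

    def test_tortuosity_coincident_endpoints_rejected(self):
        g = build_graph([(5, 5), (0, 0), (1, 0), (0, 0.0)], [(0, 1), (1, 2), (2, 3)])
        b = Branch(0, [1, 2, 3], KIND_LEAF, anchor=0)
        with pytest.raises(ValueError, match="coincident"):
            tortuosity(b, g)

    def test_rigid_motion_invariance_and_scale(self, tree):
        scores = compute_nsi(tree)
        pairs = match_salient_points(tree, tree, scores, scores)
        branches, _ = decompose(tree, {p.ref_id for p in pairs})
        annotate_features(branches, tree)
        a = math.radians(73)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        moved = build_graph(
            [R @ tree.position(i) + [11, -4] for i in tree.node_ids],
            tree.edges(),
            radii=[tree.radius(i) for i in tree.node_ids],
            ids=tree.node_ids,
        )
        for b in branches:
            if len(b.nodes) < 2:
                continue
            assert tortuosity(b, moved) == pytest.approx(b.tortuosity, rel=1e-12)
            assert sum_radius(b, moved) == pytest.approx(b.sum_radius, rel=1e-12)
            rotated = forward_direction(moved, b)
            assert rotated == pytest.approx((b.forward_direction + 73) % 360, abs=1e-9)
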