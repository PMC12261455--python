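"""Path enumeration and the similarity-tensor featurization pipeline."""

import math

import numpy as np
import pytest

from mol3dkern import (
    MoleculeGraph,
    build_path_tensors,
    cmotif_feature,
    continuous_features,
    enumerate_khop_paths,
    make_chain_fixture,
    node_feature_map,
    sample_molecule,
    twohop_feature,
)
from mol3dkern.hopfeatures import PATH_ADJACENCY_4
from conftest import random_rotation


def star_k13():
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]], float)
    return MoleculeGraph(["C", "N", "O", "F"], coords, [(0, 1), (0, 2), (0, 3)])


def cycle(n, radius=1.0):
    ang = 2 * np.pi * np.arange(n) / n
    coords = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)], axis=1)
    edges = [(i, (i + 1) % n) for i in range(n)]
    return MoleculeGraph(["C"] * n, coords, edges)


class TestEnumeration:
    def test_path_graph_has_two_directed_paths(self, collinear4):
        assert enumerate_khop_paths(collinear4, 3) == [(0, 1, 2, 3), (3, 2, 1, 0)]

    def test_star_has_no_three_hop_path(self):
        assert enumerate_khop_paths(star_k13(), 3) == []

    def test_four_cycle_has_eight(self):
        paths = enumerate_khop_paths(cycle(4), 3)
        assert len(paths) == 8
        # two directed 3-edge simple paths start at every node
        starts = [p[0] for p in paths]
        assert all(starts.count(s) == 2 for s in range(4))

    def test_dedupe_keeps_one_direction(self, collinear4):
        assert enumerate_khop_paths(collinear4, 3, dedupe_reversed=True) == [
            (0, 1, 2, 3)
        ]

    def test_paths_are_simple_and_sorted(self):
        g = sample_molecule(5, 12, ring_prob=0.3)
        paths = enumerate_khop_paths(g, 3)
        assert paths == sorted(paths)
        nbrs = g.neighbor_lists()
        for p in paths:
            assert len(set(p)) == 4
            for u, v in zip(p, p[1:]):
                assert v in nbrs[u]


class TestTensorPipeline:
    def test_chain_adjacency_matrix(self):
        expected = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], float
        )
        assert np.array_equal(PATH_ADJACENCY_4, expected)

    def test_masking_and_diagonals(self):
        g = sample_molecule(9, 10, ring_prob=0.2)
        for path in enumerate_khop_paths(g, 3)[:20]:
            t = build_path_tensors(g, path)
            assert np.allclose(np.diag(t.d), 0)
            assert np.allclose(np.diag(t.a), 1)
            assert np.all((t.a > 0) & (t.a <= 1))
            # A1 vanishes exactly off the chain, including the diagonal
            assert np.array_equal(t.a1 != 0, PATH_ADJACENCY_4 != 0)
            assert np.allclose(np.diag(t.a2), 0)
            assert np.allclose(np.diag(t.a3), 0)

    def test_closed_forms_on_random_paths(self):
        """Matrix pipeline reproduces the printed closed forms (500 paths)."""
        rng = np.random.default_rng(21)
        n = 0
        while n < 500:
            coords = rng.normal(size=(4, 3)) * 1.4
            g = make_chain_fixture(4, geometry="coords", coords=coords)
            t = build_path_tensors(g, (0, 1, 2, 3))
            d = t.d
            a2_ac = math.exp(-(d[0, 1] + d[1, 2] - d[0, 2]))
            a3_ad = math.exp(-(d[0, 1] + d[1, 2] + d[2, 3] - d[0, 2] - d[0, 3]))
            a3_da = math.exp(-(d[0, 1] + d[1, 2] + d[2, 3] - d[1, 3] - d[0, 3]))
            assert t.a2[0, 2] == pytest.approx(a2_ac, abs=1e-10)
            assert t.a3[0, 3] == pytest.approx(a3_ad, abs=1e-10)
            assert t.a3[3, 0] == pytest.approx(a3_da, abs=1e-10)
            n += 1

    def test_collinear_chain_closed_forms(self, collinear4):
        t = build_path_tensors(collinear4, (0, 1, 2, 3))
        assert t.a2[0, 2] == pytest.approx(1.0, abs=1e-12)  # exp(-(1+1-2))
        assert t.a2[1, 3] == pytest.approx(1.0, abs=1e-12)
        assert t.a3[0, 3] == pytest.approx(math.e**2, rel=1e-12)
        assert t.a3[3, 0] == pytest.approx(math.e**2, rel=1e-12)

    def test_bond_similarity_decreases_with_distance(self):
        base = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 1]], float)
        prev = None
        for stretch in (1.0, 1.2, 1.5, 2.0):
            coords = base.copy()
            coords[0, 0] = 1 - stretch  # lengthen d_AB only
            g = make_chain_fixture(4, geometry="coords", coords=coords)
            t = build_path_tensors(g, (0, 1, 2, 3))
            if prev is not None:
                assert t.a1[0, 1] < prev
            prev = t.a1[0, 1]


class TestCMotifFeature:
    def test_collinear_fixture_values(self, collinear4):
        f = cmotif_feature(collinear4, (0, 1, 2, 3))
        e = math.exp
        assert f.label4 == ("C", "C", "C", "C")
        assert np.allclose(
            f.dist6, (e(-1), e(-1), e(-1), e(-2), e(-2), e(-3)), atol=1e-12
        )
        assert f.angle2 == pytest.approx((1.0, 1.0), abs=1e-12)
        assert f.torsion1 == pytest.approx(2 * math.e**2, rel=1e-12)

    def test_reversal_permutes_but_preserves_torsion(self):
        g = sample_molecule(4, 8, ring_prob=0.0)
        paths = enumerate_khop_paths(g, 3)
        for p in paths[:5]:
            f = cmotif_feature(g, p)
            r = cmotif_feature(g, p[::-1])
            assert r.label4 == f.label4[::-1]
            # reversal swaps AB<->CD and AC<->BD, fixes BC and AD
            ab, bc, cd, ac, bd, ad = f.dist6
            assert np.allclose(r.dist6, (cd, bc, ab, bd, ac, ad), atol=1e-12)
            assert r.torsion1 == pytest.approx(f.torsion1, rel=1e-12)

    def test_rigid_transform_leaves_feature_unchanged(self):
        rng = np.random.default_rng(2)
        g = sample_molecule(12, 10, ring_prob=0.2)
        moved = g.transformed(random_rotation(rng), rng.normal(size=3) * 5)
        for p in enumerate_khop_paths(g, 3):
            f0 = cmotif_feature(g, p).vector
            f1 = cmotif_feature(moved, p).vector
            assert np.allclose(f0, f1, atol=1e-10)


class TestNodeFeatureMap:
    def test_chain_ends_hold_the_paths(self, collinear4):
        fmap = node_feature_map(collinear4)
        assert len(fmap[0]) == 1 and len(fmap[3]) == 1
        assert fmap[1] == {} and fmap[2] == {}
        key = ("C", "C", "C", "C")
        assert len(fmap[0][key]) == 1
        assert fmap[0][key][0].shape == (9,)

    def test_total_paths_conserved(self):
        for seed in (1, 2, 3):
            g = sample_molecule(seed, 14, ring_prob=0.25)
            fmap = node_feature_map(g)
            stored = sum(len(v) for m in fmap for v in m.values())
            assert stored == len(enumerate_khop_paths(g, 3))

    def test_two_hop_map_has_four_features(self):
        g = sample_molecule(8, 10, ring_prob=0.1)
        fmap = node_feature_map(g, hops=2)
        vecs = [v for m in fmap for lst in m.values() for v in lst]
        assert vecs and all(v.shape == (4,) for v in vecs)


class TestTwoHopFeature:
    def test_right_angle(self):
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0]], float)
        g = MoleculeGraph(["C", "C", "C"], coords, [(0, 1), (1, 2)])
        labels, f = twohop_feature(g, (0, 1, 2))
        assert labels == ("C", "C", "C")
        assert f[3] == pytest.approx(math.exp(-(2 - math.sqrt(2))), rel=1e-12)

    def test_collinear_angle_similarity_is_one(self):
        g = make_chain_fixture(3)
        _, f = twohop_feature(g, (0, 1, 2))
        assert f[3] == pytest.approx(1.0, abs=1e-12)

    def test_equilateral(self):
        ang = math.pi / 3
        coords = np.array([[0, 0, 0], [1, 0, 0], [math.cos(ang), math.sin(ang), 0]])
        g = MoleculeGraph(["C"] * 3, coords, [(0, 1), (1, 2)])
        _, f = twohop_feature(g, (0, 1, 2))
        assert f[3] == pytest.approx(math.exp(-1), rel=1e-12)
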