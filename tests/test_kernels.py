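"""Kernel assembly: node kernels, the four graph kernels, Gram matrices."""

import numpy as np
import pytest
from sklearn.base import clone

from mol3dkern import (
    ChainMotifKernel,
    GraphHopper2DKernel,
    GraphHopper3DKernel,
    GraphHopper3DTwoHopKernel,
    GramMatrix,
    KernelConfig,
    KERNELS,
    MoleculeGraph,
    brute_force_weights,
    cmotif_feature,
    ghk2d,
    ghk3d,
    cmgk,
    gram,
    make_chain_fixture,
    node_feature_map,
    read_gram_tsv,
    sample_molecule,
    write_gram_tsv,
)
from mol3dkern.kernels import kn3d_node_kernel, knc_node_kernel
from conftest import molecule_corpus, random_rotation

ALL_KERNELS = sorted(KERNELS)


class TestNodeKernels:
    def test_knc_identical_motif_is_squared_norm(self, collinear4):
        f = cmotif_feature(collinear4, (0, 1, 2, 3))
        assert knc_node_kernel(f, f) == pytest.approx(f.vector @ f.vector)
        assert knc_node_kernel(f, f) > 0

    def test_knc_dirac_gate_closes_on_different_multisets(self):
        g1 = make_chain_fixture(4, labels=list("CCCO"))
        g2 = make_chain_fixture(4, labels=list("CCCN"))
        f1 = cmotif_feature(g1, (0, 1, 2, 3))
        f2 = cmotif_feature(g2, (0, 1, 2, 3))
        assert knc_node_kernel(f1, f2) == 0.0

    def test_knc_motif_vs_reversal(self, collinear4):
        f = cmotif_feature(collinear4, (0, 1, 2, 3))
        r = cmotif_feature(collinear4, (3, 2, 1, 0))
        # same multiset -> gate open; value is the dot of the permuted features
        assert knc_node_kernel(f, r) == pytest.approx(f.vector @ r.vector)
        # ordered matching can still distinguish direction
        g = make_chain_fixture(4, labels=list("NCCO"))
        fo = cmotif_feature(g, (0, 1, 2, 3))
        ro = cmotif_feature(g, (3, 2, 1, 0))
        assert knc_node_kernel(fo, ro, label_match="ordered") == 0.0

    def test_kn3d_label_mismatch_and_empty_map(self, collinear4):
        fmap = node_feature_map(collinear4)
        assert kn3d_node_kernel("C", "N", fmap[0], fmap[0]) == 0.0
        assert kn3d_node_kernel("C", "C", fmap[1], fmap[0]) == 0.0  # no paths at 1

    def test_kn3d_chain_ends(self, collinear4):
        fmap = node_feature_map(collinear4)
        f = cmotif_feature(collinear4, (0, 1, 2, 3)).vector
        value = kn3d_node_kernel("C", "C", fmap[0], fmap[0])
        assert value == pytest.approx(f @ f, rel=1e-12)


class TestPairwiseKernels:
    def test_self_kernels_positive(self):
        g = make_chain_fixture(5)
        assert cmgk(g, g) > 0
        assert ghk3d(g, g) > 0
        assert ghk2d(g, g) > 0

    def test_label_disjoint_molecules_give_zero(self):
        g1 = sample_molecule(1, 8, label_alphabet=("C", "N"))
        g2 = sample_molecule(2, 8, label_alphabet=("S", "P"))
        assert cmgk(g1, g2) == 0.0
        assert ghk3d(g1, g2) == 0.0
        assert ghk2d(g1, g2) == 0.0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(8)
        g = sample_molecule(20, 12, ring_prob=0.2)
        for fn in (cmgk, ghk3d):
            ref = fn(g, g)
            for _ in range(3):
                moved = g.transformed(random_rotation(rng), rng.normal(size=3) * 8)
                assert abs(fn(g, moved) - ref) <= 1e-8 * ref

    def test_ghk2d_ignores_coordinates_entirely(self):
        g = sample_molecule(5, 10, ring_prob=0.2)
        warped = MoleculeGraph(
            g.labels, g.coords * 3.7 + 1.0, g.edges, name=g.name
        )  # non-rigid warp
        assert ghk2d(g, warped) == ghk2d(g, g)

    def test_mirror_image_is_indistinguishable(self):
        g = sample_molecule(30, 12, ring_prob=0.15)
        mirror = MoleculeGraph(g.labels, -g.coords, g.edges, name="mirror")
        assert cmgk(g, mirror) == pytest.approx(cmgk(g, g), rel=1e-10)
        assert ghk3d(g, mirror) == pytest.approx(ghk3d(g, g), rel=1e-10)

    def test_ghk2d_single_edge_pair_matches_oracle(self):
        g = make_chain_fixture(2, labels=["C", "C"])
        w = brute_force_weights(g, g)
        # all four label gates open
        assert ghk2d(g, g) == pytest.approx(w.sum())

    def test_ghk3d_matches_unfactorized_brute_force(self):
        """Literal double sum of w x kn3d on small molecules, via the oracle weights."""
        rng = np.random.default_rng(14)
        for seed in (3, 4, 5):
            g1 = sample_molecule(seed, int(rng.integers(5, 9)), ring_prob=0.3)
            g2 = sample_molecule(seed + 50, int(rng.integers(5, 9)), ring_prob=0.3)
            w = brute_force_weights(g1, g2)
            f1, f2 = node_feature_map(g1), node_feature_map(g2)
            literal = sum(
                w[v, u] * kn3d_node_kernel(g1.labels[v], g2.labels[u], f1[v], f2[u])
                for v in range(g1.n_atoms)
                for u in range(g2.n_atoms)
            )
            assert ghk3d(g1, g2) == pytest.approx(literal, rel=1e-10, abs=1e-12)

    def test_small_molecule_without_paths_gives_zero_3d_kernels(self):
        g = make_chain_fixture(3)  # no 3-hop path
        assert cmgk(g, g) == 0.0
        assert ghk3d(g, g) == 0.0
        assert ghk2d(g, g) > 0.0  # the 2D baseline still sees structure


@pytest.fixture(scope="module")
def corpus():
    return molecule_corpus(seed=100, count=10, min_atoms=6, max_atoms=14)


class TestGram:

    @pytest.mark.parametrize("kernel", ALL_KERNELS)
    def test_symmetric_psd(self, corpus, kernel):
        gm = gram(corpus, kernel)
        k = gm.values
        assert np.allclose(k, k.T, rtol=1e-9)
        eig = np.linalg.eigvalsh(k)
        assert eig.min() >= -1e-8 * np.trace(k)

    def test_single_molecule(self):
        g = make_chain_fixture(5)
        gm = gram([g], "3dghk")
        assert gm.values.shape == (1, 1)
        assert gm.values[0, 0] == pytest.approx(ghk3d(g, g))

    @pytest.mark.parametrize("kernel", ALL_KERNELS)
    def test_normalized_diagonal_is_unit(self, corpus, kernel):
        cfg = KernelConfig(kernel_name=kernel, normalize=True)
        gm = gram(corpus, cfg)
        diag = np.diag(gram(corpus, kernel).values)
        for i, d in enumerate(diag):
            expected = 1.0 if d > 0 else 0.0
            assert gm.values[i, i] == pytest.approx(expected, abs=1e-12)
        assert np.abs(gm.values).max() <= 1 + 1e-9

    def test_transform_matches_fit_transform_block(self, corpus):
        est = GraphHopper3DKernel()
        square = est.fit_transform(corpus)
        cross = est.transform(corpus[:3])
        assert np.allclose(cross, square[:3], rtol=1e-12)

    def test_estimators_are_sklearn_clonable(self):
        est = ChainMotifKernel(normalize=True, motif_label_match="ordered")
        params = est.get_params()
        assert params["normalize"] is True
        twin = clone(est)
        assert twin.get_params() == params

    def test_tsv_round_trip(self, corpus, tmp_path):
        gm = gram(corpus, "ghk2d")
        path = tmp_path / "gram.tsv"
        write_gram_tsv(gm, path)
        back = read_gram_tsv(path)
        assert back.names == gm.names
        assert np.allclose(back.values, gm.values, rtol=1e-11)

    def test_unknown_kernel_name_rejected(self):
        with pytest.raises(ValueError):
            KernelConfig(kernel_name="wlk")

    def test_two_hop_ablation_runs_and_uses_four_features(self):
        mols = molecule_corpus(seed=7, count=5, min_atoms=6, max_atoms=10)
        est = GraphHopper3DTwoHopKernel()
        k = est.fit_transform(mols)
        assert np.allclose(k, k.T)
        sums = est.profiles_[0][2]
        vecs = [v for d in sums for v in d.values()]
        assert vecs and all(v.shape == (4,) for v in vecs)
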