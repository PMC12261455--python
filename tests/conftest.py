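import numpy as np
import pytest

from mol3dkern import make_chain_fixture, sample_molecule


@pytest.fixture
def collinear4():
    """Unit-spaced collinear C-C-C-C chain on the x-axis."""
    return make_chain_fixture(4, bond_length=1.0)


@pytest.fixture
def cis_quad():
    return np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float)


@pytest.fixture
def trans_quad():
    return np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]], dtype=float)


def random_rotation(rng):
    """Haar-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def molecule_corpus(seed, count, min_atoms, max_atoms, ring_prob=0.15):
    rng = np.random.default_rng(seed)
    mols = []
    for i in range(count):
        n = int(rng.integers(min_atoms, max_atoms + 1))
        mols.append(
            sample_molecule(int(rng.integers(2**31)), n, ring_prob=ring_prob,
                            name=f"mol{i}")
        )
    return mols
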