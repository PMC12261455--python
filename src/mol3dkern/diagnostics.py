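"""Self-validation routines: oracle comparisons and kernel health checks.

These functions recompute, from scratch, the properties the package promises:
agreement of the distance-only torsion with the vector oracle, the tensor
pipeline's closed forms, equivalence of the fast hop-weight computation with
literal shortest-path enumeration, Gram-matrix validity (symmetry, positive
semidefiniteness), rigid-motion invariance, c-motif graph correctness against
brute force, and sanity of the SVM screening harness.  They are used by the
test suite and by the reproduction script; every routine is deterministic
given its seed.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import hopper
from .cmotif import build_cmotif_graph
from .geometry import (
    QuadrupleGeometry,
    torsion_cos_vector_oracle,
)
from .hopfeatures import build_path_tensors, enumerate_khop_paths
from .kernels import KernelConfig, gram, make_kernel
from .molio import MoleculeGraph, make_chain_fixture, sample_molecule
from .screen import evaluate_kernel

__all__ = [
    "torsion_identity_max_error",
    "closed_form_max_error",
    "hopper_oracle_mismatches",
    "gram_health",
    "rigid_invariance_max_deviation",
    "cmotif_mismatches",
    "molecule_corpus",
    "random_rotation",
    "separable_screen_dataset",
    "structure_screen_dataset",
]


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish random proper rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def molecule_corpus(
    seed,
    count: int,
    min_atoms: int,
    max_atoms: int,
    mean_rings: float = 1.5,
) -> list[MoleculeGraph]:
    """Deterministic corpus of random synthetic molecules.

    The per-pair ring-closure probability is set so each molecule carries
    ``mean_rings`` ring bonds on average, the regime of small organic
    molecules (average node degree slightly above 2).
    """
    rng = np.random.default_rng(seed)
    mols = []
    for i in range(count):
        n = int(rng.integers(min_atoms, max_atoms + 1))
        candidates = n * (n - 1) / 2 - (n - 1)
        ring_prob = min(1.0, mean_rings / candidates) if candidates else 0.0
        mols.append(
            sample_molecule(
                int(rng.integers(2**31)), n, ring_prob=ring_prob, name=f"mol{i}"
            )
        )
    return mols


def torsion_identity_max_error(n_quadruples: int = 1000, seed=0) -> float:
    """Max |cos phi (six distances) - cos phi (vector oracle)| over random quadruples.

    Nearly collinear configurations (denominator < 1e-6) are skipped: both
    routes are ill-conditioned there and the torsion is reported undefined.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_quadruples:
        pts = rng.normal(size=(4, 3)) * 1.2
        oracle = torsion_cos_vector_oracle(*pts)
        if oracle is None:
            continue
        q = QuadrupleGeometry.from_points(*pts)
        if q.l < 1e-6 or q.cos_phi is None:
            continue
        worst = max(worst, abs(q.cos_phi - oracle))
        done += 1
    return worst


def closed_form_max_error(n_paths: int = 500, seed=0) -> float:
    """Max deviation of (A2)_AC, (A3)_AD, (A3)_DA from their closed forms."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_paths):
        coords = rng.normal(size=(4, 3)) * 1.4
        g = make_chain_fixture(4, geometry="coords", coords=coords)
        t = build_path_tensors(g, (0, 1, 2, 3))
        d = t.d
        worst = max(
            worst,
            abs(t.a2[0, 2] - np.exp(-(d[0, 1] + d[1, 2] - d[0, 2]))),
            abs(t.a3[0, 3] - np.exp(-(d[0, 1] + d[1, 2] + d[2, 3] - d[0, 2] - d[0, 3]))),
            abs(t.a3[3, 0] - np.exp(-(d[0, 1] + d[1, 2] + d[2, 3] - d[1, 3] - d[0, 3]))),
        )
    return worst


def _random_adjacency(rng, n: int, p: float = 0.35) -> np.ndarray:
    a = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                a[i, j] = a[j, i] = True
    return a


def hopper_oracle_mismatches(
    n_pairs: int = 200, seed=0, max_nodes: int = 8
) -> int:
    """Graph pairs where fast hop weights differ from enumerated weights.

    Checks both trivial-path conventions on every pair; returns the number of
    (pair, convention) combinations with any disagreement.  Zero means exact
    equivalence.
    """
    rng = np.random.default_rng(seed)
    bad = 0
    for _ in range(n_pairs):
        a1 = _random_adjacency(rng, int(rng.integers(2, max_nodes + 1)))
        a2 = _random_adjacency(rng, int(rng.integers(2, max_nodes + 1)))
        for include_trivial in (False, True):
            fast = hopper._cropped_inner(
                hopper.occurrence_matrices(a1, include_trivial=include_trivial),
                hopper.occurrence_matrices(a2, include_trivial=include_trivial),
            )
            slow = hopper.brute_force_weights(a1, a2, include_trivial=include_trivial)
            if not np.array_equal(fast, slow):
                bad += 1
    return bad


def gram_health(mols, kernel_name: str) -> dict[str, float]:
    """Symmetry error and min-eigenvalue/trace ratio of a kernel Gram matrix."""
    k = gram(mols, kernel_name).values
    eig = np.linalg.eigvalsh(k)
    trace = float(np.trace(k))
    return {
        "symmetry_error": float(np.abs(k - k.T).max()),
        "min_eigenvalue": float(eig.min()),
        "trace": trace,
        "min_eig_over_trace": float(eig.min() / trace) if trace > 0 else 0.0,
    }


def rigid_invariance_max_deviation(
    mols, kernel_name: str, n_transforms: int = 20, seed=0
) -> float:
    """Max relative |K(G, RG+t) - K(G, G)| / K(G, G) over molecules x transforms."""
    rng = np.random.default_rng(seed)
    est = make_kernel(KernelConfig(kernel_name=kernel_name))
    worst = 0.0
    for g in mols:
        est.fit([g])
        ref = float(est.transform([g])[0, 0])
        if ref == 0.0:
            continue
        moved = [
            g.transformed(random_rotation(rng), rng.normal(size=3) * 10.0)
            for _ in range(n_transforms)
        ]
        vals = est.transform(moved)[:, 0]
        worst = max(worst, float(np.abs(vals - ref).max() / ref))
    return worst


def cmotif_mismatches(graphs) -> int:
    """Graphs whose c-motif graph differs from exhaustive construction.

    Compares motif node sets against the path enumeration and edges against
    literal pairwise atom-set intersection; returns the number of graphs with
    any discrepancy (zero = exact).
    """
    bad = 0
    for g in graphs:
        c = build_cmotif_graph(g)
        paths = enumerate_khop_paths(g, 3)
        ok = c.motifs == sorted(paths)
        expected_edges = {
            (i, j)
            for i, j in itertools.combinations(range(len(c.motifs)), 2)
            if set(c.motifs[i]) & set(c.motifs[j])
        }
        ok = ok and set(c.edges) == expected_edges
        if not ok:
            bad += 1
    return bad


def separable_screen_dataset(seed=0, n_per_class: int = 24):
    """Two-class set with disjoint atom alphabets: block-structured ghk2d Gram."""
    rng = np.random.default_rng(seed)
    mols, labels = [], {}
    for i in range(n_per_class):
        a = sample_molecule(int(rng.integers(2**31)), 9, ring_prob=0.1,
                            label_alphabet=("C", "N", "O"), name=f"act{i}")
        b = sample_molecule(int(rng.integers(2**31)), 9, ring_prob=0.1,
                            label_alphabet=("S", "P", "F"), name=f"ina{i}")
        mols += [a, b]
        labels[a.name] = "active"
        labels[b.name] = "inactive"
    return gram(mols, "ghk2d"), labels


def structure_screen_dataset(seed=0, n_per_class: int = 18, n_atoms: int = 10):
    """Two-class set differing in topology (acyclic vs ring-rich), shared alphabet.

    Used to exercise the 3-hop vs 2-hop ablation end to end: the classes are
    separable only through structural features, not through labels.
    """
    rng = np.random.default_rng(seed)
    mols, labels = [], {}
    for i in range(n_per_class):
        a = sample_molecule(int(rng.integers(2**31)), n_atoms, ring_prob=0.0,
                            name=f"chain{i}")
        b = sample_molecule(int(rng.integers(2**31)), n_atoms, ring_prob=0.45,
                            name=f"ring{i}")
        mols += [a, b]
        labels[a.name] = "active"
        labels[b.name] = "inactive"
    return mols, labels
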