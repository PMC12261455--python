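"""3D features of k-hop paths: the similarity-tensor pipeline.

For every directed simple 3-hop path A-B-C-D in a molecule a 4x4 distance
matrix ``d`` is turned into a similarity matrix ``A = exp(-d)`` and pushed
through a short chain of masked matrix products:

    A1 = A (.) Adj                 bond-length similarities on the chain
    A2 = (A1 @ A1) (./) A          bond-angle similarities
    A3 = (A2 @ A1) (./) A          torsion similarities

where ``Adj`` is the fixed path adjacency, ``(.)`` is the elementwise product
and ``(./)`` divides off-diagonal entries elementwise and zeroes the diagonal
(self-interactions are excluded).  The pipeline collapses to closed forms:

    (A2)_AC = exp(-(d_AB + d_BC - d_AC))
    (A3)_AD = exp(-(d_AB + d_BC + d_CD - d_AC - d_AD))
    (A3)_DA = exp(-(d_AB + d_BC + d_CD - d_BD - d_AD))

The exponents vanish exactly when the atoms are collinear, so these entries
are monotone surrogates for the bond angle and the torsion angle built from
distances alone (the exact distance-only torsion cosine lives in
:mod:`mol3dkern.geometry` and serves as theory/oracle, not as the feature).

Each path yields 9 continuous features — six pairwise similarities
``exp(-d)`` (AB, BC, CD, AC, BD, AD), two angle entries ``(A2)_AC, (A2)_BD``
and one torsion entry ``(A3)_AD + (A3)_DA`` — plus the 4 ordered atom labels.
The 2-hop ablation applies the same construction to paths A-B-C (3 labels,
3 similarities, 1 angle entry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molio import MoleculeGraph

__all__ = [
    "PATH_ADJACENCY_4",
    "PATH_ADJACENCY_3",
    "enumerate_khop_paths",
    "build_path_tensors",
    "continuous_features",
    "cmotif_feature",
    "node_feature_map",
    "twohop_feature",
    "PathTensorSet",
    "CMotifFeature",
]

#: fixed adjacency of the 4-node chain A-B-C-D
PATH_ADJACENCY_4 = np.array(
    [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]], dtype=float
)
#: 3-node chain analogue used by the 2-hop ablation
PATH_ADJACENCY_3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)

#: feature dimensions (labels excluded)
N_FEATURES = {3: 9, 2: 4}


def enumerate_khop_paths(
    g: MoleculeGraph, hops: int = 3, dedupe_reversed: bool = False
) -> list[tuple[int, ...]]:
    """All directed simple paths with ``hops`` edges, lexicographically sorted.

    A chain A-B-C-D is reported twice, once per direction, matching the
    per-start-node accounting of the path enumeration (each atom contributes
    the paths that start at it).  ``dedupe_reversed=True`` keeps only the
    lexicographically smaller direction.
    """
    if hops < 1:
        raise ValueError("hops must be >= 1")
    nbrs = g.neighbor_lists()
    paths: list[tuple[int, ...]] = []

    def extend(path: list[int], used: set[int]):
        if len(path) == hops + 1:
            paths.append(tuple(path))
            return
        for w in nbrs[path[-1]]:
            if w not in used:
                path.append(w)
                used.add(w)
                extend(path, used)
                path.pop()
                used.remove(w)

    for start in range(g.n_atoms):
        extend([start], {start})
    if dedupe_reversed:
        paths = [p for p in paths if p <= p[::-1]]
    paths.sort()
    return paths


@dataclass(frozen=True)
class PathTensorSet:
    """The matrix chain for one k-hop path (4x4 for 3 hops, 3x3 for 2)."""

    path: tuple[int, ...]
    d: np.ndarray
    a: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    a3: np.ndarray | None  # None for 2-hop paths


def _offdiag_divide(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise division of off-diagonal entries; diagonal forced to 0."""
    out = num / den
    np.fill_diagonal(out, 0.0)
    return out


def build_path_tensors(g: MoleculeGraph, path: tuple[int, ...]) -> PathTensorSet:
    """Distance matrix and the A -> A1 -> A2 -> A3 similarity chain for a path.

    Works for 3-hop (4 atoms) and 2-hop (3 atoms) paths; for 2-hop paths the
    chain stops at A2 and ``a3`` is ``None``.
    """
    k = len(path)
    if k not in (3, 4):
        raise ValueError("paths must have 3 or 4 atoms")
    xyz = g.coords[list(path)]
    diff = xyz[:, None, :] - xyz[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    a = np.exp(-d)
    adj = PATH_ADJACENCY_4 if k == 4 else PATH_ADJACENCY_3
    a1 = a * adj
    a2 = _offdiag_divide(a1 @ a1, a)
    a3 = _offdiag_divide(a2 @ a1, a) if k == 4 else None
    return PathTensorSet(tuple(path), d, a, a1, a2, a3)


def continuous_features(t: PathTensorSet) -> np.ndarray:
    """The continuous feature vector of a path tensor set.

    3-hop: 9 entries — exp(-d) for AB, BC, CD, AC, BD, AD, then (A2)_AC,
    (A2)_BD and (A3)_AD + (A3)_DA.  2-hop: 4 entries — exp(-d) for AB, BC,
    AC, then (A2)_AC.
    """
    a = t.a
    if t.a3 is not None:
        return np.array(
            [
                a[0, 1], a[1, 2], a[2, 3], a[0, 2], a[1, 3], a[0, 3],
                t.a2[0, 2], t.a2[1, 3],
                t.a3[0, 3] + t.a3[3, 0],
            ]
        )
    return np.array([a[0, 1], a[1, 2], a[0, 2], t.a2[0, 2]])


@dataclass(frozen=True)
class CMotifFeature:
    """13-entry chain-motif feature: 4 ordered labels + 9 continuous values."""

    label4: tuple[str, ...]
    dist6: tuple[float, ...]
    angle2: tuple[float, float]
    torsion1: float

    @property
    def vector(self) -> np.ndarray:
        """The 9 continuous entries as an array."""
        return np.array([*self.dist6, *self.angle2, self.torsion1])

    @property
    def label_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(self.label4))


def cmotif_feature(g: MoleculeGraph, path: tuple[int, ...]) -> CMotifFeature:
    """Featurize one 3-hop path (chain motif) of a molecule."""
    if len(path) != 4:
        raise ValueError("a chain motif has exactly 4 atoms")
    t = build_path_tensors(g, path)
    f = continuous_features(t)
    return CMotifFeature(
        label4=tuple(g.labels[i] for i in path),
        dist6=tuple(f[:6]),
        angle2=(f[6], f[7]),
        torsion1=f[8],
    )


def twohop_feature(
    g: MoleculeGraph, path: tuple[int, int, int]
) -> tuple[tuple[str, ...], np.ndarray]:
    """Labels and 4 continuous features of a 2-hop path A-B-C (ablation)."""
    if len(path) != 3:
        raise ValueError("a 2-hop path has exactly 3 atoms")
    t = build_path_tensors(g, path)
    return tuple(g.labels[i] for i in path), continuous_features(t)


def node_feature_map(
    g: MoleculeGraph, hops: int = 3, dedupe_reversed: bool = False
) -> list[dict[tuple[str, ...], list[np.ndarray]]]:
    """Per-node map: ordered label tuple of each k-hop path starting there -> features.

    Entry ``k`` of the returned list covers node ``k``; each key is the ordered
    atom-label tuple of a path starting at ``k`` and holds the list of that
    path's continuous feature vectors (several paths may share a key).
    Nodes without k-hop paths get an empty dict.
    """
    if hops not in (2, 3):
        raise ValueError("only 2- and 3-hop features are supported")
    out: list[dict[tuple[str, ...], list[np.ndarray]]] = [
        {} for _ in range(g.n_atoms)
    ]
    for path in enumerate_khop_paths(g, hops, dedupe_reversed=dedupe_reversed):
        t = build_path_tensors(g, path)
        key = tuple(g.labels[i] for i in path)
        out[path[0]].setdefault(key, []).append(continuous_features(t))
    return out
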