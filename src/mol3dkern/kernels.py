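"""The four molecular graph kernels, as scikit-learn style estimators.

Every kernel has the GraphHopper shape ``K(G, G') = sum w(v, v') k_n(v, v')``
with the hop weights of :mod:`mol3dkern.hopper`; they differ in which graph
the weights are computed on and in the node kernel:

``ghk2d``
    Baseline GraphHopper on the molecular graph with a Dirac kernel on atom
    labels.  Uses no coordinates.
``cmgk``
    Chain-motif graph kernel: GraphHopper on the derived c-motif graph, node
    kernel = Dirac on the motif label multiset x linear kernel on the 9
    continuous 3D features.
``3dghk``
    3D GraphHopper: weights on the molecular graph, node kernel = Dirac on
    atom labels x a 3-hop neighborhood kernel that sums the linear kernel
    over pairs of 3-hop paths with identical ordered label tuples.
``3dghk_2hop``
    Ablation of ``3dghk`` with 2-hop paths (3 labels, 3 distances, 1 angle).

Estimators follow the sklearn transformer protocol: ``fit(X)`` stores the
reference molecules (precomputing per-molecule profiles), ``transform(Y)``
returns the ``len(Y) x len(X)`` kernel matrix, and ``fit_transform(X)`` the
square Gram matrix, so they compose directly with
``sklearn.svm.SVC(kernel="precomputed")`` and sklearn model selection.

Since ``w(v, v') = <M(v), M(v')>`` is an inner product and each node kernel
is a product of Dirac and linear kernels, every kernel here is positive
semidefinite by construction; the Gram invariants (symmetry, PSD up to
floating point) are asserted in the test suite rather than at run time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import hopper
from .cmotif import build_cmotif_graph
from .hopfeatures import node_feature_map
from .molio import MoleculeGraph

__all__ = [
    "KernelConfig",
    "GramMatrix",
    "MolecularGraphKernel",
    "GraphHopper2DKernel",
    "GraphHopper3DKernel",
    "GraphHopper3DTwoHopKernel",
    "ChainMotifKernel",
    "KERNELS",
    "make_kernel",
    "gram",
    "knc_node_kernel",
    "kn3d_node_kernel",
    "cmgk",
    "ghk3d",
    "ghk2d",
    "write_gram_tsv",
    "read_gram_tsv",
]


# ---------------------------------------------------------------------------
# Node kernels (reference, per-pair form)
# ---------------------------------------------------------------------------


def knc_node_kernel(fi, fj, label_match: str = "multiset") -> float:
    """c-motif node kernel: Dirac on labels x linear kernel on 9 features.

    ``label_match="multiset"`` (default) gates on equal sorted label
    multisets; ``"ordered"`` on the ordered 4-tuples.
    """
    if label_match == "multiset":
        if fi.label_multiset != fj.label_multiset:
            return 0.0
    elif label_match == "ordered":
        if fi.label4 != fj.label4:
            return 0.0
    else:
        raise ValueError(f"unknown label_match {label_match!r}")
    return float(fi.vector @ fj.vector)


def kn3d_node_kernel(
    label_v: str,
    label_v2: str,
    paths_v: dict[tuple[str, ...], list[np.ndarray]],
    paths_v2: dict[tuple[str, ...], list[np.ndarray]],
) -> float:
    """3D node kernel: Dirac on the atom labels x 3-hop neighborhood kernel.

    The neighborhood kernel sums, over every pair of k-hop paths whose
    ordered label tuples match, the linear kernel of their continuous
    features.  Nodes without paths give 0 (empty sum).
    """
    if label_v != label_v2:
        return 0.0
    total = 0.0
    for key, feats in paths_v.items():
        other = paths_v2.get(key)
        if not other:
            continue
        for f in feats:
            for f2 in other:
                total += float(f @ f2)
    return total


# ---------------------------------------------------------------------------
# Configuration and Gram container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KernelConfig:
    """Bundle of the switches shared by the kernel CLI and estimators."""

    kernel_name: str = "3dghk"
    normalize: bool = False
    include_trivial_paths: bool = False
    dedupe_reversed: bool = False
    hydrogen_policy: str = "strip"
    motif_label_match: str = "multiset"

    def __post_init__(self):
        if canonical_kernel_name(self.kernel_name) not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel_name!r}")


@dataclass
class GramMatrix:
    """Symmetric kernel matrix with the molecule names and config that made it."""

    values: np.ndarray
    names: list[str]
    config: KernelConfig

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError("Gram matrix shape must match the name list")

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.names)}
        return np.array([pos[n] for n in names], dtype=int)

    def submatrix(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        return self.values[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


class MolecularGraphKernel(TransformerMixin, BaseEstimator):
    """Base class: precomputed-kernel transformer over molecule lists.

    Subclasses implement ``_profile`` (per-molecule precomputation) and
    ``_pair`` (kernel value from two profiles).
    """

    kernel_name: str = ""

    def __init__(
        self,
        normalize: bool = False,
        include_trivial_paths: bool = False,
        dedupe_reversed: bool = False,
        n_jobs: int | None = None,
    ):
        self.normalize = normalize
        self.include_trivial_paths = include_trivial_paths
        self.dedupe_reversed = dedupe_reversed
        self.n_jobs = n_jobs

    # subclass hooks -------------------------------------------------------

    def _profile(self, g: MoleculeGraph):
        raise NotImplementedError

    def _pair(self, p1, p2) -> float:
        raise NotImplementedError

    # sklearn protocol -----------------------------------------------------

    @staticmethod
    def _validate(X) -> list[MoleculeGraph]:
        mols = list(X)
        for g in mols:
            if not isinstance(g, MoleculeGraph):
                raise TypeError(
                    f"expected MoleculeGraph inputs, got {type(g).__name__}"
                )
        return mols

    def _profiles(self, mols: list[MoleculeGraph]):
        if self.n_jobs not in (None, 1):
            from joblib import Parallel, delayed

            return Parallel(n_jobs=self.n_jobs)(
                delayed(self._profile)(g) for g in mols
            )
        return [self._profile(g) for g in mols]

    def fit(self, X, y=None):
        mols = self._validate(X)
        self.X_fit_ = mols
        self.names_ = [g.name for g in mols]
        self.profiles_ = self._profiles(mols)
        return self

    def _check_value(self, k: float, n1: str, n2: str) -> float:
        if not np.isfinite(k):
            raise FloatingPointError(
                f"non-finite kernel value between {n1!r} and {n2!r}"
            )
        return k

    def _self_values(self, mols, profiles) -> np.ndarray:
        return np.array(
            [
                self._check_value(self._pair(p, p), g.name, g.name)
                for g, p in zip(mols, profiles)
            ]
        )

    @staticmethod
    def _cosine_normalize(k: np.ndarray, d_row: np.ndarray, d_col: np.ndarray):
        denom = np.sqrt(np.outer(d_row, d_col))
        out = np.zeros_like(k)
        np.divide(k, denom, out=out, where=denom > 0)
        return out

    def transform(self, X) -> np.ndarray:
        """Kernel matrix between ``X`` (rows) and the fitted molecules (columns)."""
        if not hasattr(self, "profiles_"):
            raise RuntimeError("kernel is not fitted")
        mols = self._validate(X)
        profs = self._profiles(mols)
        k = np.empty((len(mols), len(self.X_fit_)))
        for i, pi in enumerate(profs):
            for j, pj in enumerate(self.profiles_):
                k[i, j] = self._check_value(
                    self._pair(pi, pj), mols[i].name, self.names_[j]
                )
        if self.normalize:
            k = self._cosine_normalize(
                k,
                self._self_values(mols, profs),
                self._self_values(self.X_fit_, self.profiles_),
            )
        return k

    def fit_transform(self, X, y=None) -> np.ndarray:
        """Square Gram matrix over ``X``; each unordered pair evaluated once."""
        self.fit(X)
        n = len(self.X_fit_)
        k = np.empty((n, n))
        for i in range(n):
            for j in range(i, n):
                k[i, j] = k[j, i] = self._check_value(
                    self._pair(self.profiles_[i], self.profiles_[j]),
                    self.names_[i],
                    self.names_[j],
                )
        if self.normalize:
            d = k.diagonal().copy()
            k = self._cosine_normalize(k, d, d)
        return k

    def gram(self, X) -> GramMatrix:
        """Convenience: fit_transform wrapped in a :class:`GramMatrix`."""
        values = self.fit_transform(X)
        cfg = KernelConfig(
            kernel_name=self.kernel_name,
            normalize=self.normalize,
            include_trivial_paths=self.include_trivial_paths,
            dedupe_reversed=self.dedupe_reversed,
            motif_label_match=getattr(self, "motif_label_match", "multiset"),
        )
        return GramMatrix(values, list(self.names_), cfg)


def _group_by(values) -> dict:
    groups: dict = {}
    for i, v in enumerate(values):
        groups.setdefault(v, []).append(i)
    return groups


class GraphHopper2DKernel(MolecularGraphKernel):
    """Baseline GraphHopper kernel with a Dirac kernel on atom labels."""

    kernel_name = "ghk2d"

    def _profile(self, g: MoleculeGraph):
        m = hopper.occurrence_matrices(
            g, include_trivial=self.include_trivial_paths
        )
        return g.labels, m

    def _pair(self, p1, p2) -> float:
        labels1, m1 = p1
        labels2, m2 = p2
        w = hopper._cropped_inner(m1, m2)
        g2 = _group_by(labels2)
        total = 0.0
        for lab, idx1 in _group_by(labels1).items():
            idx2 = g2.get(lab)
            if idx2:
                total += w[np.ix_(idx1, idx2)].sum()
        return float(total)


class _Hop3DBase(MolecularGraphKernel):
    """Shared machinery of the 3-hop kernel and its 2-hop ablation."""

    hops = 3

    def _profile(self, g: MoleculeGraph):
        m = hopper.occurrence_matrices(
            g, include_trivial=self.include_trivial_paths
        )
        fmap = node_feature_map(
            g, hops=self.hops, dedupe_reversed=self.dedupe_reversed
        )
        # the linear kernel over path pairs factorizes per label key:
        # sum_{p, p'} <f_p, f_p'> = <sum_p f_p, sum_p' f_p'>
        sums = [
            {key: np.sum(feats, axis=0) for key, feats in node_map.items()}
            for node_map in fmap
        ]
        return g.labels, m, sums

    def _pair(self, p1, p2) -> float:
        labels1, m1, sums1 = p1
        labels2, m2, sums2 = p2
        w = hopper._cropped_inner(m1, m2)
        kn = np.zeros_like(w)
        for i, li in enumerate(labels1):
            si = sums1[i]
            if not si:
                continue
            for j, lj in enumerate(labels2):
                if li != lj:
                    continue
                sj = sums2[j]
                if not sj:
                    continue
                acc = 0.0
                for key, vec in si.items():
                    other = sj.get(key)
                    if other is not None:
                        acc += float(vec @ other)
                kn[i, j] = acc
        return hopper.weighted_kernel_sum(w, kn)


class GraphHopper3DKernel(_Hop3DBase):
    """3D GraphHopper kernel (3-hop neighborhood features)."""

    kernel_name = "3dghk"
    hops = 3


class GraphHopper3DTwoHopKernel(_Hop3DBase):
    """Ablation: 3D GraphHopper with 2-hop features (3 labels, 3 distances, 1 angle)."""

    kernel_name = "3dghk_2hop"
    hops = 2


class ChainMotifKernel(MolecularGraphKernel):
    """Chain-motif graph kernel: GraphHopper on the c-motif graph."""

    kernel_name = "cmgk"

    def __init__(
        self,
        normalize: bool = False,
        include_trivial_paths: bool = False,
        dedupe_reversed: bool = False,
        motif_label_match: str = "multiset",
        n_jobs: int | None = None,
    ):
        super().__init__(
            normalize=normalize,
            include_trivial_paths=include_trivial_paths,
            dedupe_reversed=dedupe_reversed,
            n_jobs=n_jobs,
        )
        self.motif_label_match = motif_label_match

    def _profile(self, g: MoleculeGraph):
        c = build_cmotif_graph(g, dedupe_reversed=self.dedupe_reversed)
        m = hopper.occurrence_matrices(
            c, include_trivial=self.include_trivial_paths
        )
        if self.motif_label_match == "multiset":
            keys = [f.label_multiset for f in c.features]
        elif self.motif_label_match == "ordered":
            keys = [f.label4 for f in c.features]
        else:
            raise ValueError(f"unknown motif_label_match {self.motif_label_match!r}")
        feats = (
            np.array([f.vector for f in c.features])
            if c.features
            else np.zeros((0, 9))
        )
        return keys, feats, m

    def _pair(self, p1, p2) -> float:
        keys1, f1, m1 = p1
        keys2, f2, m2 = p2
        if not keys1 or not keys2:
            return 0.0
        w = hopper._cropped_inner(m1, m2)
        g2 = _group_by(keys2)
        total = 0.0
        for key, idx1 in _group_by(keys1).items():
            idx2 = g2.get(key)
            if not idx2:
                continue
            total += (w[np.ix_(idx1, idx2)] * (f1[idx1] @ f2[idx2].T)).sum()
        return float(total)


KERNELS = {
    "ghk2d": GraphHopper2DKernel,
    "3dghk": GraphHopper3DKernel,
    "3dghk_2hop": GraphHopper3DTwoHopKernel,
    "cmgk": ChainMotifKernel,
}


def canonical_kernel_name(name: str) -> str:
    return name.replace("-", "_").lower()


def make_kernel(config: KernelConfig, n_jobs: int | None = None) -> MolecularGraphKernel:
    """Instantiate the estimator described by a :class:`KernelConfig`."""
    cls = KERNELS[canonical_kernel_name(config.kernel_name)]
    kwargs = dict(
        normalize=config.normalize,
        include_trivial_paths=config.include_trivial_paths,
        dedupe_reversed=config.dedupe_reversed,
        n_jobs=n_jobs,
    )
    if cls is ChainMotifKernel:
        kwargs["motif_label_match"] = config.motif_label_match
    return cls(**kwargs)


def gram(
    molecules: Sequence[MoleculeGraph],
    config: KernelConfig | str = "3dghk",
    n_jobs: int | None = None,
) -> GramMatrix:
    """Pairwise Gram matrix over a molecule list (config or kernel name)."""
    if isinstance(config, str):
        config = KernelConfig(kernel_name=config)
    if len(molecules) < 1:
        raise ValueError("need at least one molecule")
    est = make_kernel(config, n_jobs=n_jobs)
    values = est.fit_transform(list(molecules))
    return GramMatrix(values, [g.name for g in molecules], config)


# thin functional wrappers -------------------------------------------------


def _pairwise(est: MolecularGraphKernel, g1: MoleculeGraph, g2: MoleculeGraph) -> float:
    return float(est.fit([g1]).transform([g2])[0, 0])


def cmgk(g1: MoleculeGraph, g2: MoleculeGraph, cfg: KernelConfig | None = None) -> float:
    cfg = cfg or KernelConfig(kernel_name="cmgk")
    return _pairwise(make_kernel(cfg), g1, g2)


def ghk3d(g1: MoleculeGraph, g2: MoleculeGraph, cfg: KernelConfig | None = None) -> float:
    cfg = cfg or KernelConfig(kernel_name="3dghk")
    return _pairwise(make_kernel(cfg), g1, g2)


def ghk2d(g1: MoleculeGraph, g2: MoleculeGraph, cfg: KernelConfig | None = None) -> float:
    cfg = cfg or KernelConfig(kernel_name="ghk2d")
    return _pairwise(make_kernel(cfg), g1, g2)


# ---------------------------------------------------------------------------
# Gram matrix text I/O
# ---------------------------------------------------------------------------


def write_gram_tsv(gm: GramMatrix, path) -> None:
    """Tab-delimited Gram matrix: first row/column are molecule names."""
    with open(path, "w") as fh:
        fh.write("\t".join(["#name", *gm.names]) + "\n")
        for name, row in zip(gm.names, gm.values):
            fh.write(name + "\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")


def read_gram_tsv(path, config: KernelConfig | None = None) -> GramMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        names = header[1:]
        rows = []
        row_names = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_names.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if row_names != names:
        raise ValueError("Gram file row and column names disagree")
    return GramMatrix(
        np.array(rows), names, config or KernelConfig(kernel_name="3dghk")
    )
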