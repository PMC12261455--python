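"""Virtual-screening evaluation harness.

Mirrors the standard ligand-based screening protocol: balance the classes by
subsampling the inactives down to the active count, split 70/15/15 into
train/validation/test (stratified), train a precomputed-kernel SVM with the
penalty ``C`` chosen on validation accuracy from the grid
{0.001, 0.01, 0.1, 1, 10, 100, 1000}, and report the test accuracy.  Repeats
(default 20) re-balance and re-split with fresh derived seeds; the summary is
mean +/- sample standard deviation (n-1 denominator).  Paired kernels are
compared with a two-sided Wilcoxon signed-rank test on per-dataset
accuracies.

The SVM and the signed-rank test are standard components
(``sklearn.svm.SVC(kernel="precomputed")``, ``scipy.stats.wilcoxon``); the
contribution under test is always the kernel, never the classifier.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .kernels import GramMatrix

__all__ = [
    "DEFAULT_C_GRID",
    "SplitPlan",
    "RunResult",
    "balance_classes",
    "make_split",
    "evaluate_kernel",
    "compare_kernels",
]

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


def balance_classes(
    labels: dict[str, str], seed, active: str = "active", inactive: str = "inactive"
) -> list[str]:
    """Balanced subsample: keep all actives, draw an equal number of inactives.

    Sampling is without replacement and deterministic given ``seed``; the
    returned name list preserves the input ordering.
    """
    actives = [n for n, lab in labels.items() if lab == active]
    inactives = [n for n, lab in labels.items() if lab == inactive]
    if not actives or not inactives:
        raise ValueError("both classes must be present to balance")
    if len(inactives) < len(actives):
        raise ValueError(
            f"cannot subsample {len(actives)} inactives from {len(inactives)}"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(len(inactives), size=len(actives), replace=False))
    keep = set(actives) | {inactives[i] for i in sorted(chosen)}
    return [n for n in labels if n in keep]


@dataclass(frozen=True)
class SplitPlan:
    """Stratified 70/15/15 partition of dataset indices."""

    seed: int
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float] = SPLIT_FRACTIONS


def make_split(y, rng) -> SplitPlan:
    """Stratified train/val/test split (70/15/15) of label array ``y``.

    Within each class the indices are shuffled and cut proportionally, so the
    class balance of each split is preserved to within one molecule.
    """
    y = np.asarray(y)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n = len(idx)
        n_tr = int(round(SPLIT_FRACTIONS[0] * n))
        n_va = int(round(SPLIT_FRACTIONS[1] * n))
        train.extend(idx[:n_tr])
        val.extend(idx[n_tr : n_tr + n_va])
        test.extend(idx[n_tr + n_va :])
    return SplitPlan(
        seed=-1,
        train=np.sort(np.array(train, dtype=int)),
        val=np.sort(np.array(val, dtype=int)),
        test=np.sort(np.array(test, dtype=int)),
    )


@dataclass
class RunResult:
    """Per-repeat test accuracies of one kernel on one dataset."""

    accuracies: list[float]
    chosen_c: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        acc = np.asarray(self.accuracies, dtype=float)
        self.mean = float(acc.mean())
        # sample SD (n-1 denominator); 0 for a single repeat
        self.sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "accuracies": list(map(float, self.accuracies)),
            "chosen_c": list(map(float, self.chosen_c)),
            "mean": self.mean,
            "sd": self.sd,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _one_repeat(gm: GramMatrix, labels, c_grid, rng) -> tuple[float, float]:
    names = balance_classes(labels, rng.integers(2**31))
    idx = gm.index_of(names)
    y = np.array([labels[n] for n in names])
    for attempt in range(20):
        plan = make_split(y, rng)
        if len(np.unique(y[plan.train])) == 2 and len(plan.val) and len(plan.test):
            break
        logger.warning("degenerate split (attempt %d), resampling", attempt + 1)
    else:  # pragma: no cover - needs a pathological dataset
        raise RuntimeError("could not draw a split with both classes in train")
    k_all = gm.submatrix(idx, idx)
    k_tr = k_all[np.ix_(plan.train, plan.train)]
    best_c, best_acc, best_model = None, -1.0, None
    for c in c_grid:  # ascending grid; strict improvement -> smallest C wins ties
        model = SVC(kernel="precomputed", C=c)
        model.fit(k_tr, y[plan.train])
        acc = model.score(k_all[np.ix_(plan.val, plan.train)], y[plan.val])
        if acc > best_acc:
            best_c, best_acc, best_model = c, acc, model
    test_acc = best_model.score(k_all[np.ix_(plan.test, plan.train)], y[plan.test])
    return float(test_acc), float(best_c)


def evaluate_kernel(
    gm: GramMatrix,
    labels: dict[str, str],
    repeats: int = 20,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
    rebalance: bool = True,
) -> RunResult:
    """Repeated balanced-split SVM evaluation of a precomputed Gram matrix.

    Each repeat draws a fresh balanced subsample (unless ``rebalance=False``,
    which freezes the first one) and a fresh stratified split; ``C`` is picked
    on validation accuracy (ties to the smallest ``C``), the model is scored
    once on the untouched test split.  Deterministic given ``seed``.
    """
    missing = [n for n in labels if n not in gm.names]
    if missing:
        raise ValueError(f"Gram matrix is missing labeled molecules: {missing[:5]}")
    c_grid = sorted(float(c) for c in c_grid)
    if any(c <= 0 for c in c_grid):
        raise ValueError("C grid must be positive")
    ss = np.random.SeedSequence(seed)
    accs, cs = [], []
    frozen_rng = None
    if not rebalance:
        frozen_rng = np.random.default_rng(ss.spawn(1)[0])
        frozen_names = balance_classes(labels, frozen_rng.integers(2**31))
        labels = {n: labels[n] for n in frozen_names}
    for child in ss.spawn(repeats):
        rng = np.random.default_rng(child)
        acc, c = _one_repeat(gm, labels, c_grid, rng)
        accs.append(acc)
        cs.append(c)
    return RunResult(accs, cs)


def compare_kernels(results_a, results_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-dataset accuracies.

    Zero-difference pairs are dropped (the classical convention); if every
    pair ties the comparison is vacuous and p = 1 is returned with a warning.
    Fewer than 5 pairs is refused — the test has no resolution there.
    """
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired results must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 paired datasets for the signed-rank test")
    if np.all(a == b):
        warnings.warn("all paired accuracies tie; signed-rank test is vacuous")
        return 1.0
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return float(res.pvalue)
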