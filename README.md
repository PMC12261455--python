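# mol3dkern

3D molecular graph kernels for ligand-based virtual screening.

Most graph kernels see a molecule as a labeled 2D graph and throw away its
geometry. `mol3dkern` implements two kernels that keep the geometry while
remaining exactly invariant to translation, rotation and mirror reflection,
because every 3D feature is built from interatomic distances alone:

- **c-MGK** — the *chain-motif graph kernel*. Every directed simple 3-hop
  path A–B–C–D (a *c-motif*) becomes a node of a derived *c-motif graph*
  (edges join motifs sharing an atom), carrying 4 atom labels and 9
  continuous features; the GraphHopper kernel is then evaluated on these
  derived graphs.
- **3DGHK** — the *3D GraphHopper kernel*. The GraphHopper weights stay on
  the molecular graph and the node kernel compares the 3-hop path features
  anchored at each atom, which avoids building the (possibly much larger)
  c-motif graph.

Alongside them the package provides the classic 2D GraphHopper baseline
(`ghk2d`, Dirac kernel on atom labels) and a 2-hop ablation of 3DGHK
(`3dghk_2hop`: 3 labels, 3 distances, 1 angle).

All kernels share the GraphHopper form

    K(G, G') = Σ_{v∈V} Σ_{v'∈V'} w(v, v') · k_n(v, v'),
    w(v, v') = ⟨M(v), M(v')⟩,

where `M(v)` is a δ×δ table counting how often node `v` occupies position
`i` of a shortest path of discrete length `j` (lengths count nodes; δ is the
diameter in node count), over **all** shortest paths between all ordered
node pairs.

The per-path 3D features come from a small tensor pipeline: with
`A = exp(−d)` the 4×4 distance-similarity matrix of a path and `Adj` its
chain adjacency,

    A¹ = A ⊙ Adj,   A² = (A¹)² ⊘ A,   A³ = (A²·A¹) ⊘ A

(`⊘` divides off-diagonal entries and zeroes the diagonal), giving closed
forms such as `(A²)_AC = exp(−(d_AB + d_BC − d_AC))` — a bond-angle
similarity that equals 1 exactly when A, B, C are collinear — and
`(A³)_AD`, a torsion-angle surrogate. The exact distance-only torsion
cosine (the `U/L` form from the laws of sine and cosine) lives in
`mol3dkern.geometry` together with an independent cross-product oracle.

Gram matrices are positive semidefinite by construction and feed directly
into `sklearn.svm.SVC(kernel="precomputed")`; the estimators follow the
scikit-learn `fit`/`transform` protocol.

## Worked example

```python
import numpy as np
from mol3dkern import GraphHopper3DKernel, make_chain_fixture, gram, sample_molecule
from mol3dkern.diagnostics import random_rotation

# a butane-like collinear 4-carbon chain, 1.53 Å bonds
butane = make_chain_fixture(4, bond_length=1.53, name="butane-like")
est = GraphHopper3DKernel()
print(est.fit_transform([butane])[0, 0])      # 43718.49458582926

# rigid motion leaves the kernel unchanged
rng = np.random.default_rng(0)
moved = butane.transformed(random_rotation(rng), rng.normal(size=3) * 5)
print(est.transform([moved])[0, 0])           # 43718.494585829234

# Gram matrix over a synthetic corpus, chain-motif kernel
mols = [sample_molecule(s, 12, ring_prob=0.02, name=f"m{s}") for s in range(6)]
gm = gram(mols, "cmgk")
print(np.linalg.eigvalsh(gm.values).min() / np.trace(gm.values))
# 1.17378840611519e-05   (>= 0 up to floating point: the Gram is PSD)
```

The self-kernel value grows with molecule size (it is an unnormalized sum
over path pairs); pass `normalize=True` for cosine-normalized Gram matrices
with unit diagonal.

## Command line

```bash
mol3dkern gram --kernel 3dghk --input molecules.sdf --out gram.tsv
mol3dkern classify --gram gram.tsv --labels labels.tsv --repeats 20 --seed 1 --out results.json
mol3dkern features --input molecules.sdf --out features.tsv
```

`classify` runs the screening protocol: balance classes by subsampling
inactives to the active count, stratified 70/15/15 train/validation/test
split, SVM penalty C picked on validation accuracy from
{0.001, …, 1000}, test accuracy reported as mean ± SD over repeats.
`mol3dkern.screen.compare_kernels` applies the paired two-sided Wilcoxon
signed-rank test to per-dataset accuracies.

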