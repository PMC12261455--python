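# Methods

## Molecular graphs

A molecule is a labeled undirected graph `G = (V, E)` with an element symbol
`l(v)` and a 3D position (Å) per atom. Bond orders, charges and aromaticity
are read but discarded: the kernels use only labels, connectivity and
interatomic distances. Hydrogens are stripped by default (heavy-atom graphs
are the norm for molecular graph kernels and keep the maximum degree small);
`hydrogen_policy="keep"` retains them. Coordinates are taken verbatim from
the SDF record — no re-embedding or sanitization beyond finiteness checks —
and records flagged 2D (all-zero z column) are kept but reported with a
warning, since their torsion features are degenerate.

## GraphHopper weights

For a node `v`, `M(v)` is the δ×δ integer matrix whose `(i, j)` entry counts
how often `v` appears at position `i` of a shortest path of discrete length
`j` (node count; an edge has length 2; δ is the diameter in node count,
taken as the maximum over the two graphs being compared — zero padding makes
this choice immaterial, which the tests assert). The hop weight is
`w(v, v') = ⟨M(v), M(v')⟩`.

Two conventions were genuinely open and are surfaced as flags rather than
guessed silently:

- **All shortest paths** between each ordered pair are counted, not one per
  pair from an arbitrary BFS tree. This is the deterministic, tie-free
  reading; on the 4-cycle, opposite nodes contribute 2 paths per direction.
- **Trivial single-node paths** (length 1) are excluded by default — they
  carry no hop structure — and restored with `include_trivial_paths=True`
  (adds 1 to entry (1,1) of every `M(v)`).

The implementation never enumerates paths. With `D` the BFS distance matrix
and `σ` the all-pairs shortest-path counts (both computed by level-wise
matrix recurrences), node `v` lies on a shortest s→w path at position
`D(s,v)+1` exactly when `D(s,v) + D(v,w) = D(s,w)`, contributing
`σ(s,v)·σ(v,w)` paths. A literal enumeration oracle (networkx
`all_shortest_paths`) is kept for graphs ≤ 10 nodes; the test suite and the
reproduction script verify exact agreement on hundreds of random graph
pairs under both trivial-path conventions.

## Path features

Directed simple k-hop paths are enumerated per start node (a chain A–B–C–D
appears once per direction; `dedupe_reversed` collapses them). For each
3-hop path the 4×4 distance matrix `d` yields `A = exp(−d)` and the chain

    A¹ = A ⊙ Adj,  A² = (A¹)² ⊘ A,  A³ = (A²·A¹) ⊘ A,

where `Adj` is the fixed 4-node chain adjacency and `⊘` divides off-diagonal
entries elementwise and zeroes the diagonal (self-interactions carry no
angle information). Closed forms, asserted to 1e−10 in the tests:

    (A²)_AC = exp{−(d_AB + d_BC − d_AC)}
    (A³)_AD = exp{−(d_AB + d_BC + d_CD − d_AC − d_AD)}
    (A³)_DA = exp{−(d_AB + d_BC + d_CD − d_BD − d_AD)}

The exponents are triangle-inequality defects: zero exactly at collinearity,
so these entries are bounded, monotone similarity surrogates for bond angle
and torsion. The exact distance-only torsion cosine is implemented in
`geometry` as `cos φ = U/L` with `L = 2·d_AB·sinθ₁·d_CD·sinθ₂` and `U` the
law-of-cosines expansion of `2[(a·d) − (a·u)(d·u)]` (`a`, `d` the terminal
bond vectors, `u` the unit B→C axis), validated against an independent
cross-product oracle to 1e−8 over 1000 random quadruples. The kernels use
the `A³` linear surrogate, not `cos φ`; the exact form documents what the
surrogate approximates.

Each 3-hop path contributes 9 continuous features: the six pairwise
similarities `exp(−d)` for AB, BC, CD, AC, BD, AD, the two angle entries
`(A²)_AC, (A²)_BD`, and the torsion entry `(A³)_AD + (A³)_DA` (summing both
orientations makes the feature direction-symmetric). The six distance
entries deliberately use the unmasked `A` rather than `A¹`, whose chain mask
would zero the AC, BD and AD similarities; the unmasked reading keeps all
six entries informative and lets c-MGK and 3DGHK share one featurizer. The
2-hop ablation applies the 3×3 analogue: 3 labels, 3 similarities, 1 angle
entry.

Paths are required to be simple (4 distinct atoms): a walk revisiting an
atom would put zeros off the diagonal of `d` and break the division step.
Coincident non-bonded atoms (distance 0 across a pair) are tolerated and
yield similarity 1.

## The two kernels

**c-MGK.** The c-motif graph has one node per directed 3-hop path and an
edge whenever two motifs share ≥ 1 atom (read literally; overlap size is
not weighted). GraphHopper weights are computed on this derived graph; the
node kernel is a Dirac gate on the motif label **multisets** times the
linear kernel of the 9 features. The multiset reading matches the
set-language used for this kernel; `motif_label_match="ordered"` switches
to ordered 4-tuples, the convention 3DGHK uses.

**3DGHK.** Weights stay on the molecular graph. The node kernel is a Dirac
gate on the two atom labels times a neighborhood kernel: the sum, over all
pairs of 3-hop paths starting at the two atoms whose **ordered** label
4-tuples agree, of the linear kernel of their features. (Atom identity is
meaningless across molecules, so "same atoms" is implemented as same
labels.) Because the inner kernel is linear, the double sum factorizes per
label key into a dot product of per-key feature sums; an unfactorized
brute-force evaluation is kept in the tests to pin the algebra. Atoms
without 3-hop neighborhoods contribute an empty sum (0) — common in very
small molecules, where the 2D weights then dominate.

Both kernels are sums of products of inner products, hence positive
semidefinite by construction; the suite additionally checks
`λ_min ≥ −1e−8 · trace` numerically on random corpora for all four kernels.
Cosine normalization (`K̂ = K/√(K_ii K_jj)`, 0/0 → 0) is off by default;
raw values grow with molecule size.

Distance-only features cannot distinguish a molecule from its mirror image:
enantiomers receive identical kernel values. This is asserted in the tests
as a documented property, not celebrated as a feature.

## Screening harness

`balance_classes` keeps all actives and subsamples inactives to match
(without replacement, seeded). Each repeat draws a fresh balanced subsample
and a stratified 70/15/15 split (stratification is a deliberate choice: an
unstratified 15% test set on small data can lose a class entirely), fits
`SVC(kernel="precomputed")` for each C in {0.001 … 1000}, picks C on
validation accuracy with ties going to the smallest C, and scores the test
split once. Summaries use the sample SD (n−1). Kernel comparisons use the
two-sided Wilcoxon signed-rank test on paired per-dataset accuracies
(zero differences dropped; < 5 pairs refused; all-tie input returns p = 1
with a warning).

## Synthetic data

The generator grows a uniform random recursive tree, placing each atom
1.5 Å from its parent in a random direction, then closes rings
independently per candidate pair. Corpus defaults target ~1.5 rings per
molecule — average degree slightly above 2, the small-organic regime — with
8–25 heavy atoms and a C/N/O-weighted alphabet. What this emulates:
realistic connectivity, degree and size distributions, and exact 3D
geometry for the distance features. What it does not: chemically valid
valences, realistic bond-length/angle distributions (directions are
uniform, not tetrahedral), conformational ensembles, or any
structure–activity relationship. Passing tests therefore establish the
*algebraic and statistical* correctness of the kernels and harness — oracle
agreement, PSD-ness, invariances, calibration of the evaluation — not
screening accuracy on real assay data, which depends on external datasets
outside this package's scope.

Two labeled toy tasks exercise the harness end to end: a family pair with
disjoint element alphabets (the 2D Gram is block diagonal, so accuracy must
reach 1.0) and a topology task (acyclic vs ring-rich, shared alphabet) used
to run the 3-hop/2-hop ablation. The ablation's accuracy ordering is
reported, never asserted — on tiny saturable tasks both variants can reach
ceiling.

## Numerical choices

- Cosines within 1e−9 of ±1 are clamped; farther outside raises (the
  distances are then inconsistent). Torsions with denominator < 1e−12 are
  returned as `None` ("undefined") rather than NaN so downstream code must
  choose a policy explicitly.
- Shortest-path counts are computed in float64 and converted to exact
  integers; counts stay far below 2^53 at these graph sizes.
- Degenerate inputs: empty molecules, single atoms, motif-free molecules
  (no 3-hop path) all yield well-defined results (empty Gram contributions,
  kernel value 0).
- Determinism: path enumeration and motif ordering are lexicographic; all
  randomness flows through seeded numpy generators, and repeated runs are
  bit-identical.
- Problem sizes in the validation script (1000 quadruples, 500 paths, 200
  graph pairs, 30-molecule corpora, 20×20 invariance grid) keep the full
  reproduction under a couple of minutes on one CPU while exercising every
  code path at the sizes the guarantees are stated for.

## Known limitations

- No chirality: distance-only features are reflection-invariant.
- k-hop features stop at k = 3; larger k grows the path tensor and the
  path count sharply.
- The c-motif graph can be much larger than the molecule for high-degree
  graphs (≈ n·T³ motifs), making c-MGK the slowest kernel here — consistent
  with its role as the expensive reference against which 3DGHK is the
  efficient variant.
- The SDF reader trusts the input geometry; it does not detect chemically
  impossible structures.
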