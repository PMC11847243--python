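# Methods

## Model and central quantities

All computations operate on simple undirected connected graphs with vertex
labels `0..n-1` (the package validates both properties; parsing accepts
arbitrary integer labels and remaps them).  The central primitive is the
per-edge closer-vertex partition: for `e = uv`, vertex `w` is assigned to
`n_u` if `d(w,u) < d(w,v)`, to `n_v` if the reverse strict inequality
holds, and to `n_0` otherwise.  Equidistant vertices are never tie-broken
into either side.  Cut counts are exact integers obtained by comparing the
two BFS distance rows of the endpoints; all distances come from per-vertex
BFS collected into a dense matrix (`inf` marks disconnected pairs, and
every index operation refuses disconnected input).

Index values are IEEE-754 doubles.  Edge sums are accumulated in sorted
`(min,max)` edge order so results are bit-reproducible on one platform; no
compensated summation is used because the operand counts are tiny (≤ a few
hundred edges at the documented enumeration caps).

## Index catalog and conventions

* `SDZ`, `Sz`, `AG2`, `RSz` — functions of the cut counts.
* `SDD`, `RM2` — functions of endpoint degrees; `SDE` — of eccentricities
  (eccentricities require `n ≥ 2`).
* `GSDD_f` — generic symmetric ratio sum for a strictly positive valuation
  `f(vertex, edge)`; `f = degree` recovers SDD, the per-edge closer counts
  recover SDZ, and a constant valuation gives exactly `2m`.
* `M1`/`M2` — per vertex `v`, the partial Hosoya polynomial
  `H_v(x) = Σ_k c_k x^k` counts vertices at each distance `k ≥ 1`; its
  complex roots are taken with multiplicity (companion-matrix eigenvalues
  via `numpy.roots`), including the zero root from the missing constant
  term.  `M1` sums `|root|`, `M2` sums `sqrt(|root|)` over all vertices.
  This all-roots convention is a deliberate, literal choice where the
  published description is underdetermined.  Empirically it reproduces the
  tabulated `M1` column for all 18 octane isomers to within print precision
  (the test suite asserts this), while no simple aggregate reproduces the
  tabulated `M2` (sum of root square-roots gives 38.20 on the n-octane
  skeleton versus 17.97 printed).  The octane module therefore treats the
  printed `M1`/`M2`/`M3` columns as fixture data and exposes
  `hosoya_convention_report()` so the discrepancy is visible rather than
  asserted away.

## Bound and identity catalog

Each checker evaluates both sides on the given graph, records the theorem's
hypotheses as applicability flags (never assuming them), and returns a
structured report with an equality verdict and the equality condition's
truth value.  Integer-valued comparisons are exact; floating comparisons
use an absolute tolerance of `1e-9`, and strict inequalities additionally
require the gap to exceed that tolerance.

Two catalog entries deviate knowingly from their published statements:

* **Unicyclic upper bound.**  The published closed-form expression for the
  unicyclic maximum contains a term `2(n²−2n+4)/(n−2)` that contradicts the
  per-edge values in its own derivation (at `n = 6` it evaluates to 31.6,
  while the extremal graph `C3(S_{n−2})` has SDZ exactly 26.1).  The
  checker uses the derivation-consistent value — the direct SDZ of the
  extremal graph, `(n−3)(n²−2n+2)/(n−1) + 2(n²−4n+5)/(n−2) + 2` — and
  records the published expression in the report notes for transparency.
  Exhaustive enumeration up to `n = 9` confirms the corrected bound and the
  uniqueness of the extremal graph.
* **Triangle-count upper bound.**  Its published hypothesis is a
  triangulated (maximal planar) graph, but the derivation uses only the
  triangle count `t(G)`, the order and the size.  The checker requires
  `t(G) ≥ 1` and flags every report `hypothesis_unverified` instead of
  testing planarity, which is out of scope.

The square-root lower bound `SDZ > (1/8)(√(32m+1) + 1)` is implemented in
the form the underlying `AG2` comparison chain proves; it is weaker than
the `2m` floor but checked independently because the chain
`AG2 ≥ √(SDZ+2m)/2` and `AG2 < SDZ` is itself a tested invariant
(the first is strict for `m ≥ 2`, with equality at `K2`).

## Enumeration

* **Trees** come from networkx's non-isomorphic tree generator, filtered by
  maximum degree, and ordered by a centroid-rooted AHU canonical string
  (for bicentroidal trees, the lexicographically smaller of the two rooted
  encodings).  The certificate doubles as the isomorphism key for the
  skeleton→IUPAC-name table.  Counts for `n ≤ 7` are cross-checked in the
  suite against an independent brute force over all Prüfer sequences with
  Weisfeiler–Lehman dedup; the `n = 8` values (23 trees, 18 with Δ ≤ 4)
  were frozen from the same oracle, which is too slow to run on every test
  invocation (~40 s).  The practical cap is `n ≤ 12`.
* **Unicyclic graphs** are generated as {free tree on `n` vertices + one
  non-edge} with isomorphism dedup (invariant-fingerprint bucketing, VF2
  within buckets).  Every unicyclic graph contains a spanning tree, so the
  construction is exhaustive; counts for `n ≤ 7` are verified against the
  connected `m = n` graphs of the networkx atlas.  Cap `n ≤ 9` (240
  classes), keeping enumeration well under a minute.
* **Exhaustive small-order property checks** use the networkx graph atlas
  (all 143 connected graphs on ≤ 6 vertices), plus seeded Erdős–Rényi
  graphs conditioned on connectivity for larger orders.

## Graph products

Join and corona are constructed directly with a documented block numbering;
Cartesian and lexicographic products delegate to networkx and are relabeled
by `(i,j) ↦ i·n2 + j`.  Besides the direct route (construct the product,
run the cut-count machinery), each product has a closed "case formula" for
SDZ derived from the per-case cut-count analysis of the product's edge
types; the two routes are cross-checked to `1e-9` in the tests, which is
the strongest internal-consistency check the construction affords.  One
correction was needed: in the corona analysis the within-`G1` cut counts
scale by `1 + n2` (each `G1` vertex carries itself plus its pendant copy),
not by `n2` as published — the ratios, and hence the theorem, are
unaffected.  `SDD(K1)` is defined as 0 (empty sum) so pendant coronas
`G ∘ K1` are expressible.  The lexicographic case formula assumes `n1 ≥ 2`
(with `n1 = 1` the product is just `G2`).

## Octane QSPR tables

The 18 octane isomer skeletons are regenerated as free trees on 8 vertices
with maximum degree 4 — standard alkane chemistry, and the generator's
defaults are exactly these study conditions.  The tabulated physicochemical
columns (acentric factor, entropy `S`, `M1`, `M2`, `M3`) ship as a
transcribed CSV fixture guarded by a sha256 checksum.  Each regenerated
skeleton is paired to its fixture row by the nearest `(SDZ, SDD, SDE)`
triple under an absolute tolerance of 0.01 — the print precision of the
source table, which mixes rounding and truncation (27.4857 prints as 27.48
but 44.8571 as 44.86).  The pairing must be a perfect bijection, and the
fixture's closest pair of row triples is far beyond the tolerance, so the
matching is well-posed and self-validating; row order is never assumed.
IUPAC names come from a built-in SMILES→name table (the restricted alkane
SMILES parser handles only the `{C,(,)}` dialect; rings and heteroatoms are
rejected) and serve as labels only.

Pearson correlations use the sample formula via pandas; the full 8×8
computed matrix (computed SDZ/SDD/SDE plus fixture property columns)
matches the published correlation table with a maximum absolute deviation
of 0.0075, and the test suite asserts every entry at 0.01.  Scatter data
are exported as CSV; no plotting is performed.

## Synthetic inputs: what they do and do not show

Random-graph checks use seeded Erdős–Rényi samples conditioned on
connectivity (n up to 25, edge probability 0.12–0.7, 500 graphs in the
acceptance-level property run).  They probe the inequality catalog across
densities but are not chemically meaningful molecules; the chemical claims
rest on the exhaustive octane enumeration, which is complete rather than
sampled.  Conversely, the octane benchmark involves only 18 trees on 8
vertices, so correlations carried by it say nothing about graphs far from
that family.

## Problem sizes and determinism

Defaults keep the full test suite around 15 s and the acceptance script a
few seconds on one CPU: exhaustive classes to `n = 6`, trees to `n = 9`,
unicyclic to `n = 8`, 200 Cartesian factor pairs with orders ≤ 8, 500
random graphs for the catalog.  All randomness flows through
`numpy.random.default_rng` seeded explicitly (the acceptance script derives
its stream from `--seed`), so every reported number is reproducible.

## Known limitations

* No planarity testing: the triangle-count bound's published hypothesis is
  recorded, not verified.
* The `M2`/`M3` conventions behind the fixture columns remain unidentified;
  they are inputs, not outputs, of this package.
* Isomorphism dedup at scale is out of scope; the enumeration caps (trees
  `n ≤ 12`, unicyclic `n ≤ 9`) are hard errors, not soft limits.
* Equality conditions for the join/lexicographic product bounds are tested
  as biconditionals only on the small exhaustive matrix; sufficiency is
  what the verifiers assert on random inputs.
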