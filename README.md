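# szind — the symmetric division Szeged index toolkit

`szind` computes the **symmetric division Szeged index** (SDZ) and its
companion distance-, degree- and eccentricity-based topological indices for
simple connected graphs, verifies the extremal bounds and graph-product
theorems these indices satisfy, and reproduces the octane-isomer QSPR
(quantitative structure–property relationship) correlation tables from
regenerated molecular skeletons.  It is aimed at chemical graph theorists
and cheminformaticians who want the index values, the inequality checks and
the octane benchmark available as a tested library and command-line tool.

## The index

For an edge `e = uv` of a connected graph `G` on `n` vertices, partition the
vertex set by proximity to the endpoints: `n_u(e)` vertices strictly closer
to `u`, `n_v(e)` strictly closer to `v`, and `n_0(e)` equidistant
(`n_u + n_v + n_0 = n`).  The symmetric division Szeged index is

```
SDZ(G) = Σ_{uv ∈ E(G)} ( n_u/n_v + n_v/n_u ).
```

It is the Szeged-type analogue of the symmetric division degree index
`SDD(G) = Σ (d(u)² + d(v)²)/(d(u)d(v))`; both arise from the generalized
form `GSDD_f(G) = Σ (f(u)/f(v) + f(v)/f(u))` for a positive valuation `f`.
Since every per-edge term is at least 2, `SDZ(G) ≥ 2m`, with equality
exactly on *distance-balanced* graphs (`n_u = n_v` on every edge).  The
package also implements the Szeged index `Sz`, the eccentric analogue
`SDE`, the second arithmetic-geometric index `AG2`, the reverse indices
`RSz` and `RM2`, and root aggregates `M1`/`M2` of the per-vertex partial
Hosoya polynomials.

Beyond single values, `szind` ships executable verifiers for:

* closed forms (star, bistar, complete graph, cycle, triangle with a
  pendant star — the unicyclic maximizer);
* a catalog of bounds and identities (the `2m ≤ SDZ ≤ m(n²−2n+2)/(n−1)`
  sandwich, the triangle-free `RSz ≤ RM2` comparison, the bipartite
  identity `SDZ = n²·RSz − 2m`, the triangle-count upper bound, and more),
  each reporting both sides, applicability and the equality condition;
* extremal structure by exhaustive enumeration: among trees the path
  minimizes and the star maximizes SDZ (the bistar `S_{1,n−3}` leads the
  non-stars); among unicyclic graphs the cycle minimizes and `C3(S_{n−2})`
  maximizes;
* the four graph products — join, corona, Cartesian, lexicographic — with
  their SDZ lower bounds, the exact Cartesian identity
  `SDZ(G1×G2) = n2·SDZ(G1) + n1·SDZ(G2)`, and equality conditions.

## Worked example

n-octane's carbon skeleton is the path on 8 vertices:

```
$ szind compute --graph path:8 --indices sdz,sdd,sde
n=8 m=7
SDZ   27.485714
SDD   15.000000
SDE   14.214286
```

`SDZ = 962/35 ≈ 27.486` is the smallest value among all 18 octane isomers —
long unbranched alkanes split every C–C bond most evenly, and low SDZ goes
with a high acentric factor (0.40 for n-octane).  The most branched isomer,
2,2,3,3-tetramethylbutane, tops the column at `SDZ = 44.857`.  The unicyclic
extremal graph, a triangle carrying three pendant leaves on one vertex:

```
$ szind compute --graph cstars:3:3,0,0 --indices sdz,sz,ag2
n=6 m=6
SDZ   26.100000
Sz    24.000000
AG2   7.524922
```

26.1 is the maximum SDZ over all 13 unicyclic graphs on 6 vertices, which
you can confirm by exhaustion:

```
$ szind verify --suite unicyclic --n-max 8
unicyclic: 5 checks, 0 failures
```

The octane QSPR tables (computed index columns matched to the tabulated
physicochemical properties, and their 8×8 Pearson correlation matrix):

```
$ szind octane --out table1.csv
wrote 18 compounds to table1.csv
$ szind correlate --out table2.csv
wrote 8x8 matrix to table2.csv
$ szind scatter --pairs SDZ:AcentFac,SDZ:S --outdir scatter/
```

In the correlation matrix, SDZ anti-correlates strongly with the acentric
factor (r ≈ −0.97) and entropy (r ≈ −0.90) — stronger than the purely
degree-based SDD — which is the case for SDZ as a property predictor.

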