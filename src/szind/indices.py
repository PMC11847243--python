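"""Distance-, degree- and eccentricity-based topological indices.

The central quantity is the per-edge closer-vertex partition: for an edge
``e = uv`` of a connected graph, every vertex ``w`` is strictly closer to
``u`` (counted in ``n_u``), strictly closer to ``v`` (``n_v``), or
equidistant (``n_0``).  The symmetric division Szeged index is

    SDZ(G) = sum over edges uv of (n_u/n_v + n_v/n_u),

the Szeged-type analogue of the symmetric division degree index
SDD(G) = sum (d(u)^2 + d(v)^2) / (d(u) d(v)).  Both are instances of the
generalized form GSDD_f(G) = sum (f(u)/f(v) + f(v)/f(u)) for a positive
valuation f on edge endpoints.

Cut counts and distance-balance tests are exact integer computations; index
values are IEEE doubles accumulated in sorted-edge order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import networkx as nx
import numpy as np

from .exceptions import SzindError
from .graphs import (
    common_neighbor_count,
    distance_matrix,
    require_connected,
    sorted_edges,
)

__all__ = [
    "EdgeCutCounts",
    "edge_cut_counts",
    "all_edge_cut_counts",
    "sdz",
    "szeged",
    "sdd",
    "sde",
    "ag2",
    "rsz",
    "rm2",
    "companion_index",
    "gsdd",
    "hosoya_m_indices",
    "is_distance_balanced",
    "COMPANION_INDICES",
]


@dataclass(frozen=True)
class EdgeCutCounts:
    """Closer-vertex partition sizes for one edge ``(u, v)``.

    ``n_u + n_v + n_0 = n`` always, and both endpoints count themselves, so
    ``n_u, n_v >= 1``.  Bipartite graphs have ``n_0 = 0`` on every edge.
    """

    u: int
    v: int
    n_u: int
    n_v: int
    n_0: int

    @property
    def sdz_term(self) -> float:
        return self.n_u / self.n_v + self.n_v / self.n_u


def edge_cut_counts(
    g: nx.Graph, e: tuple[int, int], dist: np.ndarray | None = None
) -> EdgeCutCounts:
    """Classify every vertex of connected ``g`` against the endpoints of ``e``.

    Comparison of the two BFS distance rows of the endpoints; equidistant
    vertices go to ``n_0`` only (never tie-broken into either side).
    """
    require_connected(g)
    u, v = e
    if not g.has_edge(u, v):
        raise ValueError(f"{e!r} is not an edge of the graph")
    if dist is None:
        dist = distance_matrix(g)
    du, dv = dist[u], dist[v]
    n_u = int(np.sum(du < dv))
    n_v = int(np.sum(dv < du))
    n_0 = g.number_of_nodes() - n_u - n_v
    counts = EdgeCutCounts(u, v, n_u, n_v, n_0)
    assert counts.n_u >= 1 and counts.n_v >= 1
    return counts


def all_edge_cut_counts(g: nx.Graph, dist: np.ndarray | None = None) -> list[EdgeCutCounts]:
    """Cut counts for every edge, in sorted (min, max) edge order."""
    require_connected(g)
    if dist is None:
        dist = distance_matrix(g)
    return [edge_cut_counts(g, e, dist) for e in sorted_edges(g)]


def sdz(g: nx.Graph) -> float:
    """Symmetric division Szeged index: sum of n_u/n_v + n_v/n_u over edges.

    Every per-edge term is >= 2, so SDZ(G) >= 2m with equality exactly on
    distance-balanced graphs.
    """
    return float(sum(c.sdz_term for c in all_edge_cut_counts(g)))


def szeged(g: nx.Graph) -> float:
    """Szeged index: sum of n_u * n_v over edges."""
    return float(sum(c.n_u * c.n_v for c in all_edge_cut_counts(g)))


def ag2(g: nx.Graph) -> float:
    """Second arithmetic-geometric index: sum of (n_u + n_v) / (2 sqrt(n_u n_v))."""
    return float(
        sum((c.n_u + c.n_v) / (2.0 * np.sqrt(c.n_u * c.n_v)) for c in all_edge_cut_counts(g))
    )


def rsz(g: nx.Graph) -> float:
    """Reverse Szeged index: sum of 1 / (n_u n_v) over edges."""
    return float(sum(1.0 / (c.n_u * c.n_v) for c in all_edge_cut_counts(g)))


def sdd(g: nx.Graph) -> float:
    """Symmetric division degree index: sum of (d(u)^2 + d(v)^2) / (d(u) d(v))."""
    require_connected(g)
    if g.number_of_edges() == 0:
        return 0.0
    deg = dict(g.degree)
    return float(
        sum((deg[u] ** 2 + deg[v] ** 2) / (deg[u] * deg[v]) for u, v in sorted_edges(g))
    )


def rm2(g: nx.Graph) -> float:
    """Reverse second Zagreb index: sum of 1 / (d(u) d(v)) over edges."""
    require_connected(g)
    deg = dict(g.degree)
    return float(sum(1.0 / (deg[u] * deg[v]) for u, v in sorted_edges(g)))


def sde(g: nx.Graph) -> float:
    """Symmetric division eccentric index: SDD with eccentricities in place
    of degrees."""
    require_connected(g)
    if g.number_of_nodes() < 2:
        raise ValueError("eccentricity-based index needs n >= 2")
    dist = distance_matrix(g)
    ecc = dist.max(axis=1)
    return float(
        sum((ecc[u] ** 2 + ecc[v] ** 2) / (ecc[u] * ecc[v]) for u, v in sorted_edges(g))
    )


COMPANION_INDICES: dict[str, Callable[[nx.Graph], float]] = {
    "Sz": szeged,
    "SDD": sdd,
    "SDE": sde,
    "AG2": ag2,
    "RSz": rsz,
    "RM2": rm2,
}


def companion_index(g: nx.Graph, which: str) -> float:
    """Dispatch to one of the companion indices: Sz, SDD, SDE, AG2, RSz, RM2."""
    try:
        fn = COMPANION_INDICES[which]
    except KeyError:
        raise ValueError(f"unknown index selector {which!r}") from None
    return fn(g)


def gsdd(g: nx.Graph, f: Callable[[int, tuple[int, int]], float]) -> float:
    """Generalized symmetric division index for a positive valuation ``f``.

    ``f(vertex, edge)`` may depend on the edge, which is how the per-edge
    closer counts n_u, n_v are expressed; ``f = degree`` recovers SDD and a
    constant ``f`` gives exactly 2m.
    """
    require_connected(g)
    total = 0.0
    for e in sorted_edges(g):
        fu, fv = f(e[0], e), f(e[1], e)
        if fu <= 0 or fv <= 0:
            raise SzindError(f"valuation must be strictly positive, got {fu}, {fv} on {e}")
        total += fu / fv + fv / fu
    return float(total)


def partial_hosoya_coeffs(g: nx.Graph, v: int, dist: np.ndarray | None = None) -> np.ndarray:
    """Coefficients [c_1, ..., c_eps(v)] of the partial Hosoya polynomial
    H_v(x) = sum_k c_k x^k, c_k = #vertices at distance k from v."""
    if dist is None:
        dist = distance_matrix(g)
    row = dist[v].astype(int)
    eps = row.max()
    counts = np.bincount(row, minlength=eps + 1)[1:]
    return counts.astype(float)


def hosoya_m_indices(g: nx.Graph) -> tuple[float, float]:
    """Aggregate roots of the per-vertex partial Hosoya polynomials.

    For each vertex the polynomial H_v(x) = c_1 x + ... + c_eps x^eps is
    solved over the complex numbers (companion-matrix eigenvalues via
    ``numpy.roots``); all roots are kept with multiplicity, including the
    zero root contributed by the missing constant term.  Returns
    ``(M1, M2)`` with M1 the sum of the absolute values of all roots and M2
    the sum of their square roots.

    The root-counting convention is a genuine modeling choice (literal
    all-roots reading); see the octane module's calibration report.
    """
    require_connected(g)
    if g.number_of_nodes() < 2:
        raise ValueError("partial Hosoya polynomials need n >= 2")
    dist = distance_matrix(g)
    m1 = 0.0
    m2 = 0.0
    for v in range(g.number_of_nodes()):
        coeffs = partial_hosoya_coeffs(g, v, dist)
        # numpy.roots wants highest degree first: [c_eps, ..., c_1, 0]
        poly = np.concatenate([coeffs[::-1], [0.0]])
        roots = np.roots(poly)
        mags = np.abs(roots)
        m1 += float(mags.sum())
        m2 += float(np.sqrt(mags).sum())
    return m1, m2


def is_distance_balanced(g: nx.Graph) -> bool:
    """True iff n_u = n_v on every edge (exact integer test).

    Equivalent to SDZ(G) = 2m.  Cycles, complete graphs and more generally
    vertex-transitive graphs are distance-balanced; trees on n > 2 never are.
    """
    return all(c.n_u == c.n_v for c in all_edge_cut_counts(g))


def compute_indices(g: nx.Graph, names: Iterable[str]) -> dict[str, float]:
    """Batch computation used by the CLI; names from
    {sdz, sz, sdd, sde, ag2, rsz, rm2, m1m2}."""
    out: dict[str, float] = {}
    for name in names:
        key = name.lower()
        if key == "sdz":
            out["SDZ"] = sdz(g)
        elif key == "m1m2":
            m1, m2 = hosoya_m_indices(g)
            out["M1"], out["M2"] = m1, m2
        else:
            lut = {k.lower(): k for k in COMPANION_INDICES}
            if key not in lut:
                raise ValueError(f"unknown index {name!r}")
            out[lut[key]] = companion_index(g, lut[key])
    return out
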