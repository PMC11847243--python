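"""Closed-form SDZ values for named families and executable inequality checks.

Each named bound or identity relating SDZ to the order n, size m, triangle
count t(G) or a companion index is packaged as a checker that evaluates both
sides on a concrete graph and reports applicability, validity and the
equality condition.  Checkers never assume their hypotheses: they test and
record them, so a violation on an applicable graph is loud evidence of a bug
(or of a defect in the bound itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .graphs import (
    common_neighbor_count,
    graph_stats,
    enumerate_trees,
    enumerate_unicyclic,
    named_graph,
    require_connected,
    sorted_edges,
    triangle_count,
)
from .indices import is_distance_balanced, rm2, rsz, sdz

__all__ = [
    "sdz_star",
    "sdz_complete",
    "sdz_cycle",
    "sdz_bistar",
    "sdz_c3_star_max",
    "c3_star_max_printed",
    "sdz_closed_form",
    "InequalityReport",
    "check_inequality",
    "check_all_applicable",
    "THEOREM_IDS",
    "tree_extremal_check",
    "unicyclic_extremal_check",
    "per_edge_term",
    "balanced_split_extremes",
]

EQ_TOL = 1e-9  # absolute tolerance for floating equality verdicts


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def sdz_star(n: int) -> float:
    """SDZ of the star on n vertices: every edge splits (1, n-1), giving
    (n-1)((n-1) + 1/(n-1)) = n^2 - 2n + 2."""
    if n < 2:
        raise ValueError("star requires n >= 2")
    return float(n * n - 2 * n + 2)


def sdz_complete(n: int) -> float:
    """SDZ of K_n: every edge has n_u = n_v = 1, so SDZ = 2m = n^2 - n."""
    if n < 2:
        raise ValueError("complete requires n >= 2")
    return float(n * n - n)


def sdz_cycle(n: int) -> float:
    """SDZ of C_n: cycles are distance-balanced, so SDZ = 2m = 2n."""
    if n < 3:
        raise ValueError("cycle requires n >= 3")
    return float(2 * n)


def sdz_bistar(m: int, n: int) -> float:
    """SDZ of the bistar S_{m,n} on m+n+2 vertices.

    The m+n pendant edges each split (1, m+n+1); the central edge splits
    (m+1, n+1)."""
    if m < 1 or n < 1:
        raise ValueError("bistar requires m, n >= 1")
    s = m + n + 1
    return float((m + n) * (1.0 / s + s) + (m + 1) / (n + 1) + (n + 1) / (m + 1))


def sdz_c3_star_max(n: int) -> float:
    """SDZ of C3(S_{n-2}): a triangle with n-3 pendant leaves on one vertex —
    the unicyclic maximizer.

    Direct per-edge sum: the n-3 pendant edges split (1, n-1); the two
    triangle edges at the hub split (n-2, 1) with one equidistant vertex;
    the opposite triangle edge is balanced (term 2).
    """
    if n < 4:
        raise ValueError("requires n >= 4")
    return float(
        (n - 3) * (n * n - 2 * n + 2) / (n - 1)
        + 2 * (n * n - 4 * n + 5) / (n - 2)
        + 2
    )


def c3_star_max_printed(n: int) -> float:
    """The published closed-form expression for the unicyclic maximum,
    (n-3)(n^2-2n+2)/(n-1) + 2(n^2-2n+4)/(n-2) + 2.

    Recorded for transparency only: it disagrees with the direct SDZ of
    C3(S_{n-2}) (e.g. 31.6 vs 26.1 at n = 6), whose value
    :func:`sdz_c3_star_max` returns.
    """
    if n < 4:
        raise ValueError("requires n >= 4")
    return float(
        (n - 3) * (n * n - 2 * n + 2) / (n - 1)
        + 2 * (n * n - 2 * n + 4) / (n - 2)
        + 2
    )


_CLOSED_FORMS = {
    "star": sdz_star,
    "complete": sdz_complete,
    "cycle": sdz_cycle,
    "bistar": sdz_bistar,
    "c3_star_max": sdz_c3_star_max,
}


def sdz_closed_form(family: str, *params: int) -> float:
    """Closed-form SDZ for family in {star, bistar, complete, cycle, c3_star_max}."""
    try:
        fn = _CLOSED_FORMS[family]
    except KeyError:
        raise ValueError(f"unknown family {family!r}") from None
    return fn(*params)


# ---------------------------------------------------------------------------
# per-edge term analysis (used by the extremal arguments)
# ---------------------------------------------------------------------------

def per_edge_term(a: int, b: int) -> float:
    """The SDZ contribution a/b + b/a of one edge with closer counts (a, b)."""
    return a / b + b / a


def balanced_split_extremes(s: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Arg-min and arg-max of the per-edge term over positive splits a+b = s.

    The term is minimized at the balanced split and maximized at (1, s-1):
    brute force over all splits, used as the executable form of the
    split-monotonicity fact behind the extremal theorems.
    """
    splits = [(a, s - a) for a in range(1, s)]
    lo = min(splits, key=lambda p: per_edge_term(*p))
    hi = max(splits, key=lambda p: per_edge_term(*p))
    return lo, hi


# ---------------------------------------------------------------------------
# inequality catalog
# ---------------------------------------------------------------------------

@dataclass
class InequalityReport:
    """Outcome of one named bound/identity evaluated on one graph."""

    theorem: str
    n: int
    m: int
    lhs: float
    rhs: float
    relation: str  # one of "le", "lt", "ge", "gt", "eq"
    applicable: bool
    holds: bool | None = None  # None when inapplicable
    equality: bool | None = None
    equality_condition_met: bool | None = None
    hypothesis_unverified: bool = False
    notes: dict = field(default_factory=dict)

    def _check(self) -> None:
        if not self.applicable:
            return
        lhs, rhs = self.lhs, self.rhs
        self.equality = abs(lhs - rhs) <= EQ_TOL
        ok = {
            "le": lhs <= rhs + EQ_TOL,
            "lt": lhs < rhs - EQ_TOL or False,
            "ge": lhs >= rhs - EQ_TOL,
            "gt": lhs > rhs + EQ_TOL,
            "eq": self.equality,
        }[self.relation]
        # strict relations: a tie within tolerance is still a failure
        if self.relation in ("lt", "gt") and self.equality:
            ok = False
        self.holds = ok


def _report(theorem, g, lhs, rhs, relation, applicable=True, eq_cond=None,
            unverified=False, **notes) -> InequalityReport:
    rep = InequalityReport(
        theorem=theorem,
        n=g.number_of_nodes(),
        m=g.number_of_edges(),
        lhs=float(lhs),
        rhs=float(rhs),
        relation=relation,
        applicable=applicable,
        equality_condition_met=eq_cond,
        hypothesis_unverified=unverified,
        notes=dict(notes),
    )
    rep._check()
    return rep


def _is_star(g: nx.Graph) -> bool:
    n = g.number_of_nodes()
    degs = sorted(d for _, d in g.degree)
    return n >= 2 and g.number_of_edges() == n - 1 and degs[-1] == n - 1


def _is_cycle(g: nx.Graph) -> bool:
    n = g.number_of_nodes()
    return (
        n >= 3
        and g.number_of_edges() == n
        and all(d == 2 for _, d in g.degree)
        and nx.is_connected(g)
    )


def _check_sqrt_lower(g) -> InequalityReport:
    # SDZ > (1/8)(sqrt(32 m + 1) + 1); strict for every connected graph with
    # an edge (it is dominated by SDZ >= 2m but proved independently from the
    # AG2 comparison chain).
    m = g.number_of_edges()
    return _report("sdz_sqrt_lower", g, sdz(g), (math.sqrt(32 * m + 1) + 1) / 8, "gt",
                   applicable=m >= 1)


def _check_triangle_free_reverse(g) -> InequalityReport:
    # triangle-free, n >= 3: RSz <= RM2, equality iff diameter 2
    applicable = triangle_count(g) == 0 and g.number_of_nodes() >= 3
    if not applicable:
        return _report("triangle_free_reverse", g, 0, 0, "le", applicable=False)
    diam = graph_stats(g).diameter
    return _report("triangle_free_reverse", g, rsz(g), rm2(g), "le",
                   eq_cond=diam == 2, diameter=diam)


def _check_bipartite_upper(g) -> InequalityReport:
    # bipartite, n >= 3: SDZ <= n^2 RM2 - 2m, equality iff diameter 2;
    # the exact identity SDZ = n^2 RSz - 2m is recorded in notes.
    n, m = g.number_of_nodes(), g.number_of_edges()
    applicable = nx.is_bipartite(g) and n >= 3
    if not applicable:
        return _report("bipartite_upper", g, 0, 0, "le", applicable=False)
    diam = graph_stats(g).diameter
    return _report("bipartite_upper", g, sdz(g), n * n * rm2(g) - 2 * m, "le",
                   eq_cond=diam == 2,
                   rsz_identity=n * n * rsz(g) - 2 * m, diameter=diam)


def _check_edge_count_lower(g) -> InequalityReport:
    # SDZ >= 2m, equality iff distance-balanced
    m = g.number_of_edges()
    return _report("edge_count_lower", g, sdz(g), 2 * m, "ge",
                   applicable=m >= 1, eq_cond=is_distance_balanced(g))


def _check_edge_count_upper(g) -> InequalityReport:
    # SDZ <= m (n^2 - 2n + 2)/(n - 1), equality iff star
    n, m = g.number_of_nodes(), g.number_of_edges()
    applicable = m >= 1 and n >= 2
    if not applicable:
        return _report("edge_count_upper", g, 0, 0, "le", applicable=False)
    return _report("edge_count_upper", g, sdz(g), m * (n * n - 2 * n + 2) / (n - 1), "le",
                   eq_cond=_is_star(g))


def _check_non_tree_lower(g) -> InequalityReport:
    # non-tree (m >= n): SDZ >= 2n, equality iff cycle
    n, m = g.number_of_nodes(), g.number_of_edges()
    applicable = m >= n
    if not applicable:
        return _report("non_tree_lower", g, 0, 0, "ge", applicable=False)
    return _report("non_tree_lower", g, sdz(g), 2 * n, "ge", eq_cond=_is_cycle(g))


def _check_unicyclic_lower(g) -> InequalityReport:
    n, m = g.number_of_nodes(), g.number_of_edges()
    applicable = m == n
    if not applicable:
        return _report("unicyclic_lower", g, 0, 0, "ge", applicable=False)
    return _report("unicyclic_lower", g, sdz(g), 2 * n, "ge", eq_cond=_is_cycle(g))


def _check_unicyclic_upper(g) -> InequalityReport:
    # unicyclic, n >= 4: SDZ <= SDZ(C3(S_{n-2})) (proof-consistent value);
    # equality iff the graph is C3(S_{n-2}) itself.
    n, m = g.number_of_nodes(), g.number_of_edges()
    applicable = m == n and n >= 4
    if not applicable:
        return _report("unicyclic_upper", g, 0, 0, "le", applicable=False)
    extremal = named_graph("cycle_with_stars", [3, [n - 3, 0, 0]])
    return _report("unicyclic_upper", g, sdz(g), sdz_c3_star_max(n), "le",
                   eq_cond=nx.is_isomorphic(g, extremal),
                   printed_expression=c3_star_max_printed(n))


def _check_triangle_count_upper(g) -> InequalityReport:
    # SDZ < n^2 m + 9 t^2 - 6 n t - 2m for graphs with t >= 1.  The published
    # hypothesis is "triangulated" (planar, all faces triangles); planarity is
    # not verified here — the bound's derivation only uses t, n, m — so the
    # report is flagged hypothesis_unverified.
    n, m = g.number_of_nodes(), g.number_of_edges()
    t = triangle_count(g)
    applicable = t >= 1
    if not applicable:
        return _report("triangle_count_upper", g, 0, 0, "lt", applicable=False)
    return _report("triangle_count_upper", g, sdz(g),
                   n * n * m + 9 * t * t - 6 * n * t - 2 * m, "lt",
                   unverified=True, triangles=t)


def _check_common_neighbor_identity(g) -> InequalityReport:
    # identity: sum over edges of |N(u) ∩ N(v)| = 3 t(G)
    total = sum(common_neighbor_count(g, u, v) for u, v in sorted_edges(g))
    return _report("common_neighbor_triangle_identity", g, total,
                   3 * triangle_count(g), "eq", eq_cond=True)


_CHECKERS = {
    "sdz_sqrt_lower": _check_sqrt_lower,
    "triangle_free_reverse": _check_triangle_free_reverse,
    "bipartite_upper": _check_bipartite_upper,
    "edge_count_lower": _check_edge_count_lower,
    "edge_count_upper": _check_edge_count_upper,
    "non_tree_lower": _check_non_tree_lower,
    "unicyclic_lower": _check_unicyclic_lower,
    "unicyclic_upper": _check_unicyclic_upper,
    "triangle_count_upper": _check_triangle_count_upper,
    "common_neighbor_triangle_identity": _check_common_neighbor_identity,
}

THEOREM_IDS = tuple(_CHECKERS)


def check_inequality(theorem_id: str, g: nx.Graph) -> InequalityReport:
    """Evaluate one named bound/identity on a connected graph.

    Inapplicable hypotheses yield a report with ``applicable=False`` rather
    than an exception.
    """
    require_connected(g)
    try:
        checker = _CHECKERS[theorem_id]
    except KeyError:
        raise ValueError(f"unknown theorem id {theorem_id!r}") from None
    return checker(g)


def check_all_applicable(g: nx.Graph) -> list[InequalityReport]:
    """Run the whole catalog on one graph, returning applicable reports."""
    return [r for t in THEOREM_IDS for r in [check_inequality(t, g)] if r.applicable]


# ---------------------------------------------------------------------------
# extremal enumeration checks
# ---------------------------------------------------------------------------

@dataclass
class ExtremalReport:
    """Result of an exhaustive extremal check over one graph class."""

    n: int
    count: int
    min_value: float
    max_value: float
    min_is_expected: bool
    max_is_expected: bool
    min_unique: bool
    max_unique: bool
    ordering_holds: bool
    notes: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return (self.min_is_expected and self.max_is_expected
                and self.min_unique and self.max_unique and self.ordering_holds)


def tree_extremal_check(n: int) -> ExtremalReport:
    """Verify the tree extremal ordering SDZ(P_n) <= SDZ(T) <= SDZ(S_{1,n-3})
    < SDZ(S_n) by exhausting all trees on n vertices.

    The path is the unique minimizer, the star the unique overall maximizer,
    and the bistar S_{1,n-3} the unique maximizer among non-stars.
    """
    if not 4 <= n <= 10:
        raise ValueError("n must be in 4..10")
    trees = enumerate_trees(n)
    values = [sdz(t) for t in trees]
    path_v = sdz(named_graph("path", [n]))
    star_v = sdz_star(n)
    bistar_v = sdz_bistar(1, n - 3)
    non_star = [v for t, v in zip(trees, values) if not _is_star(t)]
    lo, hi = min(values), max(values)
    rep = ExtremalReport(
        n=n,
        count=len(trees),
        min_value=lo,
        max_value=hi,
        min_is_expected=abs(lo - path_v) <= EQ_TOL,
        max_is_expected=abs(hi - star_v) <= EQ_TOL,
        min_unique=sum(abs(v - lo) <= EQ_TOL for v in values) == 1,
        max_unique=sum(abs(v - hi) <= EQ_TOL for v in values) == 1,
        ordering_holds=(
            abs(max(non_star) - bistar_v) <= EQ_TOL and max(non_star) < star_v - EQ_TOL
        ),
        notes={"path": path_v, "bistar_1_nm3": bistar_v, "star": star_v},
    )
    return rep


def unicyclic_extremal_check(n: int) -> ExtremalReport:
    """Verify by exhaustion that C_n uniquely minimizes and C3(S_{n-2})
    uniquely maximizes SDZ among connected unicyclic graphs on n vertices."""
    if not 4 <= n <= 9:
        raise ValueError("n must be in 4..9")
    graphs = enumerate_unicyclic(n)
    values = [sdz(g) for g in graphs]
    cyc_v = sdz_cycle(n)
    max_v = sdz_c3_star_max(n)
    lo, hi = min(values), max(values)
    return ExtremalReport(
        n=n,
        count=len(graphs),
        min_value=lo,
        max_value=hi,
        min_is_expected=abs(lo - cyc_v) <= EQ_TOL,
        max_is_expected=abs(hi - max_v) <= EQ_TOL,
        min_unique=sum(abs(v - lo) <= EQ_TOL for v in values) == 1,
        max_unique=sum(abs(v - hi) <= EQ_TOL for v in values) == 1,
        ordering_holds=True,
        notes={"cycle": cyc_v, "c3_star_max": max_v,
               "printed_expression": c3_star_max_printed(n)},
    )
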