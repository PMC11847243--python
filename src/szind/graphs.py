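"""Graph substrate: I/O, named families, distances, stats, enumeration.

Every graph handled by szind is a simple undirected :class:`networkx.Graph`
whose vertices are exactly the integers ``0 .. n-1``.  Helper functions here
produce such graphs (remapping foreign labels as needed), compute all-pairs
BFS distances as a dense numpy matrix, and enumerate small trees and
unicyclic graphs up to isomorphism with a deterministic order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .exceptions import DisconnectedGraphError, GraphFormatError

__all__ = [
    "validate_graph",
    "graph_from_edge_list",
    "to_edge_list",
    "named_graph",
    "graph_spec",
    "distance_matrix",
    "require_connected",
    "sorted_edges",
    "GraphStats",
    "graph_stats",
    "tree_centroid",
    "tree_certificate",
    "enumerate_trees",
    "enumerate_unicyclic",
    "connected_graph_atlas",
    "random_connected_graph",
]

#: practical caps keeping exhaustive enumeration interactive
TREE_ENUM_CAP = 12
UNICYCLIC_ENUM_CAP = 9


def validate_graph(g: nx.Graph) -> nx.Graph:
    """Check the szind graph contract: simple, integer labels 0..n-1.

    Returns the graph unchanged; raises :class:`GraphFormatError` otherwise.
    networkx already forbids multi-edges on :class:`~networkx.Graph`, so only
    self-loops and the label set need checking.
    """
    n = g.number_of_nodes()
    if set(g.nodes) != set(range(n)):
        raise GraphFormatError(
            f"vertex labels must be exactly 0..{n - 1}, got {sorted(g.nodes)[:8]}..."
        )
    if any(u == v for u, v in g.edges):
        raise GraphFormatError("self-loops are not allowed")
    return g


def relabel_contiguous(g: nx.Graph) -> nx.Graph:
    """Relabel arbitrary hashable vertices to 0..n-1 in sorted order."""
    mapping = {v: i for i, v in enumerate(sorted(g.nodes, key=str))}
    return nx.relabel_nodes(g, mapping)


def graph_from_edge_list(text: str) -> nx.Graph:
    """Parse an edge-list document into a graph.

    Format: one edge per line as two whitespace-separated integer tokens;
    ``#`` starts a comment; an optional first non-comment line ``n=<int>``
    declares the vertex count so isolated vertices survive.  Labels may be
    arbitrary non-negative integers (1-based files are fine) and are remapped
    to ``0..n-1`` in order of first appearance.  Duplicate edges collapse;
    self-loops are a format error.
    """
    declared_n: int | None = None
    order: dict[int, int] = {}
    edges: list[tuple[int, int]] = []
    first_payload = True
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if first_payload and line.replace(" ", "").startswith("n="):
            try:
                declared_n = int(line.split("=", 1)[1])
            except ValueError as exc:
                raise GraphFormatError(f"line {lineno}: bad n= header {line!r}") from exc
            if declared_n < 0:
                raise GraphFormatError(f"line {lineno}: negative vertex count")
            first_payload = False
            continue
        first_payload = False
        tokens = line.split()
        if len(tokens) != 2:
            raise GraphFormatError(f"line {lineno}: expected two tokens, got {tokens!r}")
        try:
            a, b = int(tokens[0]), int(tokens[1])
        except ValueError as exc:
            raise GraphFormatError(f"line {lineno}: non-integer token in {tokens!r}") from exc
        if a < 0 or b < 0:
            raise GraphFormatError(f"line {lineno}: negative vertex label")
        if a == b:
            raise GraphFormatError(f"line {lineno}: self-loop {a}--{b}")
        for lab in (a, b):
            if lab not in order:
                order[lab] = len(order)
        edges.append((order[a], order[b]))
    g = nx.Graph()
    n = len(order)
    if declared_n is not None:
        if declared_n < n:
            raise GraphFormatError(f"n={declared_n} smaller than {n} labels used")
        n = declared_n
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


def to_edge_list(g: nx.Graph) -> str:
    """Serialize a graph in the edge-list format read by graph_from_edge_list."""
    lines = [f"n={g.number_of_nodes()}"]
    lines += [f"{u} {v}" for u, v in sorted_edges(g)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# named families
# ---------------------------------------------------------------------------

def _bistar(m: int, n: int) -> nx.Graph:
    """Bistar S_{m,n}: centers 0 and 1 adjacent, m pendants on 0, n on 1."""
    if m < 1 or n < 1:
        raise ValueError("bistar requires m, n >= 1")
    g = nx.Graph()
    g.add_edge(0, 1)
    for i in range(m):
        g.add_edge(0, 2 + i)
    for j in range(n):
        g.add_edge(1, 2 + m + j)
    return g


def _cycle_with_stars(r: int, sizes: list[int]) -> nx.Graph:
    """C_r(S_{t_1},...,S_{t_r}): cycle 0..r-1, then t_i pendant leaves on
    cycle vertex i, appended in cycle-vertex order."""
    if r < 3:
        raise ValueError("cycle requires r >= 3")
    if len(sizes) != r or any(t < 0 for t in sizes):
        raise ValueError("need r non-negative pendant-star sizes")
    g = nx.cycle_graph(r)
    nxt = r
    for i, t in enumerate(sizes):
        for _ in range(t):
            g.add_edge(i, nxt)
            nxt += 1
    return g


def named_graph(family: str, params: list) -> nx.Graph:
    """Build a parametric graph from one of the named families.

    Deterministic labelings: path/cycle vertices in order 0..n-1; star hub 0
    with leaves 1..n-1; bistar centers 0,1; cycle-with-stars as in
    :func:`_cycle_with_stars`.
    """
    if family == "path":
        (n,) = params
        if n < 1:
            raise ValueError("path requires n >= 1")
        return nx.path_graph(n)
    if family == "cycle":
        (r,) = params
        if r < 3:
            raise ValueError("cycle requires r >= 3")
        return nx.cycle_graph(r)
    if family == "star":
        (n,) = params
        if n < 2:
            raise ValueError("star requires n >= 2")
        return nx.star_graph(n - 1)  # hub 0, n vertices total
    if family == "bistar":
        m, n = params
        return _bistar(m, n)
    if family == "complete":
        (n,) = params
        if n < 1:
            raise ValueError("complete requires n >= 1")
        return nx.complete_graph(n)
    if family == "cycle_with_stars":
        r, sizes = params
        return _cycle_with_stars(r, list(sizes))
    raise ValueError(f"unknown family {family!r}")


_SPEC_FAMILIES = {
    "path": "path",
    "cycle": "cycle",
    "star": "star",
    "bistar": "bistar",
    "complete": "complete",
    "cstars": "cycle_with_stars",
}


def graph_spec(spec: str) -> nx.Graph:
    """Parse a compact CLI graph spec such as ``path:8`` or ``cstars:3:3,0,0``.

    Anything that is not a known ``family:params`` form is treated as a path
    to an edge-list file.
    """
    head, _, rest = spec.partition(":")
    if head in _SPEC_FAMILIES:
        family = _SPEC_FAMILIES[head]
        try:
            if family == "cycle_with_stars":
                r_str, _, sizes_str = rest.partition(":")
                params = [int(r_str), [int(t) for t in sizes_str.split(",")]]
            else:
                params = [int(t) for t in rest.split(",")]
        except ValueError as exc:
            raise GraphFormatError(f"bad graph spec {spec!r}") from exc
        return named_graph(family, params)
    with open(spec, encoding="utf-8") as fh:
        return graph_from_edge_list(fh.read())


# ---------------------------------------------------------------------------
# distances and stats
# ---------------------------------------------------------------------------

def distance_matrix(g: nx.Graph) -> np.ndarray:
    """All-pairs hop distances by BFS from every vertex.

    Returns a dense symmetric float matrix with zero diagonal; unreachable
    pairs hold ``numpy.inf``.
    """
    validate_graph(g)
    n = g.number_of_nodes()
    dist = np.full((n, n), np.inf)
    for src in range(n):
        for tgt, d in nx.single_source_shortest_path_length(g, src).items():
            dist[src, tgt] = d
    return dist


def require_connected(g: nx.Graph) -> nx.Graph:
    if g.number_of_nodes() == 0 or not nx.is_connected(g):
        raise DisconnectedGraphError("operation requires a connected non-empty graph")
    return g


def sorted_edges(g: nx.Graph) -> list[tuple[int, int]]:
    """Edges as (min, max) pairs in lexicographic order.

    All index sums iterate in this order so floating accumulation is
    reproducible.
    """
    return sorted((min(u, v), max(u, v)) for u, v in g.edges)


@dataclass
class GraphStats:
    """Basic structural summary of a graph."""

    n: int
    m: int
    degree_sequence: list[int]
    connected: bool
    bipartite: bool
    triangles: int
    eccentricity: list[int] | None = None  # None when disconnected
    diameter: int | None = None
    extras: dict = field(default_factory=dict)


def triangle_count(g: nx.Graph) -> int:
    """Number of triangles t(G), via per-edge common-neighbor counts.

    Each triangle is seen from its three edges, hence the division by 3; the
    same common-neighbor sum identity is exposed to the theorem checkers.
    """
    total = sum(common_neighbor_count(g, u, v) for u, v in g.edges)
    assert total % 3 == 0
    return total // 3


def common_neighbor_count(g: nx.Graph, u: int, v: int) -> int:
    """|N(u) ∩ N(v)| for an edge or vertex pair."""
    return len(set(g[u]) & set(g[v]))


def graph_stats(g: nx.Graph) -> GraphStats:
    validate_graph(g)
    connected = g.number_of_nodes() > 0 and nx.is_connected(g)
    ecc = diam = None
    if connected:
        dist = distance_matrix(g)
        ecc = [int(e) for e in dist.max(axis=1)] if g.number_of_nodes() > 1 else [0]
        diam = max(ecc)
    return GraphStats(
        n=g.number_of_nodes(),
        m=g.number_of_edges(),
        degree_sequence=sorted((d for _, d in g.degree), reverse=True),
        connected=connected,
        bipartite=nx.is_bipartite(g),
        triangles=triangle_count(g),
        eccentricity=ecc,
        diameter=diam,
    )


# ---------------------------------------------------------------------------
# canonical forms and enumeration
# ---------------------------------------------------------------------------

def tree_centroid(t: nx.Graph) -> list[int]:
    """Centroid vertex/vertices of a tree (minimizing the max component size
    after removal); one vertex, or two adjacent ones."""
    n = t.number_of_nodes()
    if n == 1:
        return [0]
    best: list[int] = []
    best_w = n + 1
    # O(n^2) is fine at enumeration sizes
    for v in t.nodes:
        w = max(len(c) for c in nx.connected_components(t.subgraph(set(t) - {v})))
        if w < best_w:
            best, best_w = [v], w
        elif w == best_w:
            best.append(v)
    return sorted(best)


def _ahu(t: nx.Graph, root: int, parent: int | None) -> str:
    children = sorted(
        _ahu(t, c, root) for c in t[root] if c != parent
    )
    return "(" + "".join(children) + ")"


def tree_certificate(t: nx.Graph) -> str:
    """Canonical AHU string of a free tree, rooted at its centroid.

    For a two-vertex centroid the lexicographically smaller of the two rooted
    encodings (with the edge between them cut into parent links) is used.
    Two free trees are isomorphic iff their certificates are equal.
    """
    cent = tree_centroid(t)
    if len(cent) == 1:
        return _ahu(t, cent[0], None)
    a, b = cent
    return min(
        "(" + _ahu(t, a, b) + _ahu(t, b, a) + ")",
        "(" + _ahu(t, b, a) + _ahu(t, a, b) + ")",
    )


def enumerate_trees(n: int, max_degree: int | None = None) -> list[nx.Graph]:
    """All free trees on n vertices up to isomorphism, optionally with a
    maximum-degree restriction, in sorted-certificate order.

    Alkane carbon skeletons are the case ``max_degree=4``; the 18 octane
    isomers are ``enumerate_trees(8, 4)``.
    """
    if not 1 <= n <= TREE_ENUM_CAP:
        raise ValueError(f"n must be in 1..{TREE_ENUM_CAP}")
    if n == 1:
        trees = [nx.empty_graph(1)]
    elif n == 2:
        trees = [nx.path_graph(2)]
    else:
        trees = [relabel_contiguous(t) for t in nx.nonisomorphic_trees(n)]
    if max_degree is not None:
        trees = [t for t in trees if max(d for _, d in t.degree) <= max_degree]
    tagged = sorted((tree_certificate(t), i) for i, t in enumerate(trees))
    assert len({c for c, _ in tagged}) == len(tagged), "duplicate tree certificates"
    return [trees[i] for _, i in tagged]


def _iso_fingerprint(g: nx.Graph) -> tuple:
    """Cheap isomorphism-invariant bucket key (not complete)."""
    dist = distance_matrix(g)
    rows = sorted(tuple(sorted(int(x) for x in row)) for row in dist)
    return (
        g.number_of_nodes(),
        g.number_of_edges(),
        tuple(sorted(d for _, d in g.degree)),
        triangle_count(g),
        tuple(rows),
    )


def dedup_isomorphic(graphs: list[nx.Graph]) -> list[nx.Graph]:
    """One representative per isomorphism class, keeping first occurrences.

    Buckets by an invariant fingerprint, then resolves collisions with the
    exact VF2 test.
    """
    buckets: dict[tuple, list[nx.Graph]] = {}
    out: list[nx.Graph] = []
    for g in graphs:
        key = _iso_fingerprint(g)
        reps = buckets.setdefault(key, [])
        if not any(nx.is_isomorphic(g, r) for r in reps):
            reps.append(g)
            out.append(g)
    return out


def enumerate_unicyclic(n: int) -> list[nx.Graph]:
    """All connected unicyclic graphs (m = n) on n vertices up to isomorphism.

    Every unicyclic graph is a spanning tree plus one edge, so candidates are
    generated as tree + non-edge over all free trees on n vertices, then
    deduplicated; order is deterministic (sorted fingerprints).
    """
    if not 3 <= n <= UNICYCLIC_ENUM_CAP:
        raise ValueError(f"n must be in 3..{UNICYCLIC_ENUM_CAP}")
    candidates: list[nx.Graph] = []
    for t in enumerate_trees(n):
        for u, v in itertools.combinations(range(n), 2):
            if not t.has_edge(u, v):
                g = t.copy()
                g.add_edge(u, v)
                candidates.append(g)
    uniq = dedup_isomorphic(candidates)
    tagged = sorted((_iso_fingerprint(g), i) for i, g in enumerate(uniq))
    return [uniq[i] for _, i in tagged]


def connected_graph_atlas(max_n: int = 6) -> list[nx.Graph]:
    """All connected graphs with 1..max_n (<=7) vertices up to isomorphism,
    from the networkx graph atlas, relabeled to 0..n-1."""
    if not 1 <= max_n <= 7:
        raise ValueError("atlas covers orders up to 7")
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for g in graph_atlas_g():
        if 1 <= g.number_of_nodes() <= max_n and nx.is_connected(g):
            out.append(relabel_contiguous(g))
    return out


def random_connected_graph(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    """Erdős–Rényi G(n, p) conditioned on connectivity (rejection sampling,
    with a fallback spanning tree splice to guarantee termination)."""
    for _ in range(200):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31 - 1)))
        if n == 0 or nx.is_connected(g):
            return g
    # glue components with random edges (rare at sensible p)
    comps = [sorted(c) for c in nx.connected_components(g)]
    for a, b in zip(comps, comps[1:]):
        g.add_edge(int(rng.choice(a)), int(rng.choice(b)))
    return g
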