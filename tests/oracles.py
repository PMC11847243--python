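"""Independent reference implementations used only as test oracles.

These deliberately avoid the code paths of the package: distances come from
scipy's Floyd–Warshall instead of per-vertex BFS, tree enumeration from
exhaustive Prüfer sequences deduplicated with Weisfeiler–Lehman hashes
instead of the WROM generator + AHU certificates.
"""

import itertools
import warnings

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import floyd_warshall


def fw_distance_matrix(g: nx.Graph) -> np.ndarray:
    adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes))
    return floyd_warshall(adj, directed=False, unweighted=True)


def fw_sdz(g: nx.Graph) -> float:
    """SDZ from a Floyd–Warshall distance matrix (independent oracle)."""
    dist = fw_distance_matrix(g)
    total = 0.0
    for u, v in sorted((min(e), max(e)) for e in g.edges):
        n_u = int(np.sum(dist[u] < dist[v]))
        n_v = int(np.sum(dist[v] < dist[u]))
        total += n_u / n_v + n_v / n_u
    return total


def prufer_tree_classes(n: int, max_degree: int | None = None) -> int:
    """Number of free-tree isomorphism classes on n vertices by brute force
    over all n^(n-2) Prüfer sequences, deduplicated by WL hash."""
    if n <= 2:
        return 1
    seen: set[str] = set()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seq in itertools.product(range(n), repeat=n - 2):
            t = nx.from_prufer_sequence(list(seq))
            if max_degree is not None and max(d for _, d in t.degree) > max_degree:
                continue
            seen.add(nx.weisfeiler_lehman_graph_hash(t, iterations=n))
    return len(seen)


def atlas_unicyclic_count(n: int) -> int:
    """Connected graphs with m = n on n <= 7 vertices, from the graph atlas."""
    from networkx.generators.atlas import graph_atlas_g

    return sum(
        1
        for g in graph_atlas_g()
        if g.number_of_nodes() == n
        and g.number_of_edges() == n
        and nx.is_connected(g)
    )
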