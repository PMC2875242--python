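"""Independent brute-force oracles used only by the test suite.

Each function recomputes a quantity by the most direct method available —
textbook formulas, exhaustive enumeration over node subsets, O(n^3)
Floyd-Warshall — deliberately sharing no code with the package internals.
"""

from itertools import combinations
import math

import numpy as np


def pearson_textbook(x, y) -> float:
    """Pearson R by the raw sum formula."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    sxy = sum(a * b for a, b in zip(x, y))
    num = n * sxy - sx * sy
    den = math.sqrt(n * sxx - sx * sx) * math.sqrt(n * syy - sy * sy)
    return num / den


def brute_force_edges(profiles, threshold):
    """All pairs with Pearson R strictly above the threshold, by direct scan."""
    edges = set()
    for i, j in combinations(range(len(profiles)), 2):
        xi, xj = profiles[i], profiles[j]
        if len(set(xi)) == 1 or len(set(xj)) == 1:
            continue  # zero variance: undefined R, never an edge
        if pearson_textbook(xi, xj) > threshold:
            edges.add((i, j))
    return edges


def _composition_class(labels, prefix):
    c = sum(1 for l in labels if l == "cytoplasm")
    return f"{prefix}{c}:{len(labels) - c}"


def brute_force_triangles(g):
    """Label-class counts of all 3-cliques by exhaustive subset enumeration."""
    counts = {}
    for trio in combinations(sorted(g.nodes(), key=str), 3):
        if all(g.has_edge(a, b) for a, b in combinations(trio, 2)):
            cls = _composition_class([g.nodes[n]["fraction"] for n in trio], "T")
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def brute_force_squares(g, induced=True):
    """Label-class counts of 4-cycles by exhaustive subset enumeration.

    For each 4-subset, each of the three ways to split it into two "opposite"
    pairs defines a candidate cycle a-c-b-d (opposite pairs (a,b) and (c,d));
    the cycle exists when its four rim edges are present, and is chordless
    when additionally neither diagonal is an edge.
    """
    counts = {}
    for quad in combinations(sorted(g.nodes(), key=str), 4):
        a, b, c, d = quad
        for (p, q), (r, s) in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            rim = [(p, r), (r, q), (q, s), (s, p)]
            if not all(g.has_edge(u, v) for u, v in rim):
                continue
            if induced and (g.has_edge(p, q) or g.has_edge(r, s)):
                continue
            labels = {n: g.nodes[n]["fraction"] for n in quad}
            n_cyto = sum(1 for l in labels.values() if l == "cytoplasm")
            if n_cyto == 2:
                # opposite iff the two cytoplasmic nodes form a diagonal pair
                cyto = [n for n, l in labels.items() if l == "cytoplasm"]
                opposite = set(cyto) in ({p, q}, {r, s})
                cls = "S2:2-opp" if opposite else "S2:2-adj"
            else:
                cls = f"S{n_cyto}:{4 - n_cyto}"
            counts[cls] = counts.get(cls, 0) + 1
    return counts


def floyd_warshall_spl(g):
    """All-pairs unit-weight shortest paths by O(n^3) Floyd-Warshall."""
    nodes = list(g.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges():
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    return nodes, dist
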