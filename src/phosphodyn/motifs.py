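"""Census of node-labeled network motifs: binary (edge), triangle, square.

Every node of the dynamics-based network carries a cellular-fraction label
(cytoplasm or nucleus).  A motif class is the label composition of a motif:
an edge is B2:0 / B1:1 / B0:2 (#cytoplasmic : #nucleic endpoints), a 3-clique
is T3:0 / T2:1 / T1:2 / T0:3, and a 4-cycle falls into six classes because at
a 2:2 composition the two cytoplasmic nodes can sit adjacent or opposite on
the cycle, which no relabeling of cycle positions can interconvert.

Squares are induced chordless 4-cycles by default: a chord would make the
quadruple a triangle-bearing clump rather than a ring, and a 4-clique would
otherwise contribute three spurious "squares".  The non-induced convention
(all 4-cycles, chords allowed) is available via ``induced=False``.

Exact exhaustive enumeration throughout; no sampling.  Node order inside the
enumeration is a fixed total order on node IDs so each subgraph is visited
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import networkx as nx

MOTIF_KINDS = ("binary", "triangle", "square")

BINARY_CLASSES = ("B2:0", "B1:1", "B0:2")
TRIANGLE_CLASSES = ("T3:0", "T2:1", "T1:2", "T0:3")
SQUARE_CLASSES = ("S4:0", "S3:1", "S2:2-adj", "S2:2-opp", "S1:3", "S0:4")
SQUARE_CLASSES_COLLAPSED = ("S4:0", "S3:1", "S2:2", "S1:3", "S0:4")


@dataclass
class MotifCensus:
    """Counts and percentage proportions of label-composition motif classes."""

    kind: str
    counts: dict

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict:
        """Percent of all motifs of this kind in each class (sums to 100)."""
        t = self.total
        if t == 0:
            return {c: float("nan") for c in self.counts}
        return {c: 100.0 * n / t for c, n in self.counts.items()}


def classes_for(kind: str, collapse_squares: bool = False) -> tuple:
    if kind == "binary":
        return BINARY_CLASSES
    if kind == "triangle":
        return TRIANGLE_CLASSES
    if kind == "square":
        return SQUARE_CLASSES_COLLAPSED if collapse_squares else SQUARE_CLASSES
    raise ValueError(f"unknown motif kind {kind!r}; expected one of {MOTIF_KINDS}")


# ---------------------------------------------------------------------------
# label-class combinatorics (orbit enumeration, used to derive class counts)

def n_label_classes(kind: str, n_labels: int = 2, distinguish_square_placement: bool = True) -> int:
    """Number of distinct label compositions of a motif, by orbit enumeration.

    Labelings of the motif's nodes are enumerated exhaustively and collapsed
    under the motif's symmetry group: all permutations for the edge and the
    3-clique (complete graphs), the dihedral group of the cycle for the
    square.  With two labels this yields 3 edge classes, 4 triangle classes,
    and 6 square classes (5 when adjacent/opposite placement at 2:2 is
    collapsed, i.e. when symmetry is taken as all permutations).
    """
    if kind == "binary":
        size, group = 2, list(permutations(range(2)))
    elif kind == "triangle":
        size, group = 3, list(permutations(range(3)))
    elif kind == "square":
        size = 4
        if distinguish_square_placement:
            rot = [(1, 2, 3, 0), (2, 3, 0, 1), (3, 0, 1, 2), (0, 1, 2, 3)]
            refl = [(3, 2, 1, 0), (1, 0, 3, 2), (0, 3, 2, 1), (2, 1, 0, 3)]
            group = rot + refl
        else:
            group = list(permutations(range(4)))
    else:
        raise ValueError(f"unknown motif kind {kind!r}")
    seen = set()
    for labeling in product(range(n_labels), repeat=size):
        orbit = min(tuple(labeling[g[i]] for i in range(size)) for g in group)
        seen.add(orbit)
    return len(seen)


# ---------------------------------------------------------------------------
# fast counting cores on integer-indexed nodes
#
# ``edges``: list of (u, v) int pairs; ``is_cyto``: sequence of bools per node.
# These cores are reused by the rewiring null, which re-counts motifs on
# thousands of randomized edge lists.

def _adjacency(n_nodes: int, edges) -> list:
    adj = [set() for _ in range(n_nodes)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def count_binary_classes(edges, is_cyto) -> dict:
    counts = dict.fromkeys(BINARY_CLASSES, 0)
    for u, v in edges:
        c = int(is_cyto[u]) + int(is_cyto[v])
        counts[BINARY_CLASSES[2 - c]] += 1
    return counts


def count_triangle_classes(n_nodes: int, edges, is_cyto) -> dict:
    counts = dict.fromkeys(TRIANGLE_CLASSES, 0)
    adj = _adjacency(n_nodes, edges)
    for u, v in edges:
        if u > v:
            u, v = v, u
        common = adj[u] & adj[v]
        for w in common:
            if w > v:
                c = int(is_cyto[u]) + int(is_cyto[v]) + int(is_cyto[w])
                counts[TRIANGLE_CLASSES[3 - c]] += 1
    return counts


def count_square_classes(n_nodes: int, edges, is_cyto, induced: bool = True) -> dict:
    """Count 4-cycles once each, classed by label composition and placement.

    A square is represented by its diagonal pairs {u,w} and {v,x} with u the
    smallest node of the cycle; the cycle order is u-v-w-x.  At composition
    2:2 the two cytoplasmic nodes are "opposite" when they form a diagonal and
    "adjacent" otherwise.  With ``induced`` the diagonals must be non-edges
    (chordless squares only).
    """
    counts = dict.fromkeys(SQUARE_CLASSES, 0)
    adj = _adjacency(n_nodes, edges)
    for u in range(n_nodes):
        au = adj[u]
        for w in range(u + 1, n_nodes):
            if induced and w in au:
                continue
            common = sorted(n for n in (au & adj[w]) if n > u)
            for i, v in enumerate(common):
                av = adj[v]
                for x in common[i + 1:]:
                    if induced and x in av:
                        continue
                    c = sum(map(int, (is_cyto[u], is_cyto[v], is_cyto[w], is_cyto[x])))
                    if c == 2:
                        opposite = (is_cyto[u] == is_cyto[w])  # diagonal pair shares label
                        counts["S2:2-opp" if opposite else "S2:2-adj"] += 1
                    else:
                        counts[f"S{c}:{4 - c}"] += 1
    return counts


# ---------------------------------------------------------------------------
# public graph-level API

def _index_graph(network: nx.Graph):
    nodes = sorted(network.nodes(), key=str)
    index = {n: i for i, n in enumerate(nodes)}
    is_cyto = []
    for n in nodes:
        frac = network.nodes[n].get("fraction")
        if frac not in ("cytoplasm", "nucleus"):
            raise ValueError(f"node {n!r} has no cellular-fraction label")
        is_cyto.append(frac == "cytoplasm")
    edges = [(index[u], index[v]) for u, v in network.edges()]
    return nodes, edges, is_cyto


def count_motifs(
    network: nx.Graph,
    kind: str,
    induced: bool = True,
    collapse_squares: bool = False,
) -> MotifCensus:
    """Exhaustively enumerate motifs of one kind and class them by labels."""
    if kind not in MOTIF_KINDS:
        raise ValueError(f"unknown motif kind {kind!r}; expected one of {MOTIF_KINDS}")
    nodes, edges, is_cyto = _index_graph(network)
    if kind == "binary":
        counts = count_binary_classes(edges, is_cyto)
    elif kind == "triangle":
        counts = count_triangle_classes(len(nodes), edges, is_cyto)
    else:
        counts = count_square_classes(len(nodes), edges, is_cyto, induced=induced)
        if collapse_squares:
            merged = dict.fromkeys(SQUARE_CLASSES_COLLAPSED, 0)
            for cls, n in counts.items():
                merged["S2:2" if cls.startswith("S2:2") else cls] += n
            counts = merged
    return MotifCensus(kind=kind, counts=counts)


def localization_score(census: MotifCensus) -> float | None:
    """Sum of the all-cytoplasmic and all-nucleic triangle proportions (percent).

    High scores mean triangles are label-pure, i.e. peptides from the same
    cellular fraction cluster together.  ``None`` when the network has no
    triangles (the score is undefined, not zero).
    """
    if census.kind != "triangle":
        raise ValueError("localization score is defined on the triangle census")
    if census.total == 0:
        return None
    p = census.proportions
    return p["T3:0"] + p["T0:3"]
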