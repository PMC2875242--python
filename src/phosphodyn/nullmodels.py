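"""Degree-preserving random edge rewiring (RER) nulls and empirical statistics.

RER repeatedly picks two edges at random and swaps their endpoints
((a,b),(c,d) -> (a,d),(c,b)), rejecting any swap that would create a
self-loop or a duplicate edge.  The process stops when no edge of the
original network remains in the randomized one, or after 100 * E swap
attempts, whichever comes first; rejected attempts count toward the cap, so
termination is guaranteed even on graphs (a star, a clique) where few or no
valid swaps exist.  Node degrees and labels are untouched, so RER is the
negative control that keeps the degree sequence and label frequencies of the
dynamics-based network while destroying its wiring.

Observed motif statistics are compared with the null through one-sided
empirical p-values (the fraction of null replicates at least as extreme as
the observation, ties included) and through the O/E ratio, the observed
value over the null mean.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .motifs import (
    MotifCensus,
    classes_for,
    count_binary_classes,
    count_square_classes,
    count_triangle_classes,
    localization_score,
    _index_graph,
)

DEFAULT_CAP_FACTOR = 100


def _rewire_edge_list(edges: list, rng: random.Random, cap_factor: int = DEFAULT_CAP_FACTOR):
    """Core RER loop on a list of (u, v) int pairs with u < v.

    Returns ``(new_edges, meta)`` where meta records the attempts used, the
    number of original edges still present, and whether the attempt cap was
    hit.  Degree sequence preservation is structural: every accepted swap
    replaces (a,b),(c,d) by (a,d),(c,b).
    """
    n_edges = len(edges)
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    edges = [ (u, v) if u < v else (v, u) for u, v in edges ]
    edge_set = set(edges)
    if len(edge_set) != n_edges:
        raise ValueError("duplicate edges in input")
    original = frozenset(edge_set)
    n_original_left = n_edges
    cap = cap_factor * n_edges
    attempts = 0
    randrange = rng.randrange
    while n_original_left > 0 and attempts < cap:
        attempts += 1
        i = randrange(n_edges)
        j = randrange(n_edges)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if randrange(2):  # random orientation of the swap
            c, d = d, c
        # candidate new edges (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in edge_set or e2 in edge_set or e1 == e2:
            continue
        old_i, old_j = edges[i], edges[j]
        edge_set.discard(old_i)
        edge_set.discard(old_j)
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = e1
        edges[j] = e2
        n_original_left += (e1 in original) + (e2 in original) \
            - (old_i in original) - (old_j in original)
    return edges, {
        "attempts": attempts,
        "cap": cap,
        "cap_hit": attempts >= cap and n_original_left > 0,
        "original_edges_remaining": n_original_left,
        "rejected_attempts_count_toward_cap": True,
    }


def random_edge_rewiring(
    network: nx.Graph, seed: int, cap_factor: int = DEFAULT_CAP_FACTOR
) -> nx.Graph:
    """Degree-preserving randomization of a labeled network (one replicate).

    Reproducible for a given seed.  Node attributes are carried over
    unchanged; the returned graph records rewiring metadata in
    ``graph["rer"]``.  On graphs where no valid swap exists the input wiring
    is returned once the attempt cap is exhausted (with ``cap_hit`` set).
    """
    if network.number_of_edges() < 2:
        raise ValueError("rewiring needs a network with at least 2 edges")
    nodes = sorted(network.nodes(), key=str)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in network.edges()]
    new_edges, meta = _rewire_edge_list(edges, random.Random(seed), cap_factor)
    g = nx.Graph(**network.graph)
    g.graph["rer"] = meta
    for n in nodes:
        g.add_node(n, **network.nodes[n])
    g.add_edges_from((nodes[u], nodes[v]) for u, v in new_edges)
    return g


def empirical_pvalue(observed: float, null_samples, side: str = "greater") -> float:
    """One-sided empirical p: fraction of null samples at least as extreme.

    ``side="greater"`` counts samples >= observed, ``side="less"`` counts
    samples <= observed; ties always count.  A p of exactly 0 means "less
    than 1/n" (see :func:`format_pvalue`), not impossibility.
    """
    samples = np.asarray(null_samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empirical p-value needs at least one null sample")
    if side == "greater":
        return float((samples >= observed).mean())
    if side == "less":
        return float((samples <= observed).mean())
    raise ValueError(f"unknown side {side!r}; expected 'greater' or 'less'")


def format_pvalue(p: float, n: int) -> str:
    return f"< {1.0 / n:g}" if p == 0.0 else f"{p:g}"


def significance_stars(p: float) -> str:
    """Significance marks: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class NullDistribution:
    """Observed statistic against its RER null distribution."""

    name: str
    observed: float
    samples: np.ndarray
    side: str

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.samples))

    @property
    def sd(self) -> float:
        return float(np.std(self.samples, ddof=1)) if self.n > 1 else 0.0

    @property
    def p(self) -> float:
        return empirical_pvalue(self.observed, self.samples, self.side)

    @property
    def oe(self) -> float | None:
        """Observed over expected (null mean); ``None`` when the mean is 0."""
        e = self.mean
        return None if e == 0.0 else self.observed / e

    @property
    def stars(self) -> str:
        return significance_stars(self.p)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "observed": self.observed,
            "null_mean": self.mean,
            "null_sd": self.sd,
            "n": self.n,
            "side": self.side,
            "p": self.p,
            "p_str": format_pvalue(self.p, self.n),
            "oe": self.oe,
            "stars": self.stars,
        }


def replicate_seeds(master_seed: int, n_reps: int) -> list[int]:
    """Deterministic per-replicate seeds spawned from one master seed.

    Uses numpy's SeedSequence spawning so replicates are statistically
    independent and the whole run is reproducible from the master seed alone.
    """
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _count_classes(kind: str, n_nodes: int, edges, is_cyto, induced: bool):
    if kind == "binary":
        return count_binary_classes(edges, is_cyto)
    if kind == "triangle":
        return count_triangle_classes(n_nodes, edges, is_cyto)
    return count_square_classes(n_nodes, edges, is_cyto, induced=induced)


def motif_enrichment(
    network: nx.Graph,
    kind: str = "triangle",
    n_reps: int = 1000,
    seed: int = 0,
    induced: bool = True,
    cap_factor: int = DEFAULT_CAP_FACTOR,
) -> dict:
    """Observed motif-class proportions against ``n_reps`` RER replicates.

    Returns a mapping class-name -> :class:`NullDistribution` over the class
    *proportions* (percent), plus a ``"localization_score"`` entry for the
    triangle kind.  The test side per class follows the sign of the observed
    deviation from the null mean.  Replicates whose class total is zero
    contribute an undefined (NaN-free: zero-total replicates are recorded as
    0 for every class proportion) sample only for the localization score,
    where they are skipped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    nodes, edges, is_cyto = _index_graph(network)
    n_nodes = len(nodes)
    class_names = classes_for(kind)
    obs_counts = _count_classes(kind, n_nodes, edges, is_cyto, induced)
    obs_census = MotifCensus(kind=kind, counts=obs_counts)
    obs_props = obs_census.proportions

    null_props = {c: np.empty(n_reps) for c in class_names}
    null_loc = np.empty(n_reps)
    for r, rep_seed in enumerate(replicate_seeds(seed, n_reps)):
        new_edges, _ = _rewire_edge_list(list(edges), random.Random(rep_seed), cap_factor)
        counts = _count_classes(kind, n_nodes, new_edges, is_cyto, induced)
        total = sum(counts.values())
        for c in class_names:
            null_props[c][r] = 100.0 * counts[c] / total if total else 0.0
        if kind == "triangle":
            null_loc[r] = (
                100.0 * (counts["T3:0"] + counts["T0:3"]) / total if total else 0.0
            )

    out = {}
    for c in class_names:
        side = "greater" if obs_props[c] >= float(np.mean(null_props[c])) else "less"
        out[c] = NullDistribution(
            name=c, observed=obs_props[c], samples=null_props[c], side=side
        )
    if kind == "triangle":
        obs_loc = localization_score(obs_census)
        if obs_loc is not None:
            side = "greater" if obs_loc >= float(np.mean(null_loc)) else "less"
            out["localization_score"] = NullDistribution(
                name="localization_score", observed=obs_loc, samples=null_loc, side=side
            )
    return out
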