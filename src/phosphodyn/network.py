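"""Correlation-threshold network construction from phosphorylation time courses.

Two phosphopeptides are connected when the Pearson correlation R of their
abundance profiles strictly exceeds the chosen threshold (0.99 by default;
0.97 and 0.98 are the conventional alternatives).  The resulting
"dynamics-based network" is undirected and simple, and peptides that gain no
edge at the threshold are excluded from it.  Anti-correlated pairs never form
an edge: the model targets kinase-substrate-like co-activation, not
phosphatase-like inversion.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import networkx as nx
import numpy as np

from .io import FRACTIONS, PhosphoPeptide

log = logging.getLogger(__name__)


def pearson_profile_correlation(a: Sequence[float], b: Sequence[float]) -> float | None:
    """Sample Pearson correlation of two profiles; ``None`` when undefined.

    The correlation is undefined when either profile has zero variance.
    Profiles must have equal length >= 3.
    """
    if len(a) != len(b):
        raise ValueError(f"profile length mismatch: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise ValueError("profiles must have at least 3 time points")
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        return None
    r = float((xd @ yd) / math.sqrt(sx * sy))
    return max(-1.0, min(1.0, r))


def correlation_matrix(profiles: np.ndarray) -> np.ndarray:
    """All-pairs Pearson R of profile rows; NaN rows/cols for zero variance."""
    x = np.asarray(profiles, dtype=float)
    xd = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xd * xd).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = xd / norms[:, None]
        r = unit @ unit.T
    r[norms == 0.0, :] = np.nan
    r[:, norms == 0.0] = np.nan
    return np.clip(r, -1.0, 1.0)


def build_dynamics_network(
    peptides: Sequence[PhosphoPeptide], threshold: float = 0.99
) -> nx.Graph:
    """Build the dynamics-based network at a strict ``R > threshold`` cutoff.

    Nodes are ``(peptide_id, fraction)`` pairs carrying ``fraction``,
    ``peptide_id`` and ``protein`` (standard ID when available, raw accession
    otherwise) attributes.  Pairs with undefined R (a zero-variance profile)
    contribute no edge; peptides left with no edge are dropped entirely.
    """
    if len(peptides) < 2:
        raise ValueError("need at least 2 peptides to build a network")
    if not (-1.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (-1, 1), got {threshold}")
    incomplete = [p.peptide_id for p in peptides if not p.is_complete]
    if incomplete:
        raise ValueError(
            f"{len(incomplete)} peptides have incomplete profiles "
            f"(e.g. {incomplete[0]!r}); filter them first"
        )
    node_ids = [p.node_id for p in peptides]
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate (peptide_id, fraction) node identities")

    x = np.array([p.profile for p in peptides], dtype=float)
    r = correlation_matrix(x)
    n_zero_var = int(np.isnan(np.diagonal(r)).sum())
    if n_zero_var:
        log.warning("%d zero-variance profiles excluded from edge formation", n_zero_var)

    iu, ju = np.triu_indices(len(peptides), k=1)
    with np.errstate(invalid="ignore"):
        hit = r[iu, ju] > threshold  # NaN compares False: undefined R -> no edge

    g = nx.Graph(threshold=threshold)
    for i, j in zip(iu[hit], ju[hit]):
        for k in (int(i), int(j)):
            p = peptides[k]
            if p.node_id not in g:
                g.add_node(
                    p.node_id,
                    fraction=p.fraction,
                    peptide_id=p.peptide_id,
                    protein=p.standard_id or p.protein_accession,
                )
        g.add_edge(peptides[int(i)].node_id, peptides[int(j)].node_id)

    for f in FRACTIONS:
        n_f = sum(1 for _, d in g.nodes(data=True) if d["fraction"] == f)
        log.info("fraction %s: %d nodes at R > %s", f, n_f, threshold)
    log.info(
        "dynamics network: %d nodes, %d edges at R > %s (%d peptides dropped as isolated)",
        g.number_of_nodes(), g.number_of_edges(), threshold,
        len(peptides) - g.number_of_nodes(),
    )
    return g


def fraction_subnetwork(network: nx.Graph, fraction: str) -> nx.Graph:
    """Induced subgraph on nodes of one cellular fraction.

    Nodes isolated *by the induction* are retained, so the cytoplasmic and
    nucleic subnetworks partition the parent node set and their densities are
    computed over the full fraction node count.
    """
    if fraction not in FRACTIONS:
        raise ValueError(f"unknown fraction {fraction!r}; expected one of {FRACTIONS}")
    keep = [n for n, d in network.nodes(data=True) if d.get("fraction") == fraction]
    sub = network.subgraph(keep).copy()
    sub.graph["threshold"] = network.graph.get("threshold")
    sub.graph["fraction"] = fraction
    return sub
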