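"""Concordance of the dynamics-based network with kinase-substrate pathways.

Curated phosphorylation reactions (kinase -> substrate) are collapsed into an
undirected protein graph; phosphatase and other non-phosphorylation reactions
are excluded, since a phosphatase and its substrate are expected to
anti-correlate and the dynamics network only links positively correlated
profiles.  Protein pairs are then binned by their shortest path length (SPL)
in the pathway graph, and for each bin the mean SPL of the corresponding
peptide pairs in the dynamics network is computed over the reachable pairs.
A rising trend — nearby proteins in the pathway having nearby peptides in the
dynamics network — is summarized by Pearson's R over the numeric bins; the
"All" bin (every protein pair, pathway-reachable or not) is excluded from R.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import ReactionRecord


def build_pathway_network(
    reactions: Sequence[ReactionRecord],
    tag: str | None = None,
    exclude_tag: str | None = None,
    kinase_list: Iterable[str] | None = None,
    name: str | None = None,
) -> nx.Graph:
    """Undirected protein graph from phosphorylation reactions.

    ``tag`` keeps only reactions with that pathway tag (e.g. one pathway's
    subset); ``exclude_tag`` removes them instead (the "everything minus one
    pathway" construction); ``kinase_list`` keeps only reactions where both
    proteins are in the list (a kinase-kinase subset).  Duplicate and
    direction-reversed reactions collapse onto one edge; self-reactions
    (autophosphorylation) yield no edge in this simple graph.
    """
    filters = []
    if tag is not None:
        filters.append(f"tag={tag!r}")
    if exclude_tag is not None:
        filters.append(f"exclude_tag={exclude_tag!r}")
    if kinase_list is not None:
        kinase_list = set(kinase_list)
        filters.append("kinase_list")
    g = nx.Graph(name=name or (tag or "all"))
    for rec in reactions:
        if rec.reaction_kind != "phosphorylation":
            continue
        if tag is not None and rec.pathway_tag != tag:
            continue
        if exclude_tag is not None and rec.pathway_tag == exclude_tag:
            continue
        if kinase_list is not None and (
            rec.enzyme_accession not in kinase_list
            or rec.substrate_accession not in kinase_list
        ):
            continue
        if rec.enzyme_accession != rec.substrate_accession:
            g.add_edge(rec.enzyme_accession, rec.substrate_accession)
    if g.number_of_edges() == 0:
        raise ValueError(
            "no phosphorylation reactions pass the filter "
            f"({', '.join(filters) or 'no filter'})"
        )
    return g


def _protein_nodes(dyn: nx.Graph) -> dict:
    by_protein: dict[str, list] = {}
    for n, d in dyn.nodes(data=True):
        pid = d.get("protein")
        if pid:
            by_protein.setdefault(pid, []).append(n)
    return by_protein


def protein_pair_spl_in_dynamics(
    dyn: nx.Graph,
    protein_a: str,
    protein_b: str,
    agg: str = "mean",
    _spl_cache: dict | None = None,
) -> float | None:
    """Dynamics-network SPL between two proteins, aggregated over peptide pairs.

    Every (peptide of A) x (peptide of B) node pair contributes its SPL if
    reachable; the result is the mean (default) or minimum over the reachable
    pairs, or ``None`` when no pair is reachable or a protein has no peptide
    in the network.  Pairs of one and the same node are skipped.
    """
    if agg not in ("mean", "min"):
        raise ValueError(f"unknown aggregation {agg!r}")
    by_protein = _protein_nodes(dyn)
    nodes_a = by_protein.get(protein_a, [])
    nodes_b = by_protein.get(protein_b, [])
    if not nodes_a or not nodes_b:
        return None
    spls = []
    for u in nodes_a:
        if _spl_cache is not None:
            lengths = _spl_cache.setdefault(
                u, dict(nx.single_source_shortest_path_length(dyn, u))
            )
        else:
            lengths = dict(nx.single_source_shortest_path_length(dyn, u))
        for v in nodes_b:
            if u == v:
                continue
            d = lengths.get(v)
            if d is not None:
                spls.append(d)
    if not spls:
        return None
    return float(np.mean(spls) if agg == "mean" else np.min(spls))


@dataclass
class SplComparison:
    """Binned pathway-SPL vs dynamics-SPL table with its Pearson summary."""

    bins: pd.DataFrame  # columns: bin, n_pairs, n_reachable, mean_dyn_spl
    pearson_r: float | None
    pearson_p: float | None
    pathway_name: str = ""
    n_shared_proteins: int = 0

    def as_dict(self) -> dict:
        return {
            "pathway": self.pathway_name,
            "n_shared_proteins": self.n_shared_proteins,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "bins": self.bins.to_dict(orient="records"),
        }


def spl_bin_comparison(
    dyn: nx.Graph,
    pathway: nx.Graph,
    agg: str = "mean",
    weighted: bool = False,
) -> SplComparison:
    """Figure-2-style comparison of pathway SPL bins with dynamics SPL means.

    Protein pairs (over proteins present in both networks) are binned by
    their integer SPL in the pathway graph; the "All" bin additionally takes
    the pathway-unreachable pairs.  Each bin's value is the mean dynamics-
    network SPL of its protein pairs (via :func:`protein_pair_spl_in_dynamics`,
    reachable peptide pairs only).  Pearson's R is computed across numeric
    bins with a defined mean — unweighted by default, weighted by the number
    of dynamics-reachable pairs per bin if requested.
    """
    dyn_proteins = set(_protein_nodes(dyn))
    shared = sorted(dyn_proteins & set(pathway.nodes()))
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 proteins shared between dynamics network and pathway, got {len(shared)}"
        )
    spl_cache: dict = {}
    path_lengths = {
        p: dict(nx.single_source_shortest_path_length(pathway, p)) for p in shared
    }
    records = []
    for i, a in enumerate(shared):
        for b in shared[i + 1:]:
            pw = path_lengths[a].get(b)  # None = pathway-unreachable
            dspl = protein_pair_spl_in_dynamics(dyn, a, b, agg=agg, _spl_cache=spl_cache)
            records.append({"a": a, "b": b, "pathway_spl": pw, "dyn_spl": dspl})
    pairs = pd.DataFrame(records)

    rows = []
    numeric_bins = sorted(
        int(v) for v in pairs["pathway_spl"].dropna().unique() if v > 0
    )
    for b in numeric_bins:
        sub = pairs[pairs["pathway_spl"] == b]
        reach = sub["dyn_spl"].dropna()
        rows.append(
            {
                "bin": b,
                "n_pairs": len(sub),
                "n_reachable": len(reach),
                "mean_dyn_spl": float(reach.mean()) if len(reach) else None,
            }
        )
    all_reach = pairs["dyn_spl"].dropna()
    rows.append(
        {
            "bin": "All",
            "n_pairs": len(pairs),
            "n_reachable": len(all_reach),
            "mean_dyn_spl": float(all_reach.mean()) if len(all_reach) else None,
        }
    )
    bins = pd.DataFrame(rows)

    fit = bins[(bins["bin"] != "All") & bins["mean_dyn_spl"].notna()]
    r = p = None
    if len(fit) >= 2:
        x = fit["bin"].astype(float).to_numpy()
        y = fit["mean_dyn_spl"].astype(float).to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            if weighted:
                w = fit["n_reachable"].astype(float).to_numpy()
                mx, my = np.average(x, weights=w), np.average(y, weights=w)
                cov = np.average((x - mx) * (y - my), weights=w)
                r = float(
                    cov
                    / np.sqrt(
                        np.average((x - mx) ** 2, weights=w)
                        * np.average((y - my) ** 2, weights=w)
                    )
                )
            else:
                r, p = stats.pearsonr(x, y)
                r, p = float(r), float(p)
    return SplComparison(
        bins=bins,
        pearson_r=r,
        pearson_p=p,
        pathway_name=pathway.graph.get("name", ""),
        n_shared_proteins=len(shared),
    )
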