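"""Graph-level summaries: density, degree statistics, shortest path lengths."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io import FRACTIONS
from .network import fraction_subnetwork


def density_from_counts(n_edges: int, n_nodes: int) -> float:
    """Network density as a percentage: 100 * E / (N * (N - 1) / 2)."""
    if n_nodes < 2:
        raise ValueError("density needs at least 2 nodes")
    return 100.0 * n_edges / (n_nodes * (n_nodes - 1) / 2.0)


def network_density(network: nx.Graph) -> float:
    """Density of a graph, in percent of all possible node pairs."""
    return density_from_counts(network.number_of_edges(), network.number_of_nodes())


def cumulative_degree_proportion(
    network: nx.Graph, group_by: str = "fraction", mode: str = "whole"
) -> pd.DataFrame:
    """Cumulative degree proportion P>=(k) per node group.

    For each group (cytoplasm / nucleus when grouping by fraction) and each
    integer degree k, the fraction of that group's nodes with degree >= k.
    ``mode="whole"`` uses degrees in the full network; ``mode="subnetwork"``
    recomputes degrees inside each fraction-induced subnetwork.  P>=(0) is 1
    for every group and the curve is non-increasing in k.
    """
    if mode not in ("whole", "subnetwork"):
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[str, list[int]] = {}
    if mode == "whole":
        for n, d in network.nodes(data=True):
            groups.setdefault(d.get(group_by, "all"), []).append(network.degree(n))
    else:
        if group_by != "fraction":
            raise ValueError("subnetwork mode groups by fraction")
        for f in FRACTIONS:
            sub = fraction_subnetwork(network, f)
            if sub.number_of_nodes():
                groups[f] = [sub.degree(n) for n in sub.nodes()]
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty node group")
    rows = []
    for grp, degrees in sorted(groups.items()):
        degs = np.asarray(degrees)
        for k in range(int(degs.max()) + 2):
            rows.append(
                {"group": grp, "k": k, "P_ge_k": float((degs >= k).mean())}
            )
    return pd.DataFrame(rows)


def protein_degree(network: nx.Graph) -> pd.DataFrame:
    """Per-protein degree: arithmetic mean of its peptide-node degrees.

    A protein quantified by several peptides gets the mean of their degrees
    (hence fractional values).  Proteins are ranked by descending degree,
    ties broken by protein ID.  Nodes without a protein attribute are skipped
    and counted in the ``attrs`` of the returned frame.
    """
    per_protein: dict[str, list[int]] = {}
    skipped = 0
    for n, d in network.nodes(data=True):
        pid = d.get("protein")
        if not pid:
            skipped += 1
            continue
        per_protein.setdefault(pid, []).append(network.degree(n))
    rows = [
        {"protein": pid, "degree": float(np.mean(ks)), "n_peptides": len(ks)}
        for pid, ks in per_protein.items()
    ]
    df = pd.DataFrame(rows, columns=["protein", "degree", "n_peptides"])
    df = df.sort_values(["degree", "protein"], ascending=[False, True], kind="stable")
    df = df.reset_index(drop=True)
    df.attrs["n_skipped_nodes"] = skipped
    return df


@dataclass
class SplMatrix:
    """All-pairs unweighted shortest path lengths; unreachable pairs are ``None``."""

    lengths: dict
    nodes: tuple

    def get(self, u, v) -> int | None:
        return self.lengths.get(u, {}).get(v)

    def reachable(self, u, v) -> bool:
        return self.get(u, v) is not None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, u in enumerate(self.nodes):
            for v in self.nodes[i + 1:]:
                rows.append({"u": u, "v": v, "spl": self.get(u, v)})
        return pd.DataFrame(rows)


def all_pairs_spl(network: nx.Graph) -> SplMatrix:
    """Breadth-first-search all-pairs shortest path lengths (unit edge weights)."""
    lengths = {u: dict(d) for u, d in nx.all_pairs_shortest_path_length(network)}
    return SplMatrix(lengths=lengths, nodes=tuple(network.nodes()))
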