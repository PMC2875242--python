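"""Model/Results facade over the dynamics-network analysis.

:class:`PhosphoDynamicsModel` holds the quantified peptides and the
correlation threshold; ``fit()`` builds the thresholded network and returns a
:class:`DynamicsResults` carrying the graph together with its summaries
(density, degree statistics, motif census) and the downstream analyses
(rewiring-null enrichment with empirical p-values, pathway SPL concordance).
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
import pandas as pd

from . import io as pio
from . import metrics, motifs, network, nullmodels, pathway
from .io import FRACTIONS, PhosphoPeptide


class PhosphoDynamicsModel:
    """Correlation-network model of phosphorylation dynamics.

    Parameters
    ----------
    peptides
        Completely measured peptide profiles (records with missing points are
        filtered out on construction; the count is kept in ``filter_report``).
    threshold
        Pearson R cutoff; an edge requires R strictly above it.
    """

    def __init__(self, peptides: Sequence[PhosphoPeptide], threshold: float = 0.99):
        self.peptides, self.filter_report = pio.filter_complete_profiles(peptides)
        if len(self.peptides) < 2:
            raise ValueError("need at least 2 completely measured peptides")
        self.threshold = float(threshold)

    @classmethod
    def from_table(cls, path, schema=None, idmap_path=None, threshold: float = 0.99):
        """Build from a quantification TSV, optionally standardizing IDs."""
        peptides = pio.load_quant_table(path, schema=schema)
        if idmap_path is not None:
            idmap = pio.load_idmap(idmap_path)
            peptides, _ = pio.standardize_ids(peptides, idmap)
        return cls(peptides, threshold=threshold)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema=None, threshold: float = 0.99):
        """Build from an in-memory quantification table (same layout as the TSV)."""
        import io as _stdio

        buf = _stdio.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        return cls(pio.load_quant_table(buf, schema=schema), threshold=threshold)

    def fit(self) -> "DynamicsResults":
        g = network.build_dynamics_network(self.peptides, self.threshold)
        return DynamicsResults(self, g)


class DynamicsResults:
    """A fitted dynamics-based network and everything computed from it."""

    def __init__(self, model: PhosphoDynamicsModel, net: nx.Graph):
        self.model = model
        self.network = net
        self.threshold = model.threshold

    # -- basic structure ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.network.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.network.number_of_edges()

    @property
    def nodes_by_fraction(self) -> dict:
        out = dict.fromkeys(FRACTIONS, 0)
        for _, d in self.network.nodes(data=True):
            out[d["fraction"]] += 1
        return out

    @property
    def density(self) -> float:
        """Percent of realized node pairs, 100 * E / (N (N-1) / 2)."""
        return metrics.network_density(self.network)

    def subnetwork(self, fraction: str) -> nx.Graph:
        return network.fraction_subnetwork(self.network, fraction)

    def degree_summary(self, mode: str = "whole") -> pd.DataFrame:
        return metrics.cumulative_degree_proportion(self.network, mode=mode)

    def protein_degree(self) -> pd.DataFrame:
        return metrics.protein_degree(self.network)

    def spl_matrix(self) -> metrics.SplMatrix:
        return metrics.all_pairs_spl(self.network)

    # -- motifs and nulls ---------------------------------------------------
    def motif_census(self, kind: str = "triangle", **kw) -> motifs.MotifCensus:
        return motifs.count_motifs(self.network, kind, **kw)

    def localization_score(self) -> float | None:
        return motifs.localization_score(self.motif_census("triangle"))

    def motif_enrichment(
        self, kind: str = "triangle", n_reps: int = 1000, seed: int = 0, **kw
    ) -> dict:
        return nullmodels.motif_enrichment(
            self.network, kind=kind, n_reps=n_reps, seed=seed, **kw
        )

    # -- pathway concordance ------------------------------------------------
    def compare_pathway(self, pathway_net: nx.Graph, **kw) -> pathway.SplComparison:
        return pathway.spl_bin_comparison(self.network, pathway_net, **kw)

    # -- reporting ----------------------------------------------------------
    def summary(self, enrichment: dict | None = None) -> str:
        """Plain-text summary table of the fitted network."""
        nf = self.nodes_by_fraction
        lines = [
            "Phosphorylation dynamics-based network",
            "=" * 54,
            f"{'Pearson R threshold':<34}{self.threshold:>20}",
            f"{'Peptides (complete profiles)':<34}{len(self.model.peptides):>20}",
            f"{'Nodes (degree >= 1)':<34}{self.n_nodes:>20}",
            f"{'  cytoplasmic':<34}{nf['cytoplasm']:>20}",
            f"{'  nucleic':<34}{nf['nucleus']:>20}",
            f"{'Edges':<34}{self.n_edges:>20}",
            f"{'Density (%)':<34}{self.density:>20.2f}",
        ]
        census = self.motif_census("triangle")
        lines.append(f"{'Triangles':<34}{census.total:>20}")
        if census.total:
            for cls in motifs.TRIANGLE_CLASSES:
                lines.append(f"{'  ' + cls + ' (%)':<34}{census.proportions[cls]:>20.2f}")
            lines.append(
                f"{'Localization score (%)':<34}{motifs.localization_score(census):>20.2f}"
            )
        if enrichment:
            lines.append("-" * 54)
            lines.append(f"{'class':<16}{'O%':>8}{'E%':>8}{'sd':>7}{'O/E':>7}{'p':>9}")
            for name, nd in enrichment.items():
                oe = f"{nd.oe:.2f}" if nd.oe is not None else "--"
                lines.append(
                    f"{name:<16}{nd.observed:>8.2f}{nd.mean:>8.2f}{nd.sd:>7.2f}"
                    f"{oe:>7}{nullmodels.format_pvalue(nd.p, nd.n):>8}{nd.stars}"
                )
        lines.append("=" * 54)
        return "\n".join(lines)

    # -- plotting -----------------------------------------------------------
    def plot_cumulative_degree(self, mode: str = "whole", ax=None):
        """Cumulative degree proportion P>=(k) per fraction, log-scaled axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.degree_summary(mode=mode)
        for grp, sub in df.groupby("group"):
            sub = sub[sub["k"] >= 1]
            ax.plot(sub["k"], sub["P_ge_k"], marker="o", ms=3, label=str(grp))
        ax.set_xlabel("node degree k")
        ax.set_ylabel("P≥(k)")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.legend(title="fraction")
        return ax
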