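import networkx as nx
import numpy as np
import pytest

from phosphodyn import (
    PhosphoDynamicsModel,
    ReactionRecord,
    build_pathway_network,
    generate_dataset,
    protein_pair_spl_in_dynamics,
    recovery_report,
    spl_bin_comparison,
)
from .conftest import CASCADE_THRESHOLD, cascade_config


def dyn_graph(edges, proteins):
    """Dynamics-network stand-in: nodes (pep, fraction) with protein IDs."""
    g = nx.Graph()
    for node, prot in proteins.items():
        g.add_node(node, fraction=node[1], protein=prot)
    g.add_edges_from(edges)
    return g


class TestBuildPathwayNetwork:
    def test_phosphatase_reactions_are_excluded(self):
        rxns = [
            ReactionRecord("A", "B"),
            ReactionRecord("B", "C"),
            ReactionRecord("D", "E", reaction_kind="dephosphorylation"),
        ]
        g = build_pathway_network(rxns)
        assert set(map(frozenset, g.edges())) == {frozenset("AB"), frozenset("BC")}

    def test_set_difference_via_exclude_tag(self):
        rxns = [
            ReactionRecord("A", "B", pathway_tag="egfr"),
            ReactionRecord("B", "C", pathway_tag="other"),
            ReactionRecord("C", "D", pathway_tag="other"),
        ]
        g = build_pathway_network(rxns, exclude_tag="egfr")
        assert set(map(frozenset, g.edges())) == {frozenset("BC"), frozenset("CD")}

    def test_kinase_subset_requires_both_endpoints(self):
        rxns = [ReactionRecord("A", "B"), ReactionRecord("B", "C")]
        g = build_pathway_network(rxns, kinase_list={"A", "B"})
        assert set(map(frozenset, g.edges())) == {frozenset("AB")}

    def test_direction_reversal_and_duplicates_collapse(self):
        fwd = build_pathway_network([ReactionRecord("A", "B"), ReactionRecord("B", "A")])
        assert fwd.number_of_edges() == 1

    def test_empty_filter_result_names_the_filter(self):
        with pytest.raises(ValueError, match="ghost"):
            build_pathway_network([ReactionRecord("A", "B", pathway_tag="x")], tag="ghost")


class TestProteinPairSpl:
    def test_single_peptides_pass_through(self):
        g = dyn_graph(
            [(("a", "cytoplasm"), ("m", "cytoplasm")), (("m", "cytoplasm"), ("n", "nucleus")),
             (("n", "nucleus"), ("b", "nucleus"))],
            {("a", "cytoplasm"): "PA", ("m", "cytoplasm"): "PM",
             ("n", "nucleus"): "PN", ("b", "nucleus"): "PB"},
        )
        assert protein_pair_spl_in_dynamics(g, "PA", "PB") == 3.0

    def test_mean_over_peptide_pairs(self):
        g = dyn_graph(
            [(("x", "cytoplasm"), ("m", "cytoplasm")),
             (("m", "cytoplasm"), ("z", "nucleus")),
             (("y", "cytoplasm"), ("w", "cytoplasm")),
             (("w", "cytoplasm"), ("v", "cytoplasm")),
             (("v", "cytoplasm"), ("u", "cytoplasm")),
             (("u", "cytoplasm"), ("z", "nucleus"))],
            {("x", "cytoplasm"): "P1", ("y", "cytoplasm"): "P1",
             ("z", "nucleus"): "P2", ("m", "cytoplasm"): "PM",
             ("w", "cytoplasm"): "PW", ("v", "cytoplasm"): "PV",
             ("u", "cytoplasm"): "PU"},
        )
        # SPL(x,z)=2, SPL(y,z)=4 -> mean 3, min 2
        assert protein_pair_spl_in_dynamics(g, "P1", "P2") == pytest.approx(3.0)
        assert protein_pair_spl_in_dynamics(g, "P1", "P2", agg="min") == pytest.approx(2.0)

    def test_unreachable_and_absent_proteins_are_none(self):
        g = dyn_graph(
            [(("a", "cytoplasm"), ("b", "cytoplasm")), (("c", "nucleus"), ("d", "nucleus"))],
            {("a", "cytoplasm"): "PA", ("b", "cytoplasm"): "PB",
             ("c", "nucleus"): "PC", ("d", "nucleus"): "PD"},
        )
        assert protein_pair_spl_in_dynamics(g, "PA", "PC") is None
        assert protein_pair_spl_in_dynamics(g, "PA", "GHOST") is None


class TestSplBinComparison:
    @staticmethod
    def identity_setup(seed=3):
        base = nx.random_labeled_tree(15, seed=seed)
        base.add_edges_from([(0, 7), (2, 11), (5, 13)])
        dyn = nx.Graph()
        for u, v in base.edges():
            dyn.add_edge((f"p{u}", "cytoplasm"), (f"p{v}", "cytoplasm"))
        for n in dyn.nodes():
            dyn.nodes[n]["fraction"] = "cytoplasm"
            dyn.nodes[n]["protein"] = "P" + n[0][1:]
        pathway = nx.Graph(name="identity")
        pathway.add_edges_from((f"P{u}", f"P{v}") for u, v in base.edges())
        return dyn, pathway

    def test_identity_construction_bin_means_equal_bin_values(self):
        dyn, pathway = self.identity_setup()
        cmp_res = spl_bin_comparison(dyn, pathway)
        numeric = cmp_res.bins[cmp_res.bins["bin"] != "All"]
        assert (numeric["mean_dyn_spl"] == numeric["bin"].astype(float)).all()
        assert cmp_res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_all_bin_counts_every_pair(self):
        dyn, pathway = self.identity_setup()
        cmp_res = spl_bin_comparison(dyn, pathway)
        numeric = cmp_res.bins[cmp_res.bins["bin"] != "All"]
        all_row = cmp_res.bins[cmp_res.bins["bin"] == "All"].iloc[0]
        assert all_row["n_pairs"] >= numeric["n_pairs"].sum()
        n = cmp_res.n_shared_proteins
        assert all_row["n_pairs"] == n * (n - 1) // 2

    def test_no_shared_proteins_is_an_error(self):
        dyn, _ = self.identity_setup()
        stranger = nx.Graph(name="x")
        stranger.add_edge("QA", "QB")
        with pytest.raises(ValueError, match="shared"):
            spl_bin_comparison(dyn, stranger)

    def test_weighted_correlation_option_runs(self):
        dyn, pathway = self.identity_setup()
        cmp_res = spl_bin_comparison(dyn, pathway, weighted=True)
        assert cmp_res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_planted_cascade_yields_positive_correlation(self):
        cfg = cascade_config(seed=4)
        _, _, _, peptides, truth = generate_dataset(cfg)
        res = PhosphoDynamicsModel(peptides, threshold=CASCADE_THRESHOLD).fit()
        pathway = nx.Graph(name="planted")
        pathway.add_edges_from(truth.pathway_edges)
        cmp_res = res.compare_pathway(pathway)
        assert cmp_res.pearson_r is not None and cmp_res.pearson_r > 0
        report = recovery_report(truth, res.network, comparison=cmp_res)
        assert report["cascade_spearman_rho"] > 0

    def test_label_shuffled_profiles_show_no_systematic_trend(self):
        # destroy the planted kinetics by shuffling profiles across peptides
        rng = np.random.default_rng(0)
        rs = []
        for seed in range(6):
            cfg = cascade_config(seed=seed)
            _, _, _, peptides, truth = generate_dataset(cfg)
            profiles = [p.profile for p in peptides]
            rng.shuffle(profiles)
            from dataclasses import replace

            shuffled = [replace(p, profile=tuple(prof)) for p, prof in zip(peptides, profiles)]
            res = PhosphoDynamicsModel(shuffled, threshold=0.8).fit()
            pathway = nx.Graph(name="planted")
            pathway.add_edges_from(truth.pathway_edges)
            try:
                cmp_res = res.compare_pathway(pathway)
            except ValueError:
                continue
            if cmp_res.pearson_r is not None:
                rs.append(cmp_res.pearson_r)
        assert rs, "shuffled networks produced no comparable bins"
        assert abs(np.mean(rs)) < 0.5
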