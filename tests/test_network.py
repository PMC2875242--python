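import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from phosphodyn import (
    PhosphoPeptide,
    SimConfig,
    build_dynamics_network,
    fraction_subnetwork,
    generate_dataset,
    pearson_profile_correlation,
)
from .oracles import brute_force_edges, pearson_textbook


def pep(pid, fraction, profile):
    return PhosphoPeptide(pid, "ACC_" + pid, fraction, tuple(profile), tuple(range(len(profile))))


class TestPearson:
    def test_perfect_positive_and_negative(self):
        assert pearson_profile_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]) == pytest.approx(1.0)
        assert pearson_profile_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        assert pearson_profile_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5]) is None
        assert pearson_profile_correlation([1, 2, 3], [7, 7, 7]) is None

    def test_length_mismatch_and_short_profiles_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_profile_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="3 time points"):
            pearson_profile_correlation([1, 2], [3, 4])

    def test_matches_textbook_formula_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a, b = rng.normal(size=5), rng.normal(size=5)
            assert pearson_profile_correlation(a, b) == pytest.approx(
                pearson_textbook(list(a), list(b)), abs=1e-12
            )

    @given(
        st.lists(st.floats(-50, 50), min_size=5, max_size=5),
        st.lists(st.floats(-50, 50), min_size=5, max_size=5),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_and_positive_affine_invariance(self, a, b, scale, shift):
        r_ab = pearson_profile_correlation(a, b)
        r_ba = pearson_profile_correlation(b, a)
        if r_ab is None:
            assert r_ba is None
            return
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
        r_scaled = pearson_profile_correlation([scale * x + shift for x in a], b)
        if r_scaled is not None:  # tiny scales can underflow the variance
            assert r_scaled == pytest.approx(r_ab, abs=1e-6)


class TestBuildNetwork:
    def test_identical_profiles_form_triangle(self):
        peps = [pep(f"p{i}", "cytoplasm", [1, 2, 5, 3, 1]) for i in range(3)]
        g = build_dynamics_network(peps, threshold=0.99)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_r_equal_to_threshold_gives_no_edge(self):
        a, b = [1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0, 4.0]
        r = pearson_profile_correlation(a, b)
        peps = [pep("a", "cytoplasm", a), pep("b", "nucleus", b)]
        assert build_dynamics_network(peps, threshold=r).number_of_edges() == 0
        assert build_dynamics_network(peps, threshold=r - 1e-12).number_of_edges() == 1

    def test_isolated_peptides_are_dropped(self):
        peps = [
            pep("a", "cytoplasm", [1, 2, 5, 3, 1]),
            pep("b", "cytoplasm", [1, 2, 5, 3, 1]),
            pep("c", "nucleus", [5, 1, 0, 4, 2]),
        ]
        g = build_dynamics_network(peps, threshold=0.99)
        assert set(g.nodes()) == {("a", "cytoplasm"), ("b", "cytoplasm")}

    def test_zero_variance_profile_never_forms_an_edge(self):
        peps = [
            pep("flat", "cytoplasm", [2, 2, 2, 2, 2]),
            pep("a", "cytoplasm", [1, 2, 5, 3, 1]),
            pep("b", "cytoplasm", [1, 2, 5, 3, 1]),
        ]
        g = build_dynamics_network(peps, threshold=0.5)
        assert ("flat", "cytoplasm") not in g.nodes()

    def test_node_attributes_carry_fraction_and_protein(self):
        peps = [pep("a", "cytoplasm", [1, 2, 3, 4, 5]), pep("b", "nucleus", [1, 2, 3, 4, 5])]
        g = build_dynamics_network(peps, threshold=0.9)
        assert g.nodes[("a", "cytoplasm")]["fraction"] == "cytoplasm"
        assert g.nodes[("b", "nucleus")]["protein"] == "ACC_b"

    def test_too_few_peptides_and_bad_threshold_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_dynamics_network([pep("a", "cytoplasm", [1, 2, 3])], 0.9)
        two = [pep("a", "cytoplasm", [1, 2, 3]), pep("b", "nucleus", [1, 2, 3])]
        with pytest.raises(ValueError, match="threshold"):
            build_dynamics_network(two, 1.0)

    def test_incomplete_profiles_rejected(self):
        peps = [pep("a", "cytoplasm", [1, None, 3, 4, 5]), pep("b", "nucleus", [1, 2, 3, 4, 5])]
        with pytest.raises(ValueError, match="incomplete"):
            build_dynamics_network(peps, 0.9)

    def test_equals_brute_force_scan_on_synthetic_clusters(self):
        cfg = SimConfig(n_peptides=200, n_modules=4, missing_rate=0.0, seed=11)
        _, _, _, peptides, _ = generate_dataset(cfg)
        g = build_dynamics_network(peptides, threshold=0.99)
        expected = brute_force_edges([p.profile for p in peptides], 0.99)
        got = set()
        index = {p.node_id: i for i, p in enumerate(peptides)}
        for u, v in g.edges():
            i, j = sorted((index[u], index[v]))
            got.add((i, j))
        assert got == expected

    def test_threshold_monotonicity(self):
        cfg = SimConfig(n_peptides=150, n_modules=5, missing_rate=0.0, seed=3)
        _, _, _, peptides, _ = generate_dataset(cfg)
        edges = {}
        for t in (0.97, 0.98, 0.99):
            g = build_dynamics_network(peptides, threshold=t)
            edges[t] = {frozenset(e) for e in g.edges()}
        assert edges[0.99] <= edges[0.98] <= edges[0.97]


class TestFractionSubnetwork:
    def test_path_c_n_c_leaves_two_isolated_cytoplasmic_nodes(self):
        peps = [
            pep("a", "cytoplasm", [1, 2, 5, 3, 1]),
            pep("b", "nucleus", [1, 2, 5, 3, 1]),
            pep("c", "cytoplasm", [1, 2, 5, 3, 1]),
        ]
        g = build_dynamics_network(peps, threshold=0.99)  # triangle across fractions
        g.remove_edge(("a", "cytoplasm"), ("c", "cytoplasm"))  # make it a C-N-C path
        sub = fraction_subnetwork(g, "cytoplasm")
        assert sub.number_of_nodes() == 2 and sub.number_of_edges() == 0

    def test_all_cytoplasmic_triangle_is_identity(self):
        peps = [pep(f"p{i}", "cytoplasm", [1, 2, 5, 3, 1]) for i in range(3)]
        g = build_dynamics_network(peps, threshold=0.99)
        sub = fraction_subnetwork(g, "cytoplasm")
        assert set(sub.nodes()) == set(g.nodes())
        assert set(map(frozenset, sub.edges())) == set(map(frozenset, g.edges()))

    def test_unknown_fraction_is_an_error(self, labeled_graph):
        with pytest.raises(ValueError, match="unknown fraction"):
            fraction_subnetwork(labeled_graph, "membrane")

    def test_subnetworks_partition_parent_nodes_and_match_brute_force(self, purity_network):
        net = purity_network.network
        cyto = fraction_subnetwork(net, "cytoplasm")
        nuc = fraction_subnetwork(net, "nucleus")
        assert cyto.number_of_nodes() + nuc.number_of_nodes() == net.number_of_nodes()
        for sub, f in ((cyto, "cytoplasm"), (nuc, "nucleus")):
            exp_nodes = {n for n, d in net.nodes(data=True) if d["fraction"] == f}
            exp_edges = {
                frozenset((u, v))
                for u, v in net.edges()
                if u in exp_nodes and v in exp_nodes
            }
            assert set(sub.nodes()) == exp_nodes
            assert {frozenset(e) for e in sub.edges()} == exp_edges
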