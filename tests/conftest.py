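import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phosphodyn import PhosphoDynamicsModel, SimConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# canonical scaled-down study configurations ---------------------------------
# clustered kinetics without a cascade: used for motif / localization analyses
def purity_config(fraction_purity: float, seed: int) -> SimConfig:
    return SimConfig(
        n_peptides=200,
        n_modules=8,
        noise_sd=0.08,
        cascade_delay=0.0,
        fraction_purity=fraction_purity,
        seed=seed,
    )


# chained kinetics: cascade depth shifts the pulse by one minute per step, so
# pathway distance maps onto correlation distance; threshold 0.95 matches the
# one-step correlation (~0.97) while two-step shifts fall below it
CASCADE_THRESHOLD = 0.95


def cascade_config(seed: int) -> SimConfig:
    return SimConfig(
        n_peptides=120,
        n_modules=4,
        noise_sd=0.02,
        cascade_delay=1.0,
        peptides_per_protein=(1, 2),
        seed=seed,
    )


@pytest.fixture(scope="session")
def purity_dataset():
    """One assortative synthetic dataset (fraction_purity 0.95, seed 1)."""
    return generate_dataset(purity_config(0.95, seed=1))


@pytest.fixture(scope="session")
def purity_network(purity_dataset):
    _, _, _, peptides, _ = purity_dataset
    return PhosphoDynamicsModel(peptides, threshold=0.99).fit()


@pytest.fixture()
def labeled_graph():
    """Small hand-made labeled graph: a C-clique glued to an N-clique."""
    g = nx.Graph()
    cyto = [("c%d" % i, "cytoplasm") for i in range(4)]
    nuc = [("n%d" % i, "nucleus") for i in range(3)]
    for n in cyto + nuc:
        g.add_node(n, fraction=n[1], peptide_id=n[0], protein="P_" + n[0])
    for i in range(4):
        for j in range(i + 1, 4):
            g.add_edge(cyto[i], cyto[j])
    for i in range(3):
        for j in range(i + 1, 3):
            g.add_edge(nuc[i], nuc[j])
    g.add_edge(cyto[0], nuc[0])
    return g


def random_labeled_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph with i.i.d. fraction labels, for oracle comparisons."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    rng = np.random.default_rng(seed + 1)
    labels = rng.choice(["cytoplasm", "nucleus"], size=n)
    h = nx.Graph()
    for i in g.nodes():
        h.add_node(i, fraction=str(labels[i]))
    h.add_edges_from(g.edges())
    return h
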