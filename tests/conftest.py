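import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mprsnet.network import WeightedNetwork


@pytest.fixture
def path_network():
    """3-gene path A-B-C with simple weights."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return WeightedNetwork(graph=g, weights={"A": 1.0, "B": 2.0, "C": 0.5})


@pytest.fixture
def random_network():
    """Connected 50-node random graph with uniform random weights."""
    rng = np.random.default_rng(7)
    g = nx.gnp_random_graph(50, 0.12, seed=11)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    g = nx.relabel_nodes(g, {n: f"g{n:02d}" for n in g.nodes})
    weights = {n: float(rng.uniform(0, 3)) for n in g.nodes}
    return WeightedNetwork(graph=g, weights=weights)


@pytest.fixture
def sumstats_frame():
    return pd.DataFrame({
        "snp_id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "2"],
        "pos": [100, 200, 300],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "T"],
        "beta": [0.5, -1.0, 2.0],
        "p_value": [1e-4, 0.3, 0.01],
    })
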