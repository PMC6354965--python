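import numpy as np
import pandas as pd
import pytest

from prnfs.network import Network, build_matrices
from prnfs.simulate import (GeneratorConfig, SurvivalData, generate_grn,
                            simulate_study)

import networkx as nx


def make_network(edges, nodes=None) -> Network:
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from((u, v, {"weight": w}) for u, v, w in edges)
    return Network(g)


@pytest.fixture(scope="session")
def small_study():
    """Compact simulated cohort shared by selection/benchmark tests."""
    net = generate_grn(30, 2, seed=5)
    cfg = GeneratorConfig(
        n_samples=140,
        n_features_per_level={"GE": 60, "DM": 60, "CNA": 60},
        effect_size=1.2,
        level_split={"GE": 1.0, "DM": 0.7, "CNA": 0.4},
        seed=11,
    )
    return simulate_study(net, cfg, signature_size=8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_graph(rng, n_max=50, p=0.15) -> Network:
    """Random Gnp network (possibly with isolated nodes)."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:03d}" for i in g.nodes})
    h = nx.Graph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from((u, v, {"weight": 1.0}) for u, v in g.edges)
    return Network(h)


def random_survival(rng, n=80, censor=0.25) -> SurvivalData:
    idx = pd.Index([f"s{i}" for i in range(n)])
    t = rng.exponential(1000.0, n)
    c = rng.exponential(1000.0 * (1 - censor) / censor, n) if censor else np.inf
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return SurvivalData(pd.Series(time, index=idx), pd.Series(event, index=idx))
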