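import numpy as np
import pytest

from fgrnet import data_io, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def toy_net():
    """Small fixed signed network: 3 regulators, 8 genes."""
    edges = [
        ("TF1", "G1", "activation"),
        ("TF1", "G2", "repression"),
        ("TF2", "G2", "activation"),
        ("TF2", "G3", "activation"),
        ("TF3", "G4", "repression"),
    ]
    return data_io.SignedNetwork(edges, node_ids=["TF1", "TF2", "TF3",
                                                  "G1", "G2", "G3", "G4", "G5"])


@pytest.fixture(scope="session")
def toy_expr(toy_net):
    rng = np.random.default_rng(1)
    values = rng.random((len(toy_net.node_ids), 12))
    expr = data_io.ExpressionMatrix(list(toy_net.node_ids), values,
                                    [f"s{i}" for i in range(12)])
    return data_io.normalize(expr)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated benchmark shared by slower tests."""
    cfg = synthetic.SimulationConfig(n_genes=60, n_regulators=8, n_edges=90,
                                     n_samples=60, noise_sd=0.3, seed=7)
    net, expr = synthetic.simulate(cfg)
    samples = data_io.build_pair_samples(expr, net, negative_ratio=1.0, seed=7)
    return cfg, net, expr, samples
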