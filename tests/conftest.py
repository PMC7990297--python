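import numpy as np
import pytest

import sociomort as sm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def path_graph():
    """Three districts in a line: 0-1-2."""
    return sm.build_graph([("a", "b"), ("b", "c")], ["a", "b", "c"])


@pytest.fixture(scope="session")
def hk():
    return sm.hk_graph()


@pytest.fixture(scope="session")
def small_sim():
    """A small 6-district dataset for quick end-to-end runs."""
    cfg = sm.SimConfig(n_districts=6, graph_kind="grid", seed=7,
                       category="base", variant="baseline")
    panel, graph, truth = sm.simulate_dataset(cfg)
    return cfg, panel, graph, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default 18-district study conditions (baseline variant)."""
    cfg = sm.SimConfig(seed=11, category="base", variant="baseline")
    panel, graph, truth = sm.simulate_dataset(cfg)
    return cfg, panel, graph, truth


def random_design(spec, rng):
    X = rng.standard_normal((spec.T, spec.N, spec.k))
    X[:, :, 0] = 1.0
    F = None
    if spec.variant != "baseline":
        F = rng.standard_normal((spec.T, spec.N, spec.g))
    Y = rng.standard_normal((spec.N, spec.T))
    return X, F, Y
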