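import numpy as np
import pandas as pd
import pytest

from dimflow.graph import ConnectomeGraph
from dimflow.synth import (PairedGenConfig, SensorimotorGenConfig,
                           generate_paired_connectomes,
                           generate_sensorimotor_graph)


def make_graph(edges, types=None, level="type", neurons=None, dataset=None):
    """Build a ConnectomeGraph from (pre, post, left, right) tuples."""
    df = pd.DataFrame(edges, columns=["pre", "post", "weight_left", "weight_right"])
    return ConnectomeGraph(df, types=types, neurons=neurons, level=level,
                           dataset=dataset)


def random_graph(rng, n_nodes=10, density=0.3, max_w=20):
    nodes = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < density:
                w = rng.integers(1, max_w + 1)
                l = rng.integers(0, w + 1)
                edges.append((u, v, int(l), int(w - l)))
    if not edges:
        edges = [(nodes[0], nodes[1], 1, 0)]
    return make_graph(edges)


@pytest.fixture(scope="session")
def paired_default():
    """One default paired male/female connectome with planted truth."""
    return generate_paired_connectomes(PairedGenConfig(seed=11))


@pytest.fixture(scope="session")
def sensorimotor_default():
    """One default layered sensorimotor graph with planted routes."""
    return generate_sensorimotor_graph(SensorimotorGenConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
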