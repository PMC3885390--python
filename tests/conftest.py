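import networkx as nx
import numpy as np
import pytest

from dynregnet.simulate import generate_expression, make_ground_truth


@pytest.fixture(scope="session")
def small_truth():
    """Compliant synthetic study: 5 TFs, 60 TGs, 11 time points, noiseless."""
    return make_ground_truth(
        n_tfs=5, n_tgs=60, targets_per_tf=8, tf_tf_edges=0, noise_sd=0.0, seed=3
    )


@pytest.fixture(scope="session")
def small_expression(small_truth):
    return generate_expression(small_truth, n_replicates=2)


def random_digraph(rng: np.random.Generator, max_nodes: int = 12, p: float = 0.25):
    n = int(rng.integers(4, max_nodes + 1))
    return nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)), directed=True)
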