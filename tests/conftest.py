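import numpy as np
import pytest

from glvsim import (
    InteractionMap,
    MatrixGenConfig,
    NodeSpec,
    SimulationConfig,
    random_nodes,
    sample_interaction_matrix,
)


@pytest.fixture
def logistic_system():
    """1-D noiseless logistic node: dz/dt = z(1 - 0.5 z), fixed point 2.0."""
    node = NodeSpec("n", 1, np.array([1.0]), np.array([0.1]))
    imap = InteractionMap({("n", "n"): np.array([[-0.5]])})
    return node, imap


@pytest.fixture
def small_community():
    """A stable 8-dim single-node random community with known parameters."""
    dims = {"mg": 8}
    nodes = random_nodes(dims, seed=11)
    imap = sample_interaction_matrix(
        dims, MatrixGenConfig(connectivity=0.5, self_penalty=1.0, pair_var=0.25, seed=12)
    )
    return nodes, imap, dims


@pytest.fixture
def quiet_sim_config():
    """Short noiseless simulation settings for deterministic comparisons."""
    return SimulationConfig(n_timepoints=30, dt=0.01, noise_var=0.0, n_reads=500, seed=7)
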