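import numpy as np
import pytest

import chondronet as cn
from chondronet.pipeline import lr_planted_spec, modules_planted_spec


@pytest.fixture(scope="session")
def small_sim():
    """800-cell, 800-gene demonstration pellet with QC-able low-quality tail."""
    spec = cn.demo_simulation_spec(n_cells=800, n_genes=800, seed=1)
    return cn.simulate_counts(spec)


@pytest.fixture(scope="session")
def small_norm(small_sim):
    cm, truth = small_sim
    filtered, _ = cn.apply_cell_qc(cm)
    return filtered, cn.log_normalize(filtered), truth


@pytest.fixture(scope="session")
def modules_sim():
    """Four planted 50-gene modules at loading 0.8, 500 cells."""
    return cn.simulate_counts(modules_planted_spec(seed=0))


@pytest.fixture(scope="session")
def lr_sim():
    """Three populations with three planted directed WNT/FZD interactions."""
    return cn.simulate_counts(lr_planted_spec(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
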