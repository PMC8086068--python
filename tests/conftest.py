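import numpy as np
import pandas as pd
import pytest

from mimqtl import OmicsMatrix, SimulationConfig
from mimqtl.simulate import simulate_cohorts


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_config():
    """Desk-scale study small enough for per-test pipelines."""
    return SimulationConfig(
        n_samples=(120, 150),
        n_normals=10,
        n_mirnas=40,
        n_cpgs=160,
        mirna_cluster_sizes=(6, 8, 6),
        cpg_cluster_sizes=(40, 36),
        n_decoy_loops=10,
        seed=7,
    )


@pytest.fixture
def small_cohorts(small_config):
    return simulate_cohorts(small_config)


def make_matrix(values, kind="methylation", features=None, samples=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return OmicsMatrix(pd.DataFrame(values, index=features, columns=samples), kind)


@pytest.fixture
def make_omics():
    return make_matrix
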