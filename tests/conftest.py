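import numpy as np
import pytest
from hypothesis import settings

import semidecon as sd

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def expr(values, genes=None, cols=None, unit="counts"):
    """Shorthand ExpressionMatrix constructor for tests."""
    values = np.asarray(values, dtype=float)
    m, p = values.shape
    genes = genes or [f"g{i + 1}" for i in range(m)]
    cols = cols or [f"c{j + 1}" for j in range(p)]
    return sd.ExpressionMatrix(values, genes, cols, unit)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """m=200 genes, 5 known + 1 unknown types, 4 samples, no noise."""
    cfg = sd.SimulationConfig(
        n_genes=200, n_samples=4, n_known=5, n_unknown=1,
        component_noise_scale=0.0, fraction_noise_scale=0.0, seed=0,
    )
    return sd.simulate_bulk(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same shape with the default noise multipliers."""
    cfg = sd.SimulationConfig(n_genes=200, n_samples=4, n_known=5, n_unknown=1, seed=0)
    return sd.simulate_bulk(cfg)
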