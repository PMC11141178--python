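import numpy as np
import pandas as pd
import pytest

from acnadi.config import GeneratorConfig, RaceBlock, default_config


def small_config(seed: int = 0, n_tracts: int = 120, n_ea: int = 400, n_aa: int = 300) -> GeneratorConfig:
    """Scaled-down two-stratum configuration for fast end-to-end tests."""
    cfg = default_config(seed=seed)
    cfg.n_tracts = n_tracts
    cfg.race_blocks["EA"].n_subjects = n_ea
    cfg.race_blocks["AA"].n_subjects = n_aa
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def logistic_data(rng):
    """Simulated logistic data with two real and two null covariates."""
    n = 500
    X = pd.DataFrame(rng.standard_normal((n, 4)), columns=["a", "b", "c", "d"])
    eta = -1.0 + 0.8 * X["a"] - 0.5 * X["b"]
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    return X, y
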