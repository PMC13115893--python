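import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from oamethyl.cohort import SimulationConfig, generate_cohort
from oamethyl.fusion import FusionModelConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure, shared across tests."""
    cfg = SimulationConfig(n_cases=60, n_controls=30, n_cpg=500, n_dm=40,
                           delta_beta=0.25, n_genes=80, n_effector_genes=15,
                           seed=11)
    return generate_cohort(cfg)


@pytest.fixture()
def tiny_fusion_config():
    """Fast fusion-model configuration for training tests."""
    return FusionModelConfig(d_model=16, cnn_out=16, fusion_dim=16,
                             n_heads=2, n_layers=1, ff_dim=32,
                             kernel_sizes=(5, 3), cnn_channels=(8,),
                             dropout=0.1, max_epochs=40, patience=10,
                             seed=0)


def separable_data(n=120, n_features=20, effect=0.5, noise=0.05, seed=0):
    """Two informative features shifted by `effect` in cases; the rest is
    uniform noise. Near-perfect linear separability at the defaults."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.uniform(0.2, 0.8, size=(n, n_features))
    X[:, :2] = 0.3 + effect * y[:, None] + rng.normal(0, noise, (n, 2))
    return np.clip(X, 0.0, 1.0), y
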