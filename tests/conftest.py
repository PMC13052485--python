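"""Shared fixtures: tiny model configurations and small synthetic cohorts.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from ramanadapt import synthetic as syn
from ramanadapt.resnet1d import ModelConfig, build_model


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return syn.default_grid()


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """Smallest 6-block architecture (full group structure, fast training)."""
    return ModelConfig(input_length=256, initial_filters=4, block_channels=(4,) * 6)


@pytest.fixture()
def tiny_model(tiny_config):
    return build_model(tiny_config, seed=0)


@pytest.fixture(scope="session")
def target_cohort():
    """Raw prospective-style prostate cohort: 10 patients, strong baseline."""
    return syn.generate_cohort(syn.prostate_target_domain(), 10, (7, 18), seed=42)


@pytest.fixture(scope="session")
def labelled_features():
    """A simple separable feature problem for the classical baselines."""
    rng = np.random.default_rng(7)
    x = rng.normal(size=(200, 5))
    margin = x[:, 0] + 0.5 * x[:, 1]
    x = x[np.abs(margin) > 0.6][:80]  # separable with a clear margin
    y = (x[:, 0] + 0.5 * x[:, 1] > 0).astype(int)
    return x, y
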