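"""Shared fixtures.

The heavy full-scale runs (prototype generation and the three-condition
categorization of the 66-rhythm grid) are session-scoped so the
acceptance-level tests and the classification examples share one
computation.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhythmcat import (DUPLE, NO_METER, TRIPLE, ModelConfig, build_prototypes,
                       categorize_condition, generate_grid)

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


@pytest.fixture(scope="session")
def tiny_config() -> ModelConfig:
    """A 5-oscillator, 200-Hz configuration for cheap pipeline tests."""
    cfg = ModelConfig()
    return replace(cfg,
                   bank=replace(cfg.bank, n=5),
                   encode=replace(cfg.encode, sample_rate_hz=200.0),
                   integrate=replace(cfg.integrate, step_hz=200.0))


@pytest.fixture(scope="session")
def grid66():
    return generate_grid()


@pytest.fixture(scope="session")
def default_prototypes(default_config):
    return build_prototypes(config=default_config)


@pytest.fixture(scope="session")
def condition_categorizations(grid66, default_prototypes, default_config):
    """Full-pipeline category maps for all three meter conditions."""
    return {cond.name: categorize_condition(grid66, cond, default_prototypes,
                                            default_config)
            for cond in (NO_METER, DUPLE, TRIPLE)}
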