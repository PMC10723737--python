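from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from phytomapper import (
    SimulationConfig,
    fit_reference_model,
    residual_lens,
    select_reference,
    simulate_expression,
    simulate_metadata,
    y_point_cloud,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def synthetic(default_cfg):
    """(metadata, TPM matrix, truth) under the default study conditions."""
    meta = simulate_metadata(default_cfg)
    X, truth = simulate_expression(default_cfg, meta)
    return meta, X, truth


@pytest.fixture(scope="session")
def stress_lens(synthetic):
    """Stress lens values fit on the healthy reference samples."""
    meta, X, _ = synthetic
    model = fit_reference_model(X, select_reference(meta, "stress"))
    return residual_lens(X, model)


@pytest.fixture(scope="session")
def y_cloud():
    return y_point_cloud()
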