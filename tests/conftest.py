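import numpy as np
import pytest

from mrarfi import (
    AcquisitionParams,
    ComplexImageSeries,
    Grid,
    SimulationConfig,
    TriggerSchedule,
    build_basis,
    default_params,
    simulate,
)


@pytest.fixture
def params() -> AcquisitionParams:
    return default_params()


@pytest.fixture
def small_series(params) -> ComplexImageSeries:
    """A tiny random alternating-contrast series for contract tests."""
    rng = np.random.default_rng(42)
    data = rng.normal(size=(6, 5, 4)) + 1j * rng.normal(size=(6, 5, 4))
    return ComplexImageSeries(
        data=data,
        grid=Grid(),
        schedule=TriggerSchedule((0, 1, 0, 1, 0, 1)),
        params=params,
    )


@pytest.fixture
def clean_sim():
    """Noiseless, drift-free simulation with a 200 nm focus (16×16, Nt=8)."""
    config = SimulationConfig(
        seed=7, grid_shape=(16, 16), n_timepoints=8,
        noise_std=0.0, drift_poly_std=0.0, drift_highorder_std=0.0,
    )
    series, truth = simulate(config)
    return series, truth, build_basis(config.grid_shape, 2)
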