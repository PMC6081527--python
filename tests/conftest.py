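import time

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stenoflow import (
    AcquisitionSettings,
    ExperimentConfig,
    FlowProgram,
    InjectionProtocol,
    PhantomGeometry,
    TransportModel,
    project_to_images,
    simulate_transport,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_experiment():
    """One full default bench experiment (4 grades x 3 replicates, seed 0).

    Shared by the pipeline and acceptance tests; the wall time is recorded
    so the runtime budget can be asserted.
    """
    from stenoflow import run_experiment

    t0 = time.monotonic()
    result = run_experiment(ExperimentConfig())
    elapsed = time.monotonic() - t0
    return result, elapsed


def small_run(
    grade: int = 0,
    duration: float = 6.0,
    pixel_size: float = 0.5,
    noise_sd: float = 0.0,
    lateral_profile: str = "parabolic",
    seed: int = 0,
    **model_overrides,
):
    """A cheap single simulated series for unit tests (coarse grid, short)."""
    geometry = PhantomGeometry.for_grade(grade)
    flow = FlowProgram()
    injection = InjectionProtocol()
    acq = AcquisitionSettings(duration=duration, pixel_size=pixel_size, noise_sd=noise_sd, seed=seed)
    model = TransportModel(**model_overrides)
    field = simulate_transport(
        geometry, flow, injection, duration=duration, model=model, output_times=acq.timestamps()
    )
    series = project_to_images(
        field, geometry, acq, lateral_profile=lateral_profile,
        meta={"injection_start": injection.start_time},
    )
    return field, series


@pytest.fixture(scope="session")
def small_series():
    """Noise-free nonstenotic short run shared across extraction tests."""
    return small_run()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
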