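import numpy as np
import pytest

import tripgrid as tg


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared across tests (10 drivers, 2 trips)."""
    cfg = tg.SimulationConfig(
        n_drivers=10, abnormal_fraction=0.5, trips_per_driver=2,
        trip_duration_s=120, seed=11,
    )
    telemetry, labels, manifest = tg.simulate_cohort(cfg)
    return telemetry, labels, manifest


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    telemetry, labels, _ = small_cohort
    return tg.build_dataset(telemetry, labels, tg.desk_scale_conditions())


def random_walk_segment(rng, n=13, lat0=26.4, lon0=-80.1, step_deg=2e-4):
    """Random-walk lat/lon arrays for gridding tests."""
    steps = rng.normal(0.0, step_deg, size=(n, 2))
    steps[0] = 0.0
    path = np.cumsum(steps, axis=0)
    return lat0 + path[:, 0], lon0 + path[:, 1]
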