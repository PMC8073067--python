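import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from satgai import scenarios, synth

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

d = dt.date


@pytest.fixture(scope="session")
def small_config():
    """A reduced trial (40 m × 40 m, 12 plots, 5+4 acquisitions)."""
    return synth.SyntheticConfig(
        seed=7,
        field_width=40.0,
        field_height=40.0,
        uav_pixel=0.5,
        uav_dates=(
            d(2019, 3, 15), d(2019, 4, 14), d(2019, 5, 14),
            d(2019, 6, 13), d(2019, 7, 8),
        ),
        # Apr 28 has no UAV flight within 5 days
        satellite_dates=(
            d(2019, 3, 18), d(2019, 4, 28), d(2019, 6, 10), d(2019, 7, 6),
        ),
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synth.SyntheticStudy(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_study):
    return scenarios.StudyBundle(small_study)


@pytest.fixture(scope="session")
def aligned_config():
    """Noise-free, bias-free study whose 20 m plots tile the grid exactly."""
    cfg = synth.SyntheticConfig.loop_closure(seed=3)
    return synth.dataclasses.replace(
        cfg,
        field_width=40.0,
        field_height=40.0,
        uav_dates=(
            d(2019, 3, 15), d(2019, 4, 14), d(2019, 5, 14),
            d(2019, 6, 13), d(2019, 7, 8),
        ),
        satellite_dates=(d(2019, 3, 18), d(2019, 6, 10), d(2019, 7, 6)),
    )


@pytest.fixture(scope="session")
def aligned_study(aligned_config):
    return synth.SyntheticStudy(aligned_config)


@pytest.fixture(scope="session")
def aligned_bundle(aligned_study):
    return scenarios.StudyBundle(aligned_study)
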