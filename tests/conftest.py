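import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

import _study  # noqa: E402
from scoutdose.phantom_sim import GridSpec, make_cylinder_phantom  # noqa: E402


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec((80.0, 80.0), (1.0, 1.0), 10.0)


@pytest.fixture(scope="session")
def water_cylinder(small_grid):
    """40 mm water cylinder on a small grid: the workhorse unit fixture."""
    return make_cylinder_phantom(40.0, 1.0, small_grid)


@pytest.fixture(scope="session")
def clean_calibration():
    """Calibration fitted on the standard phantom family at the clean noise
    condition (gain-SNR 100)."""
    return _study.build_calibration(_study.CLEAN_SIGMA, _study.HU_SIGMA, base_seed=20)


@pytest.fixture(scope="session")
def noiseless_calibration():
    """Calibration fitted with zero localizer and HU noise."""
    return _study.build_calibration(0.0, 0.0, base_seed=0)
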