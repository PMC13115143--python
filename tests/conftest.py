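import pytest
from hypothesis import HealthCheck, settings

# Fixtures used under @given are immutable frozen dataclasses, so reuse
# across generated examples is safe.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")

from freshlabel import PUBLISHED_CALIBRATION, ShelfLifeModel, SimulationConfig


@pytest.fixture(scope="session")
def published_model():
    return ShelfLifeModel.published()


@pytest.fixture(scope="session")
def published_calibration():
    return PUBLISHED_CALIBRATION


@pytest.fixture
def noiseless_config():
    """Study config with every noise source off: trajectories are exact."""
    return SimulationConfig(noise_sigma_ln=0.0, a0_sd=0.0, color_noise_sd=0.0, seed=7)


#: The published validation table: (temperature °C, time h, ΔE, predicted h,
#: observed h, RE %). The two rows whose printed predictions do not follow
#: from the printed model constants are marked non-reproducible.
TABLE3 = [
    # (T, time, dE, printed_pred, observed, printed_re, reproducible)
    (4.0, 24.0, 6.8, 81.2, 75.0, 8.3, True),
    (4.0, 48.0, 9.9, 54.0, 50.0, 8.0, True),
    (4.0, 72.0, 14.5, 25.9, 24.0, 7.9, True),
    (10.0, 10.0, 5.3, 57.6, 53.0, 8.7, True),
    (10.0, 26.0, 8.5, 37.9, 36.0, 5.3, True),
    (10.0, 36.0, 11.3, 26.3, 24.0, 9.6, False),
    (20.0, 10.0, 9.4, 14.7, 14.0, 5.0, False),
    (20.0, 15.0, 11.4, 10.8, 10.0, 8.0, True),
    (20.0, 20.0, 15.3, 5.4, 5.0, 8.0, True),
]


@pytest.fixture(scope="session")
def table3():
    return TABLE3
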