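import pytest

from raidose.cohort import CohortConfig, generate_cohort
from raidose.retention import ExposureReading, fit_two_point_retention


@pytest.fixture(scope="session")
def worked_model():
    """The worked two-point fit: 200 μSv/h at 2 h falling to 10 μSv/h at 67 h."""
    return fit_two_point_retention(
        ExposureReading(2.0, 200.0), ExposureReading(67.0, 10.0)
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(n_patients=20, seed=42))
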