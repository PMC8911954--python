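import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    from wineomics.io_formats import load_table1_fixture

    return load_table1_fixture()


@pytest.fixture(scope="session")
def standards():
    from wineomics.synthetic_data import make_standards_catalog

    return make_standards_catalog(seed=0)


@pytest.fixture(scope="session")
def alkane_cal():
    """Retention-index calibration from a deconvolved simulated alkane run."""
    from wineomics.deconvolution import deconvolve
    from wineomics.retention_index import calibrate
    from wineomics.synthetic_data import simulate_alkane_run

    return calibrate(deconvolve(simulate_alkane_run(seed=7)))


@pytest.fixture(scope="session")
def validation_scenario():
    from wineomics.scenarios import scenario_validation

    return scenario_validation(seed=42)


@pytest.fixture(scope="session")
def replay_scenario():
    from wineomics.scenarios import scenario_table1_replay

    return scenario_table1_replay(seed=42)
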