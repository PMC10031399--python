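import pytest

from welfarelca.aggregation import WQAssessment
from welfarelca.production import ProductionRecord
from welfarelca.synth import default_config, generate_population


@pytest.fixture
def example_record() -> ProductionRecord:
    """100-sow herd with realistic throughput; used by hand-arithmetic oracles."""
    return ProductionRecord(
        sows_avg=100.0,
        born_alive_per_year=2400.0,
        weaned_per_year=2200.0,
        weaning_age=28.0,
        slaughtered_per_year=2100.0,
        slaughter_age=180.0,
        deadweight_per_pig=88.0,
        cull_sows_per_year=45.0,
        cull_sow_deadweight=75.0,
        price_fattening=1.60,
        price_cull=0.80,
    )


@pytest.fixture
def assessment_sp() -> WQAssessment:
    return WQAssessment(60.0, 70.0, 80.0, 50.0)


@pytest.fixture
def assessment_fp() -> WQAssessment:
    return WQAssessment(40.0, 60.0, 70.0, 30.0)


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population, shared across tests."""
    return generate_population(default_config(), seed=20230120)
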