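import pytest

from ct4dnr import StudyConfig, run_dose_reduction, run_preliminary, run_quantitative

MASTER_SEED = 1


@pytest.fixture(scope="session")
def quantitative_report():
    """Base-dose quantitative study at the study's standard conditions."""
    return run_quantitative(StudyConfig.quantitative(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def preliminary_report():
    """Interval-sweep preliminary study at the standard conditions."""
    return run_preliminary(StudyConfig.preliminary(seed=MASTER_SEED))


@pytest.fixture(scope="session")
def dose_report():
    """Dose-reduction study at the standard conditions."""
    return run_dose_reduction(StudyConfig.dose_reduction(seed=MASTER_SEED))
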