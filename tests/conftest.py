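import pytest

from tempotrain import (
    GeneratingParams,
    PsychometricCurve,
    StaircaseConfig,
    cohort_frame,
    run_study,
    sample_cohort,
)


@pytest.fixture(scope="session")
def params():
    return GeneratingParams()


@pytest.fixture(scope="session")
def staircase_config():
    return StaircaseConfig()


@pytest.fixture(scope="session")
def demo_curve():
    """Mid-range observer used throughout: 50% keywords at 40% compression."""
    return PsychometricCurve(threshold_c50=40.0, slope=0.15, lapse=0.0)


@pytest.fixture(scope="session")
def fixture_cohort(params):
    return sample_cohort(14, params, demographics_source="fixture", rng_seed=7)


@pytest.fixture(scope="session")
def fixture_cohort_frame(fixture_cohort):
    return cohort_frame(fixture_cohort)


@pytest.fixture(scope="session")
def threshold_study(params, fixture_cohort):
    """One full study in direct threshold-draw mode."""
    return run_study(fixture_cohort, params, rng_seed=11, mode="threshold_level")


@pytest.fixture(scope="session")
def parametric_cohort(params):
    return sample_cohort(14, params, demographics_source="parametric", rng_seed=19)


@pytest.fixture(scope="session")
def trial_study(params, parametric_cohort):
    """One full study running the staircase + psychometric fit per block."""
    return run_study(parametric_cohort, params, rng_seed=23, mode="trial_level")
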