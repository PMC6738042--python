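import pytest
from hypothesis import settings

from ovascreen import Cohort, CohortConfig, build_training_set, generate_cohort, score_cohort

settings.register_profile("ci", deadline=None, derandomize=True, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """Default-sized synthetic cohort (80 subjects, ~480 samples), aligned."""
    subjects, samples = generate_cohort(CohortConfig(rng_seed=7))
    return Cohort(subjects, samples, aligned=True)


@pytest.fixture(scope="session")
def scored_default(default_cohort):
    """(scores, thresholds, baselines) for the default cohort."""
    return score_cohort(default_cohort)


@pytest.fixture(scope="session")
def default_training(default_cohort, scored_default):
    scores, _, _ = scored_default
    return build_training_set(default_cohort, scores)
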