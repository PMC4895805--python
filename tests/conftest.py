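import numpy as np
import pytest
from hypothesis import settings

from mtxresponse import CohortConfig, Visit, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def score_visits(months, scores):
    """Visit series with injected DAS28 scores (no components)."""
    return [Visit(month=float(m), das28=float(s)) for m, s in zip(months, scores)]


def flat_visits(level, months=range(0, 13)):
    """Constant-score trajectory sampled at the given months."""
    ms = list(months)
    return score_visits(ms, [level] * len(ms))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Well-separated, noise-free cohort: labels are unambiguous."""
    return generate_cohort(
        CohortConfig(
            seed=11,
            baseline_das28_sd=0.3,
            good_decline_rate=1.0,
            poor_decline_rate=0.02,
            measurement_noise_sd=0.0,
            weekly_dose_levels=(8.0,),
        )
    )


def rng(seed=0):
    return np.random.default_rng(seed)
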