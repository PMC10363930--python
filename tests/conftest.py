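import math

import pytest

import combopos as cp

TARGET_EFFECT = -math.log(0.75)  # 0.287682...


@pytest.fixture
def trial_outcome():
    """The observed Phase III study: HR 0.68, 604 events, 1:1, on component 2."""
    return cp.score_from_survival(0.68, 604, 1.0, component=1)


@pytest.fixture
def planned_design():
    """Planned study: two-sided alpha 0.05, 80% power against HR 0.75."""
    return cp.PlannedDesign.from_power(0.05, 0.8, TARGET_EFFECT)


def make_prior(rho: float = 0.6) -> cp.MvnBelief:
    """Bivariate prior: both means -log(0.75), variances 0.08."""
    return cp.pair_belief(TARGET_EFFECT, TARGET_EFFECT, 0.08, 0.08, rho,
                          labels=("A+B", "A+C"))


@pytest.fixture
def pair_prior():
    return make_prior(0.6)
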