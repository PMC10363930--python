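"""Score-statistic summaries of trial results and planned-study information.

A completed trial is reduced to the pair ``(Z, V)`` — efficient score and
Fisher information — under the standard large-sample approximations
``Z ~ N(V * theta, V)`` and ``theta_hat = Z / V ~ N(theta, 1/V)``.  For a
survival endpoint with ``e`` events and an ``R:1`` allocation ratio,

    V ≈ e * R / (R + 1)^2,      Z = -V * log(HR),

so the effect scale is the negative natural-log hazard ratio (positive
favours the experimental arm).  The information of a planned study powered
at ``1 - beta`` for a two-sided test at level ``alpha`` against a target
effect ``theta*`` is ``((z_{1-alpha/2} + z_{power}) / theta*)^2``.
"""

from __future__ import annotations

import math

from scipy.stats import norm

from .beliefs import StudyOutcome

__all__ = [
    "score_from_survival",
    "info_from_design",
    "info_from_normal_endpoint",
    "effect_estimate",
]


def score_from_survival(
    hazard_ratio: float,
    events: int,
    allocation_ratio: float = 1.0,
    component: int = 0,
) -> StudyOutcome:
    """Convert a survival-trial summary to a score-statistic outcome.

    Parameters
    ----------
    hazard_ratio : float
        Observed hazard ratio (experimental vs control), > 0.
    events : int
        Number of observed events, >= 1.
    allocation_ratio : float
        R for an R:1 experimental:control allocation.  The information is
        symmetric in R <-> 1/R, so either orientation gives the same value.
    component : int
        Index of the observed combination in the joint belief.

    Returns
    -------
    StudyOutcome
        With ``information = events * R / (R+1)^2`` and
        ``score = -information * ln(hazard_ratio)``.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be strictly positive")
    if events < 1:
        raise ValueError("event count must be at least 1")
    if allocation_ratio <= 0:
        raise ValueError("allocation ratio must be strictly positive")
    r = allocation_ratio
    information = events * r / (r + 1.0) ** 2
    score = -information * math.log(hazard_ratio)
    return StudyOutcome(component=component, score=score, information=information)


def info_from_design(alpha: float, power: float, target_effect: float) -> float:
    """Fisher information implied by (alpha, power, target effect).

    Returns ``((z_{1-alpha/2} + z_{power}) / target_effect)^2`` with
    full-precision normal quantiles.  ``target_effect`` is on the effect
    scale, e.g. ``-log`` of the target hazard ratio.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if target_effect == 0:
        raise ValueError("target effect must be nonzero")
    z_a = norm.ppf(1.0 - alpha / 2.0)
    z_b = norm.ppf(power)
    return float(((z_a + z_b) / target_effect) ** 2)


def info_from_normal_endpoint(n_total: int) -> float:
    """Information of a 1:1 trial with unit-variance normal responses: n/4."""
    if n_total < 2:
        raise ValueError("need at least 2 patients")
    return n_total / 4.0


def effect_estimate(outcome: StudyOutcome) -> float:
    """Effect estimate ``theta_hat = Z / V``."""
    return outcome.effect
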