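"""Assurance: the probability of success of a planned frequentist study.

The assurance is the power of the planned study averaged over the current
normal belief about the treatment effect,

    PoS = Integral P(study success | theta) p(theta | data) d theta,

which for a normal belief N(mu, sigma^2) and a planned study with Fisher
information V analysed two-sided at level alpha has the closed form

    PoS = 1 - Phi( (V^{-1/2} z_{1-alpha/2} - mu) / sqrt(V^{-1} + sigma^2) ).

Success counts only rejections in favour of the experimental arm; with a
point belief at zero effect the assurance is alpha/2, not alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import norm

from .beliefs import PlannedDesign

__all__ = [
    "PosResult",
    "assurance_closed_form",
    "assurance_monte_carlo",
    "assurance_mixture",
    "go_decision",
]


@dataclass(frozen=True)
class PosResult:
    """A probability of study success and how it was computed."""

    pos: float
    method: Literal["closed_form", "monte_carlo"]
    mc_draws: int | None = None
    mc_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pos <= 1.0:
            raise ValueError("probability of success must lie in [0, 1]")


def _closed_form(mean: float, variance: float, design: PlannedDesign) -> float:
    z_crit = norm.ppf(1.0 - design.alpha / 2.0)
    v_inv = 1.0 / design.information
    return float(1.0 - norm.cdf((math.sqrt(v_inv) * z_crit - mean) / math.sqrt(v_inv + variance)))


def assurance_closed_form(mean: float, variance: float, design: PlannedDesign) -> PosResult:
    """Closed-form assurance of a planned study under a normal belief.

    ``variance`` may be zero (a point belief), in which case the assurance
    is the ordinary power at ``theta = mean``.
    """
    if variance < 0:
        raise ValueError("belief variance must be nonnegative")
    return PosResult(pos=_closed_form(mean, variance, design), method="closed_form")


def assurance_monte_carlo(
    mean: float,
    variance: float,
    design: PlannedDesign,
    n_draws: int,
    seed: int = 0,
) -> PosResult:
    """Monte-Carlo assurance by simulating the planned study.

    Draws ``theta ~ N(mean, variance)``, then the planned study's estimate
    ``theta_hat ~ N(theta, 1/V)``, and counts the proportion of replicates
    with ``theta_hat * sqrt(V) > z_{1-alpha/2}``.
    """
    if n_draws < 1:
        raise ValueError("need at least one draw")
    if variance < 0:
        raise ValueError("belief variance must be nonnegative")
    rng = np.random.default_rng(seed)
    theta = mean + math.sqrt(variance) * rng.standard_normal(n_draws)
    theta_hat = theta + rng.standard_normal(n_draws) / math.sqrt(design.information)
    z_crit = norm.ppf(1.0 - design.alpha / 2.0)
    hits = theta_hat * math.sqrt(design.information) > z_crit
    return PosResult(
        pos=float(np.mean(hits)), method="monte_carlo", mc_draws=n_draws, mc_seed=seed
    )


def assurance_mixture(
    mix: Sequence[tuple[float, float, float]], design: PlannedDesign
) -> PosResult:
    """Assurance under a mixture belief: the weighted sum of component values.

    ``mix`` is a sequence of ``(weight, mean, variance)`` triples with
    normalized weights.  The assurance integral is linear in the belief, so
    the mixture value is exactly the weighted sum of the component
    closed-form values and always lies between their minimum and maximum.
    """
    weights = [w for w, _, _ in mix]
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must be normalized")
    if any(w < 0 for w in weights):
        raise ValueError("mixture weights must be nonnegative")
    pos = sum(w * _closed_form(m, v, design) for w, m, v in mix)
    return PosResult(pos=float(pos), method="closed_form")


def go_decision(pos: float, threshold: float) -> bool:
    """Go/no-go rule: go iff the PoS strictly exceeds the threshold."""
    if not 0 <= pos <= 1 or not 0 <= threshold <= 1:
        raise ValueError("pos and threshold must lie in [0, 1]")
    return pos > threshold
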