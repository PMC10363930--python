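"""Robustified borrowing via a two-component mixture with data-driven weights.

The joint prior on a pair of related effects is a mixture of an
uncorrelated component (no borrowing) and a correlated component (full
borrowing at the pre-specified rho), with prior weights (w00, w10).  After
observing ``(z2, v2)`` on the second effect, both components are updated
conjugately; the weights are updated from an overlap probability ``p``:

    w01 = (1 - p) w00 / ((1 - p) w00 + p w10),    w11 = 1 - w01,

where ``p`` is the mass of the correlated posterior margin of the first
effect — truncated at its own quartiles — that falls inside the
interquartile interval of a reference distribution centred at the prior
mean.  Two references are supported: the *hypothetical* posterior
N(mu1, posterior variance at the observed v2) and the *limiting* posterior
N(mu1, sigma1^2 (1 - rho^2)), the infinite-information variance.  A large
shift of the posterior mean away from the prior mean shrinks ``p`` and
moves weight onto the uncorrelated component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from scipy.stats import norm

from .beliefs import Interval, MixtureBelief, MvnBelief, StudyOutcome, pair_belief, validate
from .updating import update_pair

__all__ = [
    "QUARTILE_Z",
    "WeightUpdate",
    "hypothetical_posterior",
    "limiting_posterior",
    "quartile_interval",
    "overlap_probability",
    "update_weights",
    "robust_update",
    "robust_update_multi",
]

# standard-normal upper quartile, Phi^-1(0.75)
QUARTILE_Z: float = float(norm.ppf(0.75))

Method = Literal["standard", "hypothetical", "limiting"]


@dataclass(frozen=True)
class WeightUpdate:
    """Record of one mixture-weight update."""

    p: float
    prior_weights: tuple[float, float]
    posterior_weights: tuple[float, float]
    method: Method

    def __post_init__(self) -> None:
        w01, w11 = self.posterior_weights
        if w01 < 0 or w11 < 0 or abs(w01 + w11 - 1.0) > 1e-9:
            raise ValueError("posterior weights must be nonnegative and sum to 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


def _pair_params(pair_prior: MvnBelief) -> tuple[float, float, float, float, float]:
    validate(pair_prior)
    if pair_prior.n != 2:
        raise ValueError("a 2-dimensional belief is required")
    mu1, mu2 = pair_prior.means
    s1, s2 = pair_prior.variances()
    c12 = float(pair_prior.covariance[0, 1])
    return float(mu1), float(mu2), float(s1), float(s2), c12


def hypothetical_posterior(pair_prior: MvnBelief, v2: float) -> tuple[float, float]:
    """Reference with the prior mean and the achievable posterior variance.

    Returns ``(mu1, s1 - v2 * rho^2 * s1 * s2 / (1 + v2 * s2))``.
    """
    if v2 <= 0:
        raise ValueError("observation information must be strictly positive")
    mu1, _, s1, s2, c12 = _pair_params(pair_prior)
    var = s1 - v2 * c12 ** 2 / (1.0 + v2 * s2)  # c12^2 = rho^2 * s1 * s2
    return mu1, var


def limiting_posterior(pair_prior: MvnBelief) -> tuple[float, float]:
    """Reference with the prior mean and infinite-information variance.

    Returns ``(mu1, s1 * (1 - rho^2))``.
    """
    mu1, _, s1, s2, c12 = _pair_params(pair_prior)
    rho_sq = c12 ** 2 / (s1 * s2)
    return mu1, s1 * (1.0 - rho_sq)


def quartile_interval(mean: float, variance: float) -> Interval:
    """Central 50% interval [mean - c*sd, mean + c*sd], c = Phi^-1(0.75)."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    half = QUARTILE_Z * variance ** 0.5
    return Interval(lower=mean - half, upper=mean + half)


def overlap_probability(
    posterior_mean: float, posterior_variance: float, reference: Interval
) -> float:
    """Mass of the quartile-truncated posterior inside the reference interval.

    The posterior is truncated at its own quartiles, so the truncation
    denominator is exactly 0.5; the result is clamped to [0, 1].
    """
    if posterior_variance <= 0:
        raise ValueError("posterior variance must be strictly positive")
    own = quartile_interval(posterior_mean, posterior_variance)
    lo = max(own.lower, reference.lower)
    hi = min(own.upper, reference.upper)
    if hi <= lo:
        return 0.0
    sd = posterior_variance ** 0.5
    mass = norm.cdf((hi - posterior_mean) / sd) - norm.cdf((lo - posterior_mean) / sd)
    return float(min(1.0, max(0.0, mass / 0.5)))


def update_weights(w00: float, w10: float, p: float) -> WeightUpdate:
    """Bayes-factor style weight update from the overlap probability ``p``."""
    if w00 < 0 or w10 < 0 or abs(w00 + w10 - 1.0) > 1e-9:
        raise ValueError("prior weights must be nonnegative and sum to 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    denom = (1.0 - p) * w00 + p * w10
    if denom == 0.0:
        raise ValueError("weight update undefined: (1-p)w00 + p*w10 = 0")
    w01 = (1.0 - p) * w00 / denom
    w11 = p * w10 / denom
    return WeightUpdate(
        p=p,
        prior_weights=(w00, w10),
        posterior_weights=(w01, w11),
        method="standard",
    )


def _uncorrelated_prior(pair_prior: MvnBelief) -> MvnBelief:
    mu1, mu2, s1, s2, _ = _pair_params(pair_prior)
    return pair_belief(mu1, mu2, s1, s2, 0.0, labels=pair_prior.labels)


def robust_update(
    pair_prior: MvnBelief,
    z2: float,
    v2: float,
    w00: float = 0.5,
    w10: float = 0.5,
    method: Method = "hypothetical",
) -> tuple[MixtureBelief, WeightUpdate]:
    """Mixture posterior for a pair, with weights updated per ``method``.

    The uncorrelated component protects the unobserved margin (it keeps
    mean ``mu1`` and variance ``sigma1^2``) but still updates the observed
    margin; the correlated component is the ordinary conjugate posterior.
    ``method='standard'`` leaves the weights at their prior values.
    """
    posterior_corr = update_pair(pair_prior, z2, v2)
    posterior_uncorr = update_pair(_uncorrelated_prior(pair_prior), z2, v2)

    if method == "standard":
        wu = WeightUpdate(
            p=0.5,
            prior_weights=(w00, w10),
            posterior_weights=(w00, w10),
            method="standard",
        )
    elif method in ("hypothetical", "limiting"):
        if method == "hypothetical":
            ref_mean, ref_var = hypothetical_posterior(pair_prior, v2)
        else:
            ref_mean, ref_var = limiting_posterior(pair_prior)
        reference = quartile_interval(ref_mean, ref_var)
        post_mean1, post_var1 = posterior_corr.marginal(0)
        p = overlap_probability(post_mean1, post_var1, reference)
        base = update_weights(w00, w10, p)
        wu = WeightUpdate(
            p=p,
            prior_weights=base.prior_weights,
            posterior_weights=base.posterior_weights,
            method=method,
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    mixture = MixtureBelief(
        weights=wu.posterior_weights, components=(posterior_uncorr, posterior_corr)
    )
    return mixture, wu


def robust_update_multi(
    prior: MvnBelief,
    outcome: StudyOutcome,
    w00: float = 0.5,
    w10: float = 0.5,
    method: Method = "hypothetical",
) -> list[tuple[MixtureBelief, WeightUpdate]]:
    """Pairwise robust update of an n-dimensional belief from one outcome.

    The joint problem is split into n-1 bivariate problems, each pairing an
    unobserved effect with the observed one; each pair gets its own overlap
    probability and weights.  The n-dimensional joint is deliberately not
    reassembled: downstream PoS for each unobserved combination uses its own
    pair's mixture marginal.
    """
    validate(prior)
    if prior.n < 2:
        raise ValueError("need at least 2 combinations for pairwise robustification")
    i = outcome.component
    if not 0 <= i < prior.n:
        raise ValueError("observed component index out of range")
    results = []
    for j in range(prior.n):
        if j == i:
            continue
        labels = None
        if prior.labels is not None:
            labels = (prior.labels[j], prior.labels[i])
        sub = pair_belief(
            prior.means[j],
            prior.means[i],
            prior.covariance[j, j],
            prior.covariance[i, i],
            float(
                prior.covariance[j, i]
                / (prior.covariance[j, j] * prior.covariance[i, i]) ** 0.5
            ),
            labels=labels,
        )
        results.append(robust_update(sub, outcome.score, outcome.information, w00, w10, method))
    return results
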