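"""Conjugate updating of a joint MVN belief from observed score statistics.

Observing outcomes ``(Z_i, V_i)`` on a subset of components, with selection
matrix ``A`` picking the observed coordinates and ``V`` the diagonal
information matrix, the posterior is

    theta | theta_hat  ~  MVN( (Sigma^-1 + A'VA)^-1 (Sigma^-1 mu + A'V theta_hat),
                               (Sigma^-1 + A'VA)^-1 ).

For the bivariate case with one observation on the second component the
posterior has a closed form (``update_pair``) that serves as an oracle for
the general solve.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .beliefs import MvnBelief, StudyOutcome, validate

__all__ = ["update", "update_pair", "update_sequential"]


def update(prior: MvnBelief, outcomes: Sequence[StudyOutcome]) -> MvnBelief:
    """Batch conjugate update of ``prior`` from outcomes on distinct components.

    Simultaneous observations of the same component are rejected: the
    observation information matrix is diagonal with one entry per observed
    component, and a pooling policy is deliberately not implied.
    """
    validate(prior)
    outcomes = list(outcomes)
    if not outcomes:
        return prior
    comps = [o.component for o in outcomes]
    if len(set(comps)) != len(comps):
        raise ValueError("duplicate observed components: pre-pool repeated observations")
    n = prior.n
    for c in comps:
        if not 0 <= c < n:
            raise ValueError(f"component index {c} out of range for dimension {n}")

    a = np.zeros((len(outcomes), n))
    for row, o in enumerate(outcomes):
        a[row, o.component] = 1.0
    v = np.diag([o.information for o in outcomes])
    theta_hat = np.array([o.effect for o in outcomes])

    try:
        prior_chol = cho_factor(prior.covariance)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular prior covariance") from err
    sigma_inv = cho_solve(prior_chol, np.eye(n))

    precision = sigma_inv + a.T @ v @ a
    rhs = sigma_inv @ prior.means + a.T @ v @ theta_hat
    prec_chol = cho_factor(precision)
    post_cov = cho_solve(prec_chol, np.eye(n))
    post_cov = 0.5 * (post_cov + post_cov.T)
    post_mean = cho_solve(prec_chol, rhs)
    return MvnBelief(means=post_mean, covariance=post_cov, labels=prior.labels)


def update_pair(prior: MvnBelief, z2: float, v2: float) -> MvnBelief:
    """Closed-form bivariate posterior given one observation on component 2.

    With prior ``(mu1, mu2)``, variances ``(s1, s2)`` and correlation rho,
    and writing ``k = 1 + v2 * s2``:

        mean1 = mu1 + rho*sd1*sd2/k * (z2 - v2*mu2)
        mean2 = (mu2 + s2*z2) / k
        var1  = s1 - v2 * rho^2 * s1 * s2 / k
        var2  = s2 / k
        cov   = rho*sd1*sd2 / k
    """
    validate(prior)
    if prior.n != 2:
        raise ValueError("update_pair requires a 2-dimensional belief")
    if v2 <= 0:
        raise ValueError("observation information must be strictly positive")
    mu1, mu2 = prior.means
    s1, s2 = np.diag(prior.covariance)
    c12 = prior.covariance[0, 1]  # rho * sd1 * sd2, exact
    k = 1.0 + v2 * s2
    mean1 = mu1 + (c12 / k) * (z2 - v2 * mu2)
    mean2 = (mu2 + s2 * z2) / k
    var1 = s1 - v2 * c12 ** 2 / k  # c12^2 = rho^2 * s1 * s2
    var2 = s2 / k
    cov12 = c12 / k
    return MvnBelief(
        means=np.array([mean1, mean2]),
        covariance=np.array([[var1, cov12], [cov12, var2]]),
        labels=prior.labels,
    )


def update_sequential(prior: MvnBelief, outcomes: Sequence[StudyOutcome]) -> MvnBelief:
    """Apply ``update`` one outcome at a time; equals the batch update."""
    belief = prior
    for outcome in outcomes:
        belief = update(belief, [outcome])
    return belief
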