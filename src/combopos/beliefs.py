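"""Domain types for joint beliefs over related combination-therapy effects.

Effects live on a scale where larger values favour the experimental arm;
for survival endpoints the effect is the negative log hazard ratio,
``-log(HR)``.  A joint belief over ``n`` related combinations is a
multivariate normal with mean vector ``mu`` and covariance ``Sigma`` whose
off-diagonal entries are ``rho_ij * sigma_i * sigma_j``.  Displayed matrices
in the literature are usually rounded; computation here always uses the
exact products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "BeliefValidationError",
    "MvnBelief",
    "StudyOutcome",
    "PlannedDesign",
    "MixtureBelief",
    "Interval",
    "pair_belief",
    "validate",
]

_SYM_TOL = 1e-12
_PSD_TOL = -1e-10


class BeliefValidationError(ValueError):
    """An invariant of a belief object was violated."""


@dataclass(frozen=True)
class MvnBelief:
    """Multivariate-normal belief over ``n`` combination treatment effects.

    Parameters
    ----------
    means : array-like of shape (n,)
        Effect means (e.g. ``-log`` hazard ratios); larger favours the
        experimental arm.
    covariance : array-like of shape (n, n)
        Symmetric positive semi-definite matrix with variances on the
        diagonal and ``rho_ij * sigma_i * sigma_j`` off-diagonal.
    labels : tuple of str, optional
        Combination names, e.g. ``("A+B", "A+C")``.
    """

    means: np.ndarray
    covariance: np.ndarray
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "means", np.atleast_1d(np.asarray(self.means, dtype=float)))
        object.__setattr__(self, "covariance", np.atleast_2d(np.asarray(self.covariance, dtype=float)))
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.means.shape[0]

    def marginal(self, component: int) -> tuple[float, float]:
        """Marginal ``(mean, variance)`` of one component."""
        return float(self.means[component]), float(self.covariance[component, component])

    def variances(self) -> np.ndarray:
        return np.diag(self.covariance).copy()

    def correlation(self) -> np.ndarray:
        sd = np.sqrt(np.diag(self.covariance))
        return self.covariance / np.outer(sd, sd)

    def to_dict(self) -> dict:
        """JSON-serializable document: labels, means, variances, correlation."""
        doc = {
            "means": self.means.tolist(),
            "variances": np.diag(self.covariance).tolist(),
            "correlation": self.correlation().tolist(),
        }
        if self.labels is not None:
            doc["labels"] = list(self.labels)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "MvnBelief":
        means = np.asarray(doc["means"], dtype=float)
        var = np.asarray(doc["variances"], dtype=float)
        n = means.shape[0]
        corr = doc.get("correlation", 0.0)
        if np.isscalar(corr):
            if n != 2 and corr != 0.0:
                raise BeliefValidationError(
                    "scalar correlation is only supported for 2-dimensional beliefs"
                )
            mat = np.eye(n)
            if n == 2:
                mat[0, 1] = mat[1, 0] = float(corr)
            corr = mat
        else:
            corr = np.asarray(corr, dtype=float)
        sd = np.sqrt(var)
        cov = corr * np.outer(sd, sd)
        return validate(cls(means=means, covariance=cov, labels=doc.get("labels")))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "MvnBelief":
        return cls.from_dict(json.loads(text))


def validate(belief: MvnBelief) -> MvnBelief:
    """Check all invariants of a belief; return it unchanged if valid.

    Raises
    ------
    BeliefValidationError
        Naming the violated invariant: dimension mismatch, asymmetry,
        non-positive variance, implied correlation outside [-1, 1], or an
        indefinite covariance (smallest eigenvalue below tolerance).
    """
    mu, cov = belief.means, belief.covariance
    if mu.ndim != 1 or cov.ndim != 2:
        raise BeliefValidationError("means must be a vector and covariance a matrix")
    n = mu.shape[0]
    if cov.shape != (n, n):
        raise BeliefValidationError(
            f"dimension mismatch: means has length {n} but covariance is {cov.shape}"
        )
    if belief.labels is not None and len(belief.labels) != n:
        raise BeliefValidationError("labels length does not match dimension")
    if not np.all(np.isfinite(mu)) or not np.all(np.isfinite(cov)):
        raise BeliefValidationError("non-finite entries in belief")
    if np.max(np.abs(cov - cov.T)) > _SYM_TOL:
        raise BeliefValidationError("covariance is not symmetric (tolerance 1e-12)")
    d = np.diag(cov)
    if np.any(d <= 0):
        raise BeliefValidationError("covariance has a non-positive diagonal entry")
    corr = cov / np.outer(np.sqrt(d), np.sqrt(d))
    off = corr - np.diag(np.diag(corr))
    if np.max(np.abs(off)) > 1.0 + 1e-12:
        raise BeliefValidationError("implied correlation exceeds 1 in absolute value")
    if np.linalg.eigvalsh(cov).min() < _PSD_TOL:
        raise BeliefValidationError(
            "covariance is not positive semi-definite (smallest eigenvalue < -1e-10)"
        )
    return belief


def pair_belief(
    mu1: float,
    mu2: float,
    var1: float,
    var2: float,
    rho: float,
    labels: Sequence[str] | None = None,
) -> MvnBelief:
    """Bivariate belief with off-diagonal exactly ``rho * sqrt(var1 * var2)``.

    ``rho`` must lie strictly inside (-1, 1); variances must be positive.
    """
    if var1 <= 0 or var2 <= 0:
        raise BeliefValidationError("variances must be strictly positive")
    if abs(rho) >= 1:
        raise BeliefValidationError("|rho| must be strictly less than 1")
    off = rho * np.sqrt(var1 * var2)
    cov = np.array([[var1, off], [off, var2]])
    return MvnBelief(means=np.array([mu1, mu2], dtype=float), covariance=cov,
                     labels=tuple(labels) if labels is not None else None)


@dataclass(frozen=True)
class StudyOutcome:
    """Observed study summarized by its efficient score and Fisher information.

    ``component`` is the 0-based index of the observed combination within a
    joint belief.  The implied effect estimate is ``score / information`` and
    is approximately ``N(theta, 1/information)``.
    """

    component: int
    score: float
    information: float

    def __post_init__(self) -> None:
        if self.information <= 0:
            raise BeliefValidationError("Fisher information must be strictly positive")
        if not np.isfinite(self.score / self.information):
            raise BeliefValidationError("effect estimate score/information must be finite")

    @property
    def effect(self) -> float:
        """Effect estimate ``theta_hat = Z / V``."""
        return self.score / self.information


@dataclass(frozen=True)
class PlannedDesign:
    """Design of the planned (future) study: two-sided alpha and information.

    ``1/information`` is the sampling variance of the planned study's effect
    estimate.  Use :meth:`from_power` to derive the information from
    (alpha, power, target effect).
    """

    alpha: float
    information: float
    derived_from: tuple[float, float, float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise BeliefValidationError("alpha must lie in (0, 1)")
        if self.information <= 0:
            raise BeliefValidationError("planned information must be strictly positive")
        if self.derived_from is not None:
            from .scores import info_from_design

            a, pw, eff = self.derived_from
            implied = info_from_design(a, pw, eff)
            if abs(implied - self.information) > 1e-9:
                raise BeliefValidationError(
                    "information inconsistent with (alpha, power, target_effect) record"
                )

    @classmethod
    def from_power(cls, alpha: float, power: float, target_effect: float) -> "PlannedDesign":
        from .scores import info_from_design

        info = info_from_design(alpha, power, target_effect)
        return cls(alpha=alpha, information=info, derived_from=(alpha, power, target_effect))


@dataclass(frozen=True)
class MixtureBelief:
    """Finite mixture of equal-dimension MVN beliefs with normalized weights."""

    weights: tuple[float, ...]
    components: tuple[MvnBelief, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.weights) != len(self.components):
            raise BeliefValidationError("weights and components length mismatch")
        if any(w < 0 for w in self.weights):
            raise BeliefValidationError("mixture weights must be nonnegative")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise BeliefValidationError("mixture weights must sum to 1 (tolerance 1e-12)")
        dims = {c.n for c in self.components}
        if len(dims) > 1:
            raise BeliefValidationError("mixture components must share one dimension")

    def marginal_mixture(self, component: int) -> list[tuple[float, float, float]]:
        """Per-component ``(weight, mean, variance)`` of one margin."""
        return [
            (w, *c.marginal(component)) for w, c in zip(self.weights, self.components)
        ]

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "components": [c.to_dict() for c in self.components],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MixtureBelief":
        return cls(
            weights=tuple(doc["weights"]),
            components=tuple(MvnBelief.from_dict(d) for d in doc["components"]),
        )


@dataclass(frozen=True)
class Interval:
    """Closed interval on the effect scale."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise BeliefValidationError("interval lower bound exceeds upper bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower
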