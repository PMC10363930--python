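"""Model/Results facade tying the updating, robustification and assurance
machinery together in the style of a statistical modelling package.

``RelatedCombinations`` holds the joint prior belief over a set of related
combination therapies together with the observed study outcomes; ``fit``
performs the conjugate (or robustified mixture) update and returns a
``PoSResults`` object carrying the posterior, per-combination assurance of
a planned study, go decisions and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .assurance import assurance_closed_form, assurance_mixture, go_decision
from .beliefs import MixtureBelief, MvnBelief, PlannedDesign, StudyOutcome, validate
from .robust import WeightUpdate, robust_update_multi
from .updating import update

__all__ = ["RelatedCombinations", "PoSResults"]


class RelatedCombinations:
    """Joint model of related combination-therapy effects.

    Parameters
    ----------
    prior : MvnBelief
        Joint prior over the n combination effects.
    outcomes : sequence of StudyOutcome
        Observed studies, one per observed combination.
    design : PlannedDesign
        Planned study whose probability of success is of interest.

    Examples
    --------
    >>> from combopos import pair_belief, score_from_survival, PlannedDesign
    >>> prior = pair_belief(0.2877, 0.2877, 0.08, 0.08, 0.6)
    >>> obs = score_from_survival(0.68, 604, 1.0, component=1)
    >>> design = PlannedDesign.from_power(0.05, 0.8, 0.2877)
    >>> res = RelatedCombinations(prior, [obs], design).fit()
    """

    def __init__(
        self,
        prior: MvnBelief,
        outcomes: Sequence[StudyOutcome],
        design: PlannedDesign,
    ) -> None:
        self.prior = validate(prior)
        self.outcomes = list(outcomes)
        self.design = design

    @classmethod
    def from_dataframe(
        cls,
        priors: pd.DataFrame,
        correlation: np.ndarray | float,
        outcomes: Sequence[StudyOutcome],
        design: PlannedDesign,
    ) -> "RelatedCombinations":
        """Build from a DataFrame with columns ``label``, ``mean``, ``variance``."""
        belief = MvnBelief.from_dict(
            {
                "labels": priors["label"].tolist(),
                "means": priors["mean"].tolist(),
                "variances": priors["variance"].tolist(),
                "correlation": correlation if np.isscalar(correlation) else np.asarray(correlation).tolist(),
            }
        )
        return cls(belief, outcomes, design)

    def fit(
        self,
        method: Literal["multivariate", "standard", "hypothetical", "limiting"] = "multivariate",
        w00: float = 0.5,
        w10: float = 0.5,
        threshold: float = 0.6,
    ) -> "PoSResults":
        """Update the belief and compute per-combination assurance.

        ``method='multivariate'`` is the plain conjugate update; the other
        methods use the two-component mixture with the corresponding weight
        rule (pairwise for n > 2, which requires a single observed study).
        """
        if method == "multivariate":
            posterior = update(self.prior, self.outcomes)
            pos = {}
            for i in range(posterior.n):
                mean, var = posterior.marginal(i)
                pos[i] = assurance_closed_form(mean, var, self.design).pos
            return PoSResults(
                model=self,
                method=method,
                posterior=posterior,
                pos=pos,
                threshold=threshold,
            )

        if len(self.outcomes) != 1:
            raise ValueError("robustified methods require exactly one observed study")
        outcome = self.outcomes[0]
        pairs = robust_update_multi(self.prior, outcome, w00, w10, method)
        observed = outcome.component
        unobserved = [j for j in range(self.prior.n) if j != observed]
        pos: dict[int, float] = {}
        weight_updates: dict[int, WeightUpdate] = {}
        mixtures: dict[int, MixtureBelief] = {}
        for j, (mixture, wu) in zip(unobserved, pairs):
            pos[j] = assurance_mixture(mixture.marginal_mixture(0), self.design).pos
            weight_updates[j] = wu
            mixtures[j] = mixture
        # observed margin is identical across mixture components
        obs_mean, obs_var = pairs[0][0].components[1].marginal(1)
        pos[observed] = assurance_closed_form(obs_mean, obs_var, self.design).pos
        return PoSResults(
            model=self,
            method=method,
            posterior=None,
            pos=pos,
            threshold=threshold,
            mixtures=mixtures,
            weight_updates=weight_updates,
            observed_marginal=(observed, obs_mean, obs_var),
        )


@dataclass
class PoSResults:
    """Fitted results: posterior belief(s), PoS and go decisions."""

    model: RelatedCombinations
    method: str
    posterior: MvnBelief | None
    pos: dict[int, float]
    threshold: float
    mixtures: dict[int, MixtureBelief] | None = None
    weight_updates: dict[int, WeightUpdate] | None = None
    observed_marginal: tuple[int, float, float] | None = None

    def _label(self, i: int) -> str:
        labels = self.model.prior.labels
        return labels[i] if labels is not None else f"combination_{i}"

    def go(self, component: int) -> bool:
        return go_decision(self.pos[component], self.threshold)

    def summary(self) -> pd.DataFrame:
        """Per-combination table of prior/posterior moments, PoS and go."""
        rows = []
        observed = {o.component for o in self.model.outcomes}
        for i in sorted(self.pos):
            prior_mean, prior_var = self.model.prior.marginal(i)
            if self.posterior is not None:
                post_mean, post_var = self.posterior.marginal(i)
            elif self.mixtures is not None and i in self.mixtures:
                mix = self.mixtures[i].marginal_mixture(0)
                post_mean = sum(w * m for w, m, _ in mix)
                second = sum(w * (v + m * m) for w, m, v in mix)
                post_var = second - post_mean ** 2
            elif self.observed_marginal is not None and i == self.observed_marginal[0]:
                _, post_mean, post_var = self.observed_marginal
            else:
                post_mean, post_var = float("nan"), float("nan")
            row = {
                "combination": self._label(i),
                "observed": i in observed,
                "prior_mean": prior_mean,
                "prior_var": prior_var,
                "post_mean": post_mean,
                "post_var": post_var,
                "pos": self.pos[i],
                "go": self.go(i),
            }
            if self.weight_updates is not None and i in self.weight_updates:
                wu = self.weight_updates[i]
                row["p"] = wu.p
                row["omega01"] = wu.posterior_weights[0]
            rows.append(row)
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return self.summary().to_string(index=False, float_format=lambda x: f"{x:.4f}")
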