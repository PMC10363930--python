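import numpy as np
import pytest

import combopos as cp
from combopos.robust import QUARTILE_Z
from tests.conftest import TARGET_EFFECT, make_prior


class TestReferencePosteriors:
    def test_hypothetical_matches_usual_posterior_variance(self, pair_prior, trial_outcome):
        mean, var = cp.hypothetical_posterior(pair_prior, trial_outcome.information)
        assert mean == pytest.approx(TARGET_EFFECT, abs=1e-12)
        post = cp.update_pair(pair_prior, trial_outcome.score, trial_outcome.information)
        assert var == pytest.approx(post.covariance[0, 0], rel=1e-12)
        assert var == pytest.approx(0.053402, abs=1e-5)

    def test_hypothetical_with_zero_correlation_keeps_prior_variance(self):
        mean, var = cp.hypothetical_posterior(make_prior(0.0), 151.0)
        assert var == pytest.approx(0.08, abs=1e-14)

    def test_hypothetical_tends_to_limiting_as_information_grows(self, pair_prior):
        _, var_hyp = cp.hypothetical_posterior(pair_prior, 1e12)
        _, var_lim = cp.limiting_posterior(pair_prior)
        assert var_hyp == pytest.approx(var_lim, rel=1e-6)

    @pytest.mark.parametrize(
        "rho, s1, expected",
        [(0.6, 0.08, 0.0512), (0.0, 0.08, 0.08), (0.8, 0.2, 0.072)],
    )
    def test_limiting_variance_formula(self, rho, s1, expected):
        prior = cp.pair_belief(0.1, 0.1, s1, s1, rho)
        _, var = cp.limiting_posterior(prior)
        assert var == pytest.approx(expected, abs=1e-12)


class TestQuartileInterval:
    def test_standard_normal_quartiles(self):
        iv = cp.quartile_interval(0.0, 1.0)
        assert iv.lower == pytest.approx(-0.674490, abs=1e-6)
        assert iv.upper == pytest.approx(0.674490, abs=1e-6)

    def test_worked_example_posterior_quartiles(self):
        iv = cp.quartile_interval(0.341977, 0.053402)
        assert iv.lower == pytest.approx(0.186102, abs=1e-4)
        assert iv.upper == pytest.approx(0.497852, abs=1e-4)

    def test_shift_equivariance(self):
        a = cp.quartile_interval(0.1, 0.05)
        b = cp.quartile_interval(0.6, 0.05)
        assert b.lower - a.lower == pytest.approx(0.5, abs=1e-12)
        assert b.upper - a.upper == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_degenerates_to_point(self):
        iv = cp.quartile_interval(0.3, 0.0)
        assert iv.lower == iv.upper == 0.3


class TestOverlapProbability:
    def test_perfect_alignment_gives_one(self):
        ref = cp.quartile_interval(0.3, 0.05)
        assert cp.overlap_probability(0.3, 0.05, ref) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_reference_gives_zero(self):
        ref = cp.Interval(lower=10.0, upper=11.0)
        assert cp.overlap_probability(0.0, 0.05, ref) == 0.0

    def test_worked_example_overlap(self):
        ref = cp.quartile_interval(TARGET_EFFECT, 0.053402)
        p = cp.overlap_probability(0.341977, 0.053402, ref)
        assert p == pytest.approx(0.8398, abs=5e-4)

    def test_increasing_shift_never_increases_p(self):
        ref = cp.quartile_interval(0.0, 0.05)
        shifts = np.linspace(0.0, 1.5, 30)
        ps = [cp.overlap_probability(s, 0.05, ref) for s in shifts]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))

    def test_always_within_unit_interval(self):
        for mean in np.linspace(-2, 2, 9):
            for var in (0.01, 0.05, 0.5):
                ref = cp.quartile_interval(0.1, 0.07)
                assert 0.0 <= cp.overlap_probability(mean, var, ref) <= 1.0


class TestUpdateWeights:
    def test_worked_example_weights(self):
        wu = cp.update_weights(0.5, 0.5, 0.8398)
        assert wu.posterior_weights[0] == pytest.approx(0.160, abs=5e-4)
        assert wu.posterior_weights[1] == pytest.approx(0.840, abs=5e-4)

    def test_uninformative_p_leaves_weights_unchanged(self):
        wu = cp.update_weights(0.5, 0.5, 0.5)
        assert wu.posterior_weights == pytest.approx((0.5, 0.5))

    def test_certain_correlation(self):
        wu = cp.update_weights(0.3, 0.7, 1.0)
        assert wu.posterior_weights == pytest.approx((0.0, 1.0))

    def test_undefined_update_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cp.update_weights(0.0, 1.0, 0.0)  # p = 0 with no mass on uncorrelated
        with pytest.raises(ValueError, match="undefined"):
            cp.update_weights(1.0, 0.0, 1.0)  # p = 1 with no mass on correlated


class TestRobustUpdate:
    def test_hypothetical_worked_example(self, pair_prior, trial_outcome):
        mix, wu = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information,
            0.5, 0.5, "hypothetical",
        )
        assert wu.posterior_weights[0] == pytest.approx(0.16, abs=5e-3)
        (w0, m0, v0), (w1, m1, v1) = mix.marginal_mixture(0)
        assert (m0, v0) == pytest.approx((0.288, 0.08), abs=5e-4)
        assert (m1, v1) == pytest.approx((0.342, 0.053), abs=5e-4)

    def test_limiting_worked_example(self, pair_prior, trial_outcome):
        _, wu = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information,
            0.5, 0.5, "limiting",
        )
        assert wu.posterior_weights[0] == pytest.approx(0.17, abs=5e-3)

    def test_limiting_weight_on_uncorrelated_exceeds_hypothetical(
        self, pair_prior, trial_outcome
    ):
        _, hyp = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information, method="hypothetical"
        )
        _, lim = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information, method="limiting"
        )
        assert lim.posterior_weights[0] >= hyp.posterior_weights[0]

    def test_standard_method_keeps_weights(self, pair_prior, trial_outcome):
        _, wu = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information,
            0.5, 0.5, "standard",
        )
        assert wu.posterior_weights == (0.5, 0.5)

    def test_uncorrelated_component_still_updates_observed_margin(
        self, pair_prior, trial_outcome
    ):
        mix, _ = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information
        )
        uncorr = mix.components[0]
        assert uncorr.means[1] == pytest.approx(0.378, abs=5e-4)
        assert uncorr.covariance[1, 1] == pytest.approx(0.006, abs=5e-4)
        assert uncorr.covariance[0, 1] == 0.0

    def test_mixture_pos_between_univariate_and_multivariate(
        self, pair_prior, trial_outcome, planned_design
    ):
        mix, _ = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information
        )
        pos_mix = cp.assurance_mixture(mix.marginal_mixture(0), planned_design).pos
        pos_uni = cp.assurance_closed_form(TARGET_EFFECT, 0.08, planned_design).pos
        m1, v1 = mix.components[1].marginal(0)
        pos_multi = cp.assurance_closed_form(m1, v1, planned_design).pos
        assert min(pos_uni, pos_multi) <= pos_mix <= max(pos_uni, pos_multi)


class TestRobustUpdateMulti:
    def test_pair_case_matches_robust_update(self, pair_prior, trial_outcome):
        results = cp.robust_update_multi(pair_prior, trial_outcome)
        assert len(results) == 1
        mix_multi, wu_multi = results[0]
        mix_pair, wu_pair = cp.robust_update(
            pair_prior, trial_outcome.score, trial_outcome.information
        )
        assert wu_multi.p == pytest.approx(wu_pair.p, abs=1e-12)
        np.testing.assert_allclose(
            mix_multi.components[1].means, mix_pair.components[1].means, atol=1e-12
        )

    def _three_dim_prior(self, rho01, rho02, rho12):
        corr = np.array([[1.0, rho01, rho02], [rho01, 1.0, rho12], [rho02, rho12, 1.0]])
        return cp.MvnBelief(means=[0.2, 0.3, 0.25], covariance=0.1 * corr)

    def test_distinct_correlations_give_distinct_p(self):
        prior = self._three_dim_prior(0.2, 0.3, 0.7)
        outcome = cp.StudyOutcome(component=2, score=40.0, information=100.0)
        results = cp.robust_update_multi(prior, outcome)
        ps = [wu.p for _, wu in results]
        assert len(results) == 2
        assert abs(ps[0] - ps[1]) > 1e-6

    def test_zero_correlation_pair_components_coincide(self):
        prior = self._three_dim_prior(0.2, 0.0, 0.5)
        outcome = cp.StudyOutcome(component=2, score=40.0, information=100.0)
        results = cp.robust_update_multi(prior, outcome)
        mix0, wu0 = results[0]  # pair (0, 2) has rho = 0
        np.testing.assert_allclose(
            mix0.components[0].means, mix0.components[1].means, atol=1e-12
        )
        assert 0.0 <= wu0.p <= 1.0  # p still computed

    def test_univariate_belief_rejected(self):
        prior = cp.MvnBelief(means=[0.2], covariance=[[0.1]])
        outcome = cp.StudyOutcome(component=0, score=1.0, information=10.0)
        with pytest.raises(ValueError):
            cp.robust_update_multi(prior, outcome)


def test_quartile_constant_is_upper_quartile():
    from scipy.stats import norm

    assert QUARTILE_Z == norm.ppf(0.75)
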