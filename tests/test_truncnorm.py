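"""Unit and property tests for the truncated-normal conditional model."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import integrate
from scipy.stats import norm

from wcmr import (
    SelectionError,
    SelectionRule,
    SummaryPair,
    alpha_bounds,
    cond_log_density,
    cond_mean,
    cond_var,
    fit_mu_x,
    fit_mu_x_batch,
    log_selection_prob,
    score_residual,
    selection_prob,
)

GW = 5.45131


class TestAlphaBounds:
    @pytest.mark.parametrize(
        "mu, sigma, tau, expected",
        [
            (0.0, 1.0, 2.0, (-2.0, 2.0)),
            (4.0, 1.0, GW, (-9.45131, 1.45131)),
            (4.0, 2.0, 0.0, (-2.0, -2.0)),
        ],
    )
    def test_direct_arithmetic(self, mu, sigma, tau, expected):
        a1, a2 = alpha_bounds(mu, sigma, SelectionRule(tau=tau))
        assert a1 == pytest.approx(expected[0], abs=1e-12)
        assert a2 == pytest.approx(expected[1], abs=1e-12)
        assert a2 - a1 == pytest.approx(2 * tau, abs=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            alpha_bounds(0.0, 0.0, SelectionRule(tau=1.0))


class TestSelectionProb:
    def test_no_selection_is_certain(self):
        assert selection_prob(0.0, 1.0, SelectionRule(tau=0.0)) == pytest.approx(1.0)

    def test_null_at_genome_wide_threshold(self, gw_rule):
        # A at mu=0 is the two-sided p-value at the threshold z
        assert selection_prob(0.0, 1.0, gw_rule) == pytest.approx(5e-8, rel=1e-4)

    def test_matches_normal_tail_oracle(self, gw_rule):
        expected = norm.sf(1.45131) + norm.cdf(-9.45131)
        assert selection_prob(4.0, 1.0, gw_rule) == pytest.approx(expected, rel=1e-12)

    def test_log_prob_survives_deep_truncation(self):
        # at tau=10 the plain 1-CDF route would return exactly 0
        rule = SelectionRule(tau=10.0)
        got = log_selection_prob(0.0, 1.0, rule)
        assert got == pytest.approx(np.log(2) + norm.logsf(10.0), rel=1e-12)


class TestCondLogDensity:
    def test_reduces_to_plain_normal_without_selection(self):
        rule = SelectionRule(tau=0.0)
        for x, mu, s in [(0.3, 0.1, 1.0), (-2.0, 1.0, 0.5), (5.0, 5.0, 3.0)]:
            assert cond_log_density(x, mu, s, rule) == pytest.approx(
                norm.logpdf(x, mu, s), rel=1e-12
            )

    def test_threshold_case_arithmetic(self, gw_rule):
        got = cond_log_density(6.0, 0.0, 1.0, gw_rule)
        expected = norm.logpdf(6.0) - log_selection_prob(0.0, 1.0, gw_rule)
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mu", [0.0, 2.0, -1.0])
    def test_normalizes_to_one_by_quadrature(self, mu, gw_rule):
        dens = lambda x: np.exp(cond_log_density(x, mu, 1.0, gw_rule))
        upper, _ = integrate.quad(dens, GW, np.inf)
        lower, _ = integrate.quad(dens, -np.inf, -GW)
        assert upper + lower == pytest.approx(1.0, abs=1e-8)

    def test_rejects_x_inside_truncation_band(self, gw_rule):
        with pytest.raises(SelectionError):
            cond_log_density(3.0, 0.0, 1.0, gw_rule)


class TestCondMoments:
    def test_reduce_to_normal_moments_without_selection(self):
        rule = SelectionRule(tau=0.0)
        assert cond_mean(1.7, 2.0, rule) == pytest.approx(1.7)
        assert cond_var(1.7, 2.0, rule) == pytest.approx(4.0)

    def test_mean_is_zero_under_symmetry(self, gw_rule):
        assert cond_mean(0.0, 1.0, gw_rule) == pytest.approx(0.0, abs=1e-12)
        assert cond_mean(0.0, 1.0, SelectionRule(tau=2.0)) == pytest.approx(0.0, abs=1e-12)

    def test_variance_scale_equivariance(self):
        rule = SelectionRule(tau=3.0)
        assert cond_var(0.0, 2.0, rule) == pytest.approx(4 * cond_var(0.0, 1.0, rule), rel=1e-12)

    @pytest.mark.parametrize(
        "mu, tau", [(0.0, 2.0), (1.0, 2.0), (4.0, 2.0), (4.0, GW)]
    )
    def test_moments_match_rejection_sampling_oracle(self, mu, tau, rng):
        """Analytic truncated mean/variance vs. accepted Monte-Carlo draws (3 MC SE)."""
        rule = SelectionRule(tau=tau)
        accept_p = selection_prob(mu, 1.0, rule)
        n_total = int(min(1.2e6 / accept_p, 4e7))
        draws = rng.normal(mu, 1.0, n_total)
        acc = draws[np.abs(draws) >= tau]
        n = acc.size
        assert n > 5e5
        se_mean = acc.std(ddof=1) / np.sqrt(n)
        assert cond_mean(mu, 1.0, rule) == pytest.approx(acc.mean(), abs=3 * se_mean)
        v = acc.var(ddof=1)
        m4 = np.mean((acc - acc.mean()) ** 4)
        se_var = np.sqrt(max(m4 - v**2, 0.0) / n)
        assert cond_var(mu, 1.0, rule) == pytest.approx(v, abs=3 * se_var)


class TestScoreResidual:
    def test_root_is_exact_without_selection(self):
        rule = SelectionRule(tau=0.0)
        pair = SummaryPair(x=2.5, sigma_x=1.0, y=0.0, sigma_y=1.0)
        assert score_residual(2.5, pair, rule) == pytest.approx(0.0, abs=1e-12)

    def test_sign_at_zero_matches_observed_sign(self, gw_rule):
        for z in [GW, 6.0, 8.0, -GW, -7.0]:
            pair = SummaryPair(x=z, sigma_x=1.0, y=0.0, sigma_y=1.0)
            assert np.sign(score_residual(0.0, pair, gw_rule)) == np.sign(z)


class TestFitMuX:
    @pytest.mark.parametrize("z", [GW, 5.5, 6.0, 7.5, 9.0])
    @pytest.mark.parametrize("sigma", [1.0, 0.1])
    def test_fixed_point_and_shrinkage(self, z, sigma, gw_rule):
        pair = SummaryPair(x=z * sigma, sigma_x=sigma, y=0.0, sigma_y=1.0)
        fit = fit_mu_x(pair, gw_rule)
        assert fit.converged
        # the MLE makes the observed x the truncated mean exactly
        assert cond_mean(fit.mu_x_hat, sigma, gw_rule) == pytest.approx(pair.x, abs=1e-8 * sigma)
        # strict shrinkage toward zero without sign change
        assert 0 < fit.mu_x_hat < pair.x

    def test_local_likelihood_maximum(self, fig3_pair, gw_rule):
        fit = fit_mu_x(fig3_pair, gw_rule)
        for eps in (1e-4, -1e-4):
            assert fit.loglik >= cond_log_density(
                fig3_pair.x, fit.mu_x_hat + eps, 1.0, gw_rule
            )

    def test_odd_symmetry(self, gw_rule):
        for z in [GW, 6.2, 8.0]:
            plus = fit_mu_x(SummaryPair(x=z, sigma_x=1.0, y=0.0, sigma_y=1.0), gw_rule)
            minus = fit_mu_x(SummaryPair(x=-z, sigma_x=1.0, y=0.0, sigma_y=1.0), gw_rule)
            assert minus.mu_x_hat == pytest.approx(-plus.mu_x_hat, abs=1e-9)

    def test_strictly_increasing_in_x(self, gw_rule):
        zs = np.linspace(GW, GW + 10, 40)
        fits = [fit_mu_x(SummaryPair(x=z, sigma_x=1.0, y=0.0, sigma_y=1.0), gw_rule).mu_x_hat
                for z in zs]
        assert np.all(np.diff(fits) > 0)

    def test_no_selection_returns_x(self):
        rule = SelectionRule(tau=0.0)
        fit = fit_mu_x(SummaryPair(x=-1.3, sigma_x=2.0, y=0.0, sigma_y=1.0), rule)
        assert fit.mu_x_hat == -1.3
        assert fit.converged

    def test_unselected_pair_rejected(self, gw_rule):
        with pytest.raises(SelectionError):
            fit_mu_x(SummaryPair(x=4.0, sigma_x=1.0, y=0.0, sigma_y=1.0), gw_rule)

    def test_batch_agrees_with_scalar(self, gw_rule):
        zs = np.array([GW, -5.8, 6.5, -9.0, 7.2])
        batch = fit_mu_x_batch(zs, 1.0, gw_rule)
        for z, mb in zip(zs, batch):
            scalar = fit_mu_x(SummaryPair(x=z, sigma_x=1.0, y=0.0, sigma_y=1.0), gw_rule)
            assert mb == pytest.approx(scalar.mu_x_hat, abs=1e-9)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    # beyond z ~ tau+5 the shrinkage falls under the solver tolerance and
    # strictness of mu_hat < x is no longer numerically resolvable
    z=st.floats(min_value=GW, max_value=GW + 5),
    sigma=st.floats(min_value=1e-2, max_value=10.0),
    sign=st.sampled_from([-1.0, 1.0]),
)
def test_fit_fixed_point_property(z, sigma, sign):
    """For any selected statistic, the MLE is the fixed point of the truncated mean."""
    rule = SelectionRule(tau=GW)
    x = sign * z * sigma
    assume(rule.selects(x, sigma))  # guard against x/sigma rounding below tau
    fit = fit_mu_x(SummaryPair(x=x, sigma_x=sigma, y=0.0, sigma_y=1.0), rule)
    assert cond_mean(fit.mu_x_hat, sigma, rule) == pytest.approx(x, abs=1e-7 * sigma)
    assert 0 < abs(fit.mu_x_hat) < abs(x)
    assert np.sign(fit.mu_x_hat) == np.sign(x)
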