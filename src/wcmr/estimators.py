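"""Point estimates and tests of the causal effect b = mu_y / mu_x.

Two estimators are provided side by side:

* the winner's-curse-corrected MLE ``b_hat = y / mu_x_hat``, where
  ``mu_x_hat`` comes from the truncated-normal conditional likelihood, with
  the conditional likelihood-ratio test T = (y/sigma_y)^2 ~ chi2(1);
* the classical SMR ratio ``b_SMR = y / x`` with its delta-method variance
  V_delta = (sigma_y^2 + b_SMR^2 sigma_x^2) / x^2 and Wald interval, which
  ignores the selection of the instrument.

The modified statistic T_SMR-tilde (the SMR form with the truncated variance
plugged in) is implemented for completeness; it is always smaller than T and
therefore never preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

from .truncnorm import (
    SelectionRule,
    SummaryPair,
    cond_var,
    fit_mu_x,
)

__all__ = ["CausalEstimate", "corrected_estimate", "conditional_test", "smr_estimate", "modified_smr"]


@dataclass(frozen=True)
class CausalEstimate:
    """A causal-effect estimate with its test of H0: b = 0 (chi-square, 1 df)."""

    b_hat: float
    method: str  # "corrected" | "smr"
    statistic: float
    p_value: float
    variance: float | None = None  # delta-method variance (SMR only)
    ci_lower: float | None = None
    ci_upper: float | None = None
    ci_level: float | None = None
    df: int = 1


def _chi2_sf(statistic: float) -> float:
    return float(chi2.sf(statistic, df=1))


def conditional_test(pair: SummaryPair) -> tuple[float, float]:
    """Likelihood-ratio test of H0: b = 0 under the selected-SNP model.

    The exposure-likelihood terms cancel between null and alternative, so
    the statistic is simply (y/sigma_y)^2 ~ chi2(1) — valid under selection
    and independent of x, sigma_x and tau.
    """
    stat = float(pair.z_y**2)
    return stat, _chi2_sf(stat)


def corrected_estimate(pair: SummaryPair, rule: SelectionRule) -> CausalEstimate:
    """Winner's-curse-corrected MLE b_hat = y / mu_x_hat with the conditional test."""
    fit = fit_mu_x(pair, rule)
    stat, p = conditional_test(pair)
    return CausalEstimate(
        b_hat=pair.y / fit.mu_x_hat,
        method="corrected",
        statistic=stat,
        p_value=p,
    )


def smr_estimate(pair: SummaryPair, alpha: float = 0.05) -> CausalEstimate:
    """Classical SMR ratio estimate with delta-method variance and Wald CI.

    b_SMR = y/x, V_delta = (sigma_y^2 + b_SMR^2 sigma_x^2)/x^2 (two-sample
    form: the cross-covariance is zero across independent GWAS samples),
    T_SMR = b_SMR^2/V_delta ~ chi2(1), CI = b_SMR +/- z_{1-alpha/2} sqrt(V).
    No winner's-curse correction is applied.
    """
    if pair.x == 0:
        raise ZeroDivisionError("SMR ratio undefined for x = 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    b = pair.y / pair.x
    v = (pair.sigma_y**2 + b**2 * pair.sigma_x**2) / pair.x**2
    stat = b**2 / v
    z = float(norm.ppf(1 - alpha / 2))
    half = float(z * np.sqrt(v))
    return CausalEstimate(
        b_hat=float(b),
        method="smr",
        statistic=float(stat),
        p_value=_chi2_sf(stat),
        variance=float(v),
        ci_lower=b - half,
        ci_upper=b + half,
        ci_level=1 - alpha,
    )


def modified_smr(pair: SummaryPair, rule: SelectionRule) -> tuple[float, float]:
    """SMR-style statistic with the selection-aware variance plugged in.

    T_SMR-tilde = y^2 / (sigma_y^2 + sigma_tilde_x^2 * y^2 / mu_x_hat^2),
    where sigma_tilde_x^2 is the truncated-normal variance at mu_x_hat.
    Strictly smaller than the conditional test statistic whenever y != 0,
    i.e. strictly less powerful.
    """
    fit = fit_mu_x(pair, rule)
    var_trunc = cond_var(fit.mu_x_hat, pair.sigma_x, rule)
    stat = pair.y**2 / (pair.sigma_y**2 + var_trunc * pair.y**2 / fit.mu_x_hat**2)
    return float(stat), _chi2_sf(float(stat))
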