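"""One-sample two-stage least squares and its link to the SMR delta variance.

For one-sample individual-level data with a single (unselected) genetic
instrument, the SMR ratio b_gy_hat / b_gx_hat equals the TSLS estimate, and
the delta-method variance of the ratio — *including* the cross-covariance
term, which is nonzero within one sample — collapses algebraically to the
classical TSLS sampling variance:

    V_delta = n^-1 (y - b_hat x)'(y - b_hat x) / (x'Px),   P = g g'/g'g.

This module exists to exercise that identity numerically; it is a testing
surface, not part of the summary-data workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndividualSample", "gwas_coefs", "tsls_fit", "delta_variance_one_sample", "simulate_one_sample"]


@dataclass(frozen=True)
class IndividualSample:
    """Centered vectors of n observations: genotype g, exposure x, outcome y."""

    g: np.ndarray
    x_vec: np.ndarray
    y_vec: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.g, dtype=float)
        x = np.asarray(self.x_vec, dtype=float)
        y = np.asarray(self.y_vec, dtype=float)
        if not (g.ndim == x.ndim == y.ndim == 1 and g.size == x.size == y.size):
            raise ValueError("g, x_vec, y_vec must be 1-D vectors of equal length")
        if g.size < 3:
            raise ValueError("need at least 3 observations")
        for name, v in (("g", g), ("x_vec", x), ("y_vec", y)):
            if abs(v.mean()) > 1e-10 * max(1.0, np.abs(v).max()):
                raise ValueError(f"{name} must be mean-centered")
        if not np.any(g != 0):
            raise ValueError("g must not be identically zero")
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "x_vec", x)
        object.__setattr__(self, "y_vec", y)

    @property
    def n(self) -> int:
        return self.g.size


def gwas_coefs(sample: IndividualSample):
    """Marginal regression coefficients of x and y on g with their moments.

    Returns (b_gx, b_gy, var_gx, var_gy, cov_gxgy) where the second-order
    moments use the residual projector I - P, P = gg'/g'g, with 1/n scaling.
    The within-sample covariance of the two coefficients is generally
    nonzero — the reason TSLS cannot be run from two-sample summary data.
    """
    g, x, y = sample.g, sample.x_vec, sample.y_vec
    gg = g @ g
    if gg <= 0:
        raise ValueError("degenerate genotype vector")
    n = sample.n
    b_gx = (g @ x) / gg
    b_gy = (g @ y) / gg
    rx = x - b_gx * g  # (I - P) x
    ry = y - b_gy * g
    var_gx = (rx @ rx) / (n * gg)
    var_gy = (ry @ ry) / (n * gg)
    cov_gxgy = (rx @ ry) / (n * gg)
    return b_gx, b_gy, var_gx, var_gy, cov_gxgy


def tsls_fit(sample: IndividualSample) -> tuple[float, float]:
    """TSLS estimate of the causal effect and its classical variance.

    b_tsls = x'Py / x'Px = b_gy/b_gx; v_tsls = n^-1 (y-bx)'(y-bx) / (x'Px).
    """
    g, x, y = sample.g, sample.x_vec, sample.y_vec
    gg = g @ g
    gx = g @ x
    if gx == 0:
        raise ZeroDivisionError("instrument orthogonal to exposure: TSLS undefined")
    b = (g @ y) / gx
    px = (gx / gg) * g  # P x
    resid = y - b * x
    v = (resid @ resid) / (sample.n * (x @ px))
    return float(b), float(v)


def delta_variance_one_sample(sample: IndividualSample) -> float:
    """Delta-method variance of the ratio b_gy/b_gx with the covariance term.

    V = (var_gy + b^2 var_gx - 2 b cov) / b_gx^2.  For one-sample data this
    equals the TSLS variance exactly (the identity tsls tests verify).
    """
    b_gx, b_gy, var_gx, var_gy, cov = gwas_coefs(sample)
    b = b_gy / b_gx
    return float((var_gy + b**2 * var_gx - 2 * b * cov) / b_gx**2)


def simulate_one_sample(
    n: int,
    b_gx: float = 0.5,
    b: float = 1.0,
    confounding: float = 0.5,
    rng: np.random.Generator | None = None,
) -> IndividualSample:
    """Simulate confounded one-sample data under the structural model.

    g ~ Binomial(2, 0.3) (centered), x = b_gx*g + eps_x with eps_x correlated
    (strength ``confounding``) with an unobserved confounder u, and
    y = b*x + u + eps_y — so naive regression of y on x is biased but the
    instrument identities still hold.
    """
    rng = np.random.default_rng(rng)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    u = rng.normal(size=n)
    eps_x = confounding * u + np.sqrt(max(1.0 - confounding**2, 0.0)) * rng.normal(size=n)
    x = b_gx * g + eps_x
    y = b * x + u + rng.normal(size=n)
    return IndividualSample(g - g.mean(), x - x.mean(), y - y.mean())
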