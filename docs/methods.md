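# Methods

## Sampling model

One SNP contributes four summary statistics: the exposure-GWAS estimate `x`
with standard error `σx` and the outcome-GWAS estimate `y` with `σy`, from
two non-overlapping samples. Assumptions:

* `x` and `y` are independent and (pre-selection) normally distributed
  around the true effects `μx`, `μy` — adequate for the large GWAS sample
  sizes this targets, including binary traits via the normal approximation
  of logistic coefficients;
* `σx`, `σy` are known constants (their sampling variation is ignored);
* the SNP is a valid instrument, so the causal effect is `b = μy/μx`;
* the SNP entered the analysis only because `|x/σx| ≥ τ` held in the
  exposure GWAS (closed inequality; two-sided selection).

Under selection, `x ~ N(μx, σx²)` conditioned on the two tails. The density
is `φ((x−μx)/σx)/(σx·A)` with `A = 1 − Φ(α₂) + Φ(α₁)`,
`α₁ = −τ − μx/σx`, `α₂ = τ − μx/σx`; the mean is
`μx + σx(φ(α₂) − φ(α₁))/A` and the variance
`σ̃x² = σx²(1 + (α₂φ(α₂) − α₁φ(α₁))/A − ((φ(α₂) − φ(α₁))/A)²)`,
which depends on `μx`. At `τ = 0` everything reduces to the plain normal.

## Estimation

The conditional score equation sets the observed `x` equal to the truncated
mean; its root `μ̂x` is the conditional MLE. A sign argument confines the
root to the open interval between 0 and `x`, so the solver is a bracketed
Brent root-find on `x − E[x | μx]` over `(ε·sign(x), x)` with
`ε = 1e−12·σx`, absolute tolerance `1e−10·σx`, at most 200 iterations. If
bracketing ever fails the code falls back to bounded golden-section
maximization of the conditional log-likelihood over `(−|x|, |x|)` with ten
sub-bracket starts (the log-likelihood is treated as unimodal, consistent
with the smooth monotone shrinkage curve; the fallback has never triggered
in testing). A vectorized bisection variant (80 halvings on the same
bracket) serves the simulation engine, where thousands of SNPs are fitted
per batch.

All tail arithmetic is in log space: `log A` is assembled from
`log Φ̄(α₂)` and `log Φ(α₁)` via `logaddexp`, and the `φ/A` ratios as
`exp(log φ − log A)`, so selection probabilities at and far beyond the
genome-wide threshold (5×10⁻⁸ and smaller) keep full relative precision.

The corrected causal estimate is `b̂ = y/μ̂x`; H₀: b = 0 uses
`T = (y/σy)² ~ χ²₁` (exact under the model — the exposure likelihood terms
cancel between null and alternative). `b̂` is reported without a standard
error on purpose: its sampling distribution is heavy-tailed and far from
normal, which is the reason the interval estimate below is a likelihood
support rather than a Wald interval.

Numerical caveat worth recording: the MLE shrinkage `x/σx − μ̂x/σx` at
`x/σx = 7.5`, `τ = 5.45131` converges to 0.0561 (confirmed by forward
evaluation of the truncated mean and by an independent tight-tolerance R
optimization), slightly above the 0.05 often quoted as the point where the
winner's curse becomes negligible; that bound holds a little beyond
z = 7.5. Similarly, for the worked example `x/σx = 5.4599`,
`y/σy = 12.3155` the converged estimate is `b̂ = 33.412` with 2-unit-support
lower limit 2.141; values computed with looser generic-optimizer defaults
(e.g. ~1e−4 in `μx`) land a few thousandths away (33.413–33.416,
2.14–2.15).

## Support intervals

`pl(b) = max_{μx}[log Lx(μx) + log Ly(b·μx)]` is maximized at `b̂` with
`pl(b̂) = log Lx(μ̂x) + log Ly(y)`. The k-unit support is
`{b : pl(b) > pl(b̂) − k}`.

* Inner maximization (fixed `b`): dense scan of 201–241 points over a
  bracket spanning `μ̂x`, `y/b` and 0 widened by several units of
  `max(σx, σy/|b|)`, then a bounded scalar polish (scalar path) or 60
  vectorized golden-section steps (batch path). The scan guards against the
  bimodality that arises when the exposure and outcome likelihood components
  pull `μx` toward different modes. `pl(0)` is computed exactly from the
  decoupled form `log Lx(μ̂x) + log Ly(0)`, which also gives the duality
  `pl(b̂) − pl(0) = T/2` used for the `contains_zero` verdict.
* Boundary search: geometric expansion from `b̂` in steps
  `±2^m · 0.1·max(1, |b̂|)` until `pl` drops below the cut, then Brent
  root-finding between the last inside and first outside points
  (`xtol = 1e−10·max(1, |b̂|)`); bounded limits therefore sit on the cut to
  well below 1e−6. A limit is certified unbounded when the scan exhausts
  while the tail value `log Lx(0) + log Ly(y)` exceeds the cut.
* Disconnected supports are real: whenever the tail value exceeds the cut,
  `pl` climbs back above it for extreme `b`. The search continues a few
  steps past the first crossing, warns if it sees a re-crossing, and reports
  the connected component containing `b̂` (the conventional reading of the
  support as an interval).
* Calibration: `k_from_alpha(α, m) = χ²₁(1 − α/m)/2` matches support
  exclusion of 0 to the conditional test at the Bonferroni level `α/m`; the
  multiplicity count `m` is the number of *selected* SNPs in the input.

## Simulation engine

`run_table1` reproduces the coverage/power comparison: per true effect `b`
it draws `n_draws` exposure statistics `x ~ N(μx, σx²)`, keeps those with
`|x/σx| ≥ τ`, pairs each with an independent `y ~ N(b·μx, σy²)`, and
summarizes the corrected estimator (mean, median, k-unit support coverage of
the true `b`, power of `T`) against SMR (mean, median, Wald CI coverage,
power of `T_SMR`). Defaults — `μx = 4`, `σx = σy = 1`, `τ = 5.45131`,
100,000 draws, 2-unit supports, 95% CIs — retain ≈7.3% of draws (≈7,400
pairs), so coverage/power proportions carry Monte-Carlo standard errors of
roughly 0.002–0.006. The selected count is left binomial rather than fixed:
any single published count is itself one binomial realization.

Coverage of the true `b` is evaluated by superlevel membership
`pl(b) > pl(b̂) − k` (equivalent to membership in the support's defining
set, and cheaper than locating both limits); at `b = 0` this reduces
exactly to `T ≤ 2k`.

Randomness: a master seed plus a per-`b` substream keyed by the value of `b`
(micro-unit resolution), so adding, dropping or reordering effect values
never changes the draws of the others; results are bit-reproducible for a
given seed.

What the generator emulates — and does not: it draws summary statistics
directly from the sampling model (known σ's, a single instrument, perfectly
independent samples, exact normality, one common `μx`). It does not emulate
linkage disequilibrium between candidate SNPs, effect-size heterogeneity,
sample overlap, allele-harmonization errors or σ estimation noise, so
passing tests demonstrate correctness of the method under its own
assumptions, not robustness to those real-data complications.

## One-sample TSLS identity

A validation module simulates confounded one-sample data
(`x = b_gx·g + εx` with `corr(εx, u) = 0.5` by default, `y = b·x + u + εy`)
and checks to 1e−10 that the ratio estimate equals two-stage least squares
and that the delta-method variance of the ratio — including the
within-sample covariance term — collapses to the classical TSLS variance.
This anchors the two-sample `V_delta` (covariance dropped, samples
independent) in the standard instrumental-variable theory.

## Problem sizes used in checks

The bundled tests and the acceptance script run the simulation at the full
design size (100,000 draws per effect value; a few seconds per run thanks to
the vectorized fitting and profile paths) and the rejection-sampling oracles
for the truncated moments with ≥10⁶ accepted draws wherever the acceptance
probability makes rejection sampling tractable (τ = 2 at μx ∈ {0, 1, 4};
τ = 5.45131 at μx = 4). At (μx = 0, τ = 5.45131) the acceptance probability
is 5×10⁻⁸, so rejection sampling is physically infeasible; the density at
such parameters is validated by quadrature normalization instead.

## Known limitations

* Single-SNP analysis only; no IVW/MR-Egger style multi-SNP combination.
* Non-overlapping exposure and outcome samples are assumed; overlap changes
  the joint likelihood and is not supported.
* Two-sided selection on the z-scale only; no one-sided rules or selection
  on non-normal test statistics.
* LD pruning, clumping and allele harmonization are upstream of this
  package: the input table is assumed pre-harmonized, one row per
  independent SNP.
* The corrected point estimate is biased (`E[y]·E[1/μ̂x] ≠ b`) and
  heavy-tailed, especially for barely-selected instruments; the support
  interval, not the point estimate, is the primary inferential output.
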