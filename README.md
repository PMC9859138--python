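# wcmr — winner's-curse-corrected two-sample Mendelian randomization

`wcmr` estimates the causal effect of an exposure on an outcome from per-SNP
GWAS summary statistics in the common situation where the instrument SNP was
*selected from the exposure GWAS itself* (typically at genome-wide
significance, p < 5×10⁻⁸). That selection induces a winner's curse: the
exposure effect estimate of a selected SNP is biased away from zero, so the
naive Wald/SMR ratio underestimates the causal effect and its confidence
interval under-covers.

The package is for statistical geneticists and epidemiologists running
single-instrument two-sample MR from summary data (effect estimate and
standard error per SNP from two non-overlapping GWAS).

## The model

For one SNP, write `x, σx` for the exposure-GWAS effect estimate and its
standard error and `y, σy` for the outcome-GWAS pair; `μx, μy` are the true
effects and the causal effect is `b = μy/μx`. Because the SNP was kept only
when `|x/σx| ≥ τ`, the sampling distribution of `x` is the normal `N(μx,
σx²)` conditioned on the two tails, with selection probability

    A(μx) = 1 − Φ(α₂) + Φ(α₁),   α₁ = −τ − μx/σx,  α₂ = τ − μx/σx.

The conditional MLE `μ̂x` solves the score equation `x = μx +
σx(φ(α₂) − φ(α₁))/A` — the observed `x` equals the truncated mean — and
always shrinks strictly toward zero (`0 < μ̂x < x` for `x > 0`). The
corrected causal estimate is `b̂ = y/μ̂x`, and H₀: b = 0 is tested by the
conditional likelihood-ratio statistic `T = (y/σy)² ~ χ²₁`, which stays valid
under selection because the exposure terms cancel.

Since the effective sample size per SNP is one, no asymptotic confidence
interval exists for `b` away from 0. The interval estimate is the *k-unit
support*: the set of `b` whose profile log-likelihood

    pl(b) = max_{μx} [ log Lx(μx) + log Ly(b·μx) ]

lies within `k` units of its maximum `pl(b̂)`. Choosing
`k = χ²₁(1 − α/m)/2` makes "support excludes 0" coincide with the conditional
test rejecting at the Bonferroni-adjusted level `α/m` (k = 1.92 for α = 0.05
and one SNP; k = 5.9 for 84 SNPs). A support limit can be genuinely
unbounded — `pl(b)` tends to `log Lx(0) + log Ly(y)` as `|b| → ∞` — and the
search certifies this rather than guessing a large number.

For comparison the classical SMR estimator is always reported alongside:
`b̂_SMR = y/x`, `V_delta = (σy² + b̂²_SMR σx²)/x²`, Wald CI, and the χ²₁ test
`T_SMR = b̂²_SMR/V_delta`. A small companion module verifies the identity
that for one-sample individual-level data without selection the delta-method
variance (including the within-sample covariance term) equals the classical
two-stage least squares variance.

## Worked example

A just-selected SNP (`x/σx = 5.4599` at τ = 5.45131) with a strongly
significant outcome association (`y/σy = 12.3155`):

```python
from wcmr import (SummaryPair, SelectionRule, corrected_estimate,
                  smr_estimate, support_interval)

pair = SummaryPair(x=5.4599, sigma_x=1.0, y=12.3155, sigma_y=1.0)
rule = SelectionRule()          # tau = 5.45131, genome-wide significance
est = corrected_estimate(pair, rule)
sup = support_interval(pair, rule, k=2.0)
smr = smr_estimate(pair, alpha=0.05)
print(f"corrected b_hat = {est.b_hat:.3f}  (T = {est.statistic:.2f}, p = {est.p_value:.3g})")
print(f"2-unit support  = {sup}")
print(f"SMR b_hat       = {smr.b_hat:.3f}  (95% CI {smr.ci_lower:.3f} to {smr.ci_upper:.3f})")
```

prints

```
corrected b_hat = 33.412  (T = 151.67, p = 7.48e-35)
2-unit support  = 2-unit support (2.141, Inf)
SMR b_hat       = 2.256  (95% CI 1.370 to 3.141)
```

The exposure z-score barely clears the threshold, so the winner's-curse
shrinkage is severe: the MLE of `μx` is 0.369 against the observed 5.46, and
the corrected estimate 33.4 is an order of magnitude above the naive ratio
2.26 — with a support whose upper limit is certified unbounded, honestly
reflecting how little one barely-selected instrument says about the
magnitude of `b`. (The support is also disconnected here — the profile
likelihood climbs back above the cut for very small `b` — and `wcmr` warns
and reports the component containing `b̂`.)

The same workflow from the shell:

```sh
wcmr run --input sumstats.tsv --output results.tsv --adjust bonferroni
wcmr simulate --b-values 0,0.5,1,1.5,2 --n-draws 100000 --seed 1
wcmr calibrate-k --alpha 0.05 --n-tests 84
```

Input is a TSV with columns `snp, beta_exposure, se_exposure, beta_outcome,
se_outcome` (remappable via `--column-map`).

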