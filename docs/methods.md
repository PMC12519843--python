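# Methods

`fircompat` models the aboveground biomass (AGB) of Chinese fir
(*Cunninghamia lanceolata*) and its four components — bark, trunk (stem
wood), branch and leaf, all in kg dry mass — from two UAV-LiDAR tree
metrics: tree height `LH` (m) and crown diameter `LCD` (m).  Three model
layers build on one another, and a synthetic stand generator supplies
data with the statistical structure the analysis assumes, because the
field data behind the published coefficients are withheld.

## Model layers

**Candidate single-equation forms.**  Four mean functions compete per
response:

| form        | mean function                          | parameters |
|-------------|----------------------------------------|------------|
| logistic    | `a / (1 + b·exp(−c·LH − d·LCD))`       | 4          |
| linear      | `a·LH + b·LCD − c`                     | 3          |
| exponential | `a·exp(−b·LH − c·LCD)`                 | 3          |
| power       | `a·LH^b·LCD^c`                         | 3          |

Sign conventions are kept exactly as in the source reference tables —
the exponential form carries negative signs inside the exponent, so a
fitted negative `b, c` means a positive effective growth exponent.
Forms are ranked by AIC on the training data; if the top two differ by
no more than 2 AIC units, the form with fewer parameters wins (which is
how a logistic/power near-tie resolves to the power form).

**Age-group dummy model.**  Stand age enters as a five-level factor
(young 1–10 y, middle-aged 11–20 y, near-mature 21–25 y, mature
26–35 y, over-mature >36 y) through group-specific scale coefficients
with shared exponents: `BM = (Σᵢ b0ᵢ·Sᵢ)·LH^b·LCD^c`, `Sᵢ` the 0/1 group
indicator.  All five scales are estimated directly; the multiplicative
form has no separate intercept, so the "n−1 dummies" rule for linear
encodings does not apply here (the reference-category view is documented,
not implemented).  The base power model is the equal-scales special
case, making the pair nested: the dummy fit is initialised *at* the base
solution, so its training RSS can only be lower or equal.

**Additivity-constrained NSUR.**  The four component equations (each a
dummy power model) are estimated jointly by nonlinear seemingly
unrelated regression.  The total is the identity
`total = bark + trunk + branch + leaf`, enforced at prediction time and
*not* estimated as a fifth equation — its residuals are an exact linear
combination of the component residuals and would make the residual
covariance singular.  The estimator is iterated feasible GLS: from
equationwise starts, alternate `Σ̂ = R'R/n` (4×4 residual covariance,
`1/n` divisor by default, `1/(n−p)` available) with a damped Gauss–Newton
minimisation of `Σᵢ rᵢ'Σ̂⁻¹rᵢ`, implemented by whitening each tree's
residual 4-vector with the Cholesky factor of `Σ̂`.  Convergence is
declared on the parameters (relative change < 1e-8, max 100 outer
iterations); `Σ̂` at the final iterate is reported.  A near-singular `Σ̂`
receives an escalating ridge on the diagonal with a logged warning.
`fit_nsur(fixed_sigma=...)` runs one GLS pass with a *known* covariance;
with a diagonal matrix the criterion separates by equation and the
estimates must coincide with equationwise least squares — the oracle
test for the whitening machinery.

## Optimisation and uncertainty

All nonlinear fits share one deterministic Levenberg–Marquardt engine
(`fircompat._optimize`): accepted steps never increase the objective
(the trajectory is stored and asserted in tests), convergence requires
relative parameter change < 1e-10 or relative RSS change < 1e-12 within
200 iterations, and non-convergence returns a flagged fit rather than an
exception.  Initial values are deterministic log-linearisations: OLS of
`ln y` on `(ln LH, ln LCD)` for the power form, on `(LH, LCD)` for the
exponential, plain OLS for the linear form, and for the logistic
`a ← 1.05·max(y)` with the remaining parameters from OLS of
`ln(a/y − 1)`.

Standard errors default to the heteroscedasticity-robust sandwich
`(J'J)⁻¹(J' diag(r²) J)(J'J)⁻¹` (a tree-clustered analogue for the NSUR
system), because biomass scatter grows with tree size while the fits are
unweighted — the classic `σ̂²(J'J)⁻¹` covariance (available as
`se_method="classic"`) understates uncertainty under that error
structure.  A rank-deficient Jacobian (e.g. a logistic fitted to data
with no covariate effect) yields inflated/infinite standard errors, not
an exception.  An optional per-equation power-variance weighting exists
for sensitivity analysis and is off by default.

## Evaluation metrics

The source conventions are implemented verbatim and pinned by tests:
`R² = 1 − RSS/TSS`; `RMSE = √(RSS/(n−1))` — note the `n−1` denominator,
not `n`; `TRE = Σ|y−ŷ|/Σy` in absolute form (a signed variant is
provided under a separate name).  `AIC = 2k − 2 ln L` and
`BIC = k·ln n − 2 ln L` use the Gaussian likelihood concentrated over
the error variance, `ln L = −(n/2)(ln(2π·RSS/n)+1)`; a zero RSS is
signalled as degenerate rather than silently returned.  Relative changes
between models are `(new−old)/old × 100` on the metric itself.

## Synthetic stand generator

The generator emulates the study conditions: 20,836 trees in 133-plot
batches across the five age groups.  Only the youngest (7,481) and
oldest (1,885) group sizes are reported for the source study; the middle
groups default to 4,600 / 3,600 / 3,270, interpolated once to the
reported total.  Structure:

- `LH` per group from a lognormal (medians 10.0 / 12.5 / 14.5 / 16.5 /
  17.5 m, increasing with age; log-sd 0.25) truncated to 2.7–31.7 m —
  the published covariate envelope.  Only pooled moments are published;
  the per-group medians are an interpolation choice made once.
- `LCD = 0.23·LH^0.9` times mean-one lognormal noise (log-sd 0.45),
  matching the pooled crown-diameter mean (≈2.3 m) and its strong right
  skew.
- Component biomass = published NSUR system allometry (the only fully
  specified per-age-group coefficient set available) × multiplicative
  mean-one lognormal error with per-component CV 0.30 and pairwise
  Gaussian-copula correlation 0.5.  CV 0.30 reproduces the R² ≈ 0.7
  scatter scale of the source fits; correlation 0.5 makes joint
  estimation meaningfully different from equationwise fitting.
- The total is always the exact sum of the four components; it is never
  drawn.

Draw order (groups in age order; within a group: `LH`, then the `LCD`
noise, then the n×4 error matrix) is part of the format contract; one
seeded generator threads through all draws, so output CSVs are
byte-identical for identical (config, seed).

A second path generates biomass from DBH/height via the national-standard
style allocation equations (`M_A = a0·D^a1·H^a2` split by fixed
bark/branch/leaf-to-stem ratios) with `LH`/`LCD` attached as noisy
proxies.  The standard's real coefficients are not distributed; the
shipped `PLACEHOLDER_PARAMS` are synthetic, for tests and examples only.

**What passing tests do and do not show.**  The generator produces
exactly additive, power-law-true data with lognormal errors and clean
covariates.  Real field data add measurement error in the covariates
themselves, segmentation errors from the LiDAR pipeline, model
misspecification, and spatial/plot-level dependence — none of which are
emulated, so recovery results here demonstrate correctness of the
estimators, not field-data performance.  Two consequences surfaced in
testing and are worth knowing:

- With an *estimated* `Σ̂`, sampling noise in its off-diagonals moves the
  NSUR solution away from equationwise NLS by O(n^−1/2) (≈0.5% at
  n = 2,000) even when the generating correlation is zero; exact
  equivalence holds only for a known diagonal covariance, which is how
  the oracle test is run.
- The classical SUR efficiency gain (lower sampling variance than
  equationwise fitting under cross-equation correlation) holds in the
  additive homoscedastic-error setting GLS assumes — measured at ~96% of
  parameters with a median variance ratio 0.92 under correlation 0.7.
  Under the generator's default multiplicative errors the constant-Σ
  weighting is misspecified and the gain disappears; the efficiency test
  therefore constructs additive correlated errors on the noise-free
  means.

## Published reference values

`fircompat.published` stores the source study's coefficient tables and
summary statistics verbatim as generator defaults and regression
anchors.  Several entries of the biomass summary are internally
inconsistent (apparent typographic duplications across rows); they are
flagged in `SUSPECT_SUMMARY_ENTRIES` and excluded from calibration
checks, never corrected.  Likewise the published trunk/bark rows of both
the single-equation table and the SUR system appear label-swapped
relative to each other's magnitudes; values are stored under their
printed labels with a caveat flag.  A checksum test pins the stored
values against accidental edits.

## Problem sizes and numerical choices

Tests run the generator at 1,000–2,500 trees (study-proportioned group
shares) and the Monte-Carlo studies at the sizes their claims name
(n = 2,000 replicated 50×; 500/group for the dummy-scale study), which
the fitting engine completes in seconds.  The split rule is
`round(0.7·n)` per stratum, stratified by age group so that all five
groups appear in both partitions (the dummy and SUR stages require it);
a stratum too small to contribute a test tree goes wholly to training
with a warning.  Duplicate `(plot_id, tree_id)` rows, non-positive
covariates, out-of-range age groups and additivity violations beyond
1e-9 relative are rejected at CSV load with row-numbered diagnostics.

## Known limitations

- Age is categorical only; no continuous-age or mixed-effects extension.
- No error-in-variables treatment of the LiDAR covariates.
- The allocation path's age assignment (DBH quintiles) is a synthetic
  stand-in for a real stand-age record.
- Heteroscedasticity is acknowledged through robust standard errors, not
  through weighted estimation, by default — matching the unweighted
  source fits.
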