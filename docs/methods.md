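# Methods

## Model

Postoperative endothelial cell count is modelled as a two-phase
exponential decay,

    ECC(t) = a·e^(b·t) + c·e^(d·t),    t ≥ 0 months,

with scale factors `a, c > 0` (cells/mm², or dimensionless fractions of
the donor count in synthetic mode) and rate constants `b, d < 0`
(1/month). Parameters are kept in the canonical order `|b| ≥ |d|`, so
the first term is always the fast/early phase; the fitter enforces this
after optimisation, making the "early"/"late" labels well defined
regardless of the optimizer's output order. The model is phenomenological:
it assumes the pooled mean series decays smoothly, with no regeneration,
no plateau, and the same functional form inside and beyond the observed
window — extrapolations to decades rest entirely on that assumption.

Derived quantities follow the field's reporting conventions:

- **Half-times** `ln 2/|b|` (early) and `ln 2/|d|` (late), reported to
  2 decimals. They are computed from whatever coefficients they are
  given; feeding coefficients that were rounded for publication
  reproduces the small discrepancies such rounding creates (e.g.
  `ln 2/0.2298 = 3.02` where the source analysis, working from the
  unrounded rate, printed 3.03).
- **ECL** at a horizon is a percent of the *preoperative donor* ECC,
  not of the fitted curve's t = 0 value. The fitted `a + c` (≈1757
  cells/mm² for the reference coefficients) sits far below the donor
  mean (2518.46) because the first fitted visit is already one month
  after surgery; only the donor baseline reproduces the reported ECL
  values. Rounded to a whole percent for presentation.
- **Threshold crossings** are the largest whole month at which the
  curve is still at or above the threshold: the continuous crossing is
  bracketed by doubling, located by Brent root-finding to 1e-6 months,
  and floored. Flooring is the only whole-month convention consistent
  with continuous crossings ≈218.3 and ≈349.8 both printing as 218 and
  349. After flooring, the defining inequality is re-checked directly
  against the curve so root-tolerance wobble around integer crossings
  cannot shift the month.

## Synthetic cohorts

`CohortConfig` defaults encode the study conditions the package
emulates: 65 eyes; donor ECC rejection-sampled from a normal
(mean 2518.46, SD 89.95 cells/mm²) truncated to [2300, 2700]; visits at
1, 3, 6, 9, 12, 18, 24 months with exactly 14 randomly chosen eyes
re-examined at 36 months; round(65 × 35/65) = 35 eyes assigned to the
DMEK+phaco arm (a deterministic count, matching the reported 35/30
split exactly, rather than a Bernoulli draw).

Each eye decays along its arm's curve expressed as a *fraction* of its
own donor count: expected ECC at month t is `donor_ecc × (a·e^{bt} +
c·e^{dt})` with fractional `a, c`. The pooled mean of such a cohort is
again biexponential with scales `donor-mean × (a, c)`, which is what
lets one cohort target the absolute reference coefficients.

Per-arm default kinetics use the subgroup half-times reported for real
cohorts — DMEK-only 2.26/250.32 months, DMEK+phaco 4.06/98.05 months.
The subgroup scale fractions are not reported anywhere, so they are
fixed here by two constraints: each arm's 120-month ECL against its own
donor count equals the reported 56% (DMEK-only) and 72% (phaco), and
t = 0 retention matches the pooled fit's `a + c` (≈0.698 of donor).

Measurement noise is additive Gaussian, homoscedastic across visits,
truncated at zero, with default SD 20 cells/mm² (~1% of the donor mean,
a typical specular-microscopy repeatability figure; the source analysis
states no noise model). Dropout is not modelled beyond the 36-month
subset, and follow-up to 24 months is complete.

What the generator deliberately does **not** emulate: real between-eye
biological variability in decay kinetics (every eye in an arm shares one
fractional curve), rebubbling and its effect on ECC, visit-time jitter,
or attrition. Consequences worth keeping in mind: per-visit arm means
are far less noisy than real data (SD ≈ 3.5 cells/mm² for a 32-eye arm
versus between-eye SDs of hundreds), so subgroup tests on synthetic
cohorts with genuinely different arm kinetics reject almost surely —
unlike the real study, which found no significant arm difference.
Passing tests therefore demonstrate correctness and calibration of the
statistics, not that real cohorts of this size would separate the arms.

## Fitting

Mono- (`c·e^{dt}`) and biexponential curves are fitted to the per-visit
*mean* series (per-eye mixed modelling is out of scope) by bounded
nonlinear least squares (`scipy.optimize.least_squares`, trust-region
reflective, analytic Jacobian, `x_scale="jac"` to condition the very
different scale/rate magnitudes; ftol = xtol = 1e-12, gtol = 1e-10, at
most 10,000 evaluations). Bounds impose decay: scales in [0, ∞), rates
in [−60, 0] (a half-time of half an hour is far below anything
physiological). The preoperative donor ECC is not a fit point; the fit
window defaults to months ≤ 24 with later visits held out. Least
squares is unweighted: per-visit sample sizes are equal through 24
months anyway, and no weighting scheme is part of the reference method.

Starting values come from classical curve peeling: a log-linear
regression on the late half of the series estimates (c, d); the early
residuals, clamped positive, estimate (a, b); the fallback when peeling
fails is `(0.1·y₀, −0.3, 0.9·y₀, −0.005)`. A deterministic multi-start
— the peel guess plus the four variants with each rate multiplied or
divided by 3 — is run and the lowest RSS wins, so a fixed series always
returns a bit-identical fit. Spot checks against an independent
implementation (R's `minpack.lm::nlsLM`) agree with the constrained
optimum up to the intended `d ≤ 0` bound.

Two degenerate regimes are handled explicitly. If both fitted rates are
(numerically) zero there is no decay signal and the fit is rejected. If
the two rates coalesce (|b − d| ≤ 1e-3·|d|) the split of the scale
between phases is not identifiable — any split along the ridge gives
the same curve — so the fit collapses to the optimal single-phase
representative (`a = 0`, found by the monoexponential path). This also
preserves the nested-model guarantee that the biexponential RSS never
exceeds the monoexponential RSS.

Model selection compares R² = 1 − RSS/TSS of the two families, with
differences below 1e-12 treated as ties broken toward the simpler
model. R² (not AIC/BIC) is the criterion because it is the reference
method's criterion. R² is undefined (error) for a constant series.

The fit's log-likelihood is the profile Gaussian likelihood at the MLE
variance RSS/n, `−(n/2)(ln(2π·RSS/n) + 1)`; a perfect fit (RSS = 0) has
unbounded likelihood and is reported as +inf by `FitResult` while
`gaussian_loglik` itself rejects it.

## Subgroup comparison

`lrt_subgroup_vs_pooled` asks whether a subgroup's mean series is
adequately described by the pooled-cohort curve. The restricted model
is the pooled parameters evaluated on the subgroup series (0 free
parameters); the unrestricted model refits all four parameters, giving
the likelihood-ratio statistic `stat = n·ln(RSS_r/RSS_u)` with 4
degrees of freedom and the decision `h = 1` iff p < α (default 0.05).

With only ~7 visit means, referring that statistic to its asymptotic
χ²(4) distribution is badly anticonservative: simulated null cohorts
(both arms sharing one curve) rejected at ~0.17 instead of 0.05. The
p-value therefore uses the statistic's exact finite-sample null
distribution under the Gaussian model: the monotonically equivalent
extra-sum-of-squares F statistic `((RSS_r − RSS_u)/4)/(RSS_u/(n − 4))`
referred to F(4, n − 4). Because the pooled parameters are themselves
estimated from data that contain the subgroup, the restricted RSS is
somewhat deflated and the calibrated test runs conservative (simulated
null rejection ≈0.02 at α = 0.05); its power against arms with late
half-times 98 vs 250 months at low noise is ≈1.

Arm comparisons in the pipeline run on **donor-normalized** series:
each eye's measurements are rescaled by (cohort-mean donor ECC)/(its
own donor ECC) before averaging. Without this, random between-arm
differences in mean donor count (~0.5% of baseline for 30-odd-eye arms)
masquerade as kinetic differences and inflate the null rejection rate
several-fold; normalization removes the scale offset and leaves the
decay kinetics untouched.

Per-visit arm differences in ECL (each eye against its own donor
baseline) use the classic equal-variance two-sided Student's t-test,
one test per visit month with no multiplicity correction (mirroring
per-timepoint reporting). Rebubbling-style 2×2 arm × outcome tables use
Pearson's chi-squared without continuity correction, df = 1; the
generator does not simulate rebubbling, so the pipeline includes this
test only when a table is supplied.

## Pipeline and reproducibility

`run_pipeline` executes simulate → aggregate → fit → derive → compare,
writing the cohort CSV, fit/summary/comparison JSON, a Markdown
summary, and a manifest with the seed and a SHA-256 hash of the
scientific configuration (the output directory is excluded from the
hash). One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence.spawn`, so a stage can be re-run in
isolation; identical configurations produce byte-identical artifacts
(CSV floats are written and re-read at full round-trip precision).
JSON carries full precision; rounding (2-decimal half-times, whole
percent ECL, whole months) is applied only in the Markdown summary.

## Test problem sizes

Stochastic suites use sizes chosen to make the checked quantities
stable: 500 replicate noisy series for parameter recovery (the
late-rate estimator's half-time distribution has a heavy right tail
from occasional boundary fits with d → 0, so a median over 100
replicates is itself too noisy to test against a 15% band), 500 null
cohorts (1000 arm-level LRTs) for the type-I band, and 60 low-noise
cohorts for LRT power.

## Known limitations

- Extrapolation to 10–30 years inherits every assumption of the
  two-phase form; no confidence intervals are attached to derived
  quantities.
- The fit targets the pooled mean series; per-eye heterogeneity in
  kinetics is neither modelled nor estimable from the mean.
- The LRT treats the pooled parameters as fixed, and its F calibration
  is exact only under the Gaussian, fixed-restricted-curve
  idealisation; as measured, the net effect is mildly conservative.
- The generator's noise model makes synthetic subgroup comparisons far
  more powerful than real ones of the same size (see above).
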