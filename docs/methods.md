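# Methods

## The modelling problem

A single-year fertility schedule assigns to each age x ∈ {15, …, 49} the
age-specific fertility rate f(x), births per woman per year. Its sum over
the 35 ages is the total fertility rate (TFR). Schedules in
moderate-fertility populations such as India's are unimodal and right-
skewed, with a sharp peak near ages 19–24 and a long, thin upper tail.
The package treats the schedule as a 35-point regression problem: choose a
parametric curve family, minimise the sum of squared errors
SSE = Σₓ (f(x) − f̂(x))², and compare families by small-sample AICc.

## Curve families

Nine families are registered (see the README table). Four design points
deserve comment.

**P-K exponent sign.** The two-sided Gaussian ("P-K") curves are
implemented as b·exp{−((x−μ)/σ)²}; the variant without the minus sign,
which occasionally appears in print, is unbounded and cannot describe a
fertility schedule.

**Modified skew normal Φ argument.** The default branch factor is
Φ((δ·x − λ)/s) (`phi_arg="shifted"`); the alternative reading
Φ(δ·(x − λ)/s) is available as `phi_arg="centered"`. With the shifted
argument and the bundled NFHS-4 estimates the curve is numerically
indistinguishable from the modified P-K curve, which is the behaviour the
reference estimates display. The shifted form makes the curve piecewise
with a potential jump at x = λ: the jump is < 10⁻⁹ when δ ≥ ~2.5 (the Φ
factor saturates at 1 on both branches) but is a genuine small
discontinuity (≈ 0.007 births/woman/year) at low skewness such as the
Gujarat and Karnataka reference estimates (δ ≈ 1.5). The test suite bounds
it; users fitting low-δ populations who need continuity should use the
centred variant.

**Identifiability of the modified Gompertz family.** The four-parameter
curve (α/β)^γ·exp[−z − α·e^(−z)], z = (x−m)/β, carries an exact
one-dimensional reparametrisation ridge: for any shift c, the parameter
set (α·e^(c/β), γ′, m) with γ′ = (γ·ln(α/β) + c/β)/(ln(α/β) + c/β)
produces the identical curve. Consequently α, γ and m are not separately
identifiable from data; only β, the peak location m + β·ln α, the peak
height (α/β)^γ·e^(−(1+ln α)) and every other functional of the curve are.
Fits to the same schedule from different starts may therefore report very
different (α, γ, m) triples with equal SSE; published parameter tables for
this family should be read as one arbitrary point on the ridge. Tests
assert recovery of the identified quantities only.

**δ saturation in the modified skew normal.** At the bundled estimates the
Φ factor equals 1 to machine precision at every age, so δ is only bounded
below by the data, not estimated; tests treat it as unidentified.

## Derived quantities

`model_peak` maximises a curve over continuous age by a 10⁻³-year grid
refined with bounded golden-section search (ties broken toward the younger
age); closed forms — μ for the P-K curves, m + β·ln α for the Gompertz
family, 15 + 49·q/(q+r) for the modified G-P curve — serve as independent
oracles in the tests. `model_implied_tfr` sums the curve at integer ages
15–49, matching how observed single-year ASFRs aggregate to TFR; for the
Gompertz family it agrees with the analytic integral β·(α/β)^γ/α to within
the ~2% truncation/discretisation error at realistic parameter values.

## Estimation

`FertilityCurveModel.fit()` minimises SSE with scipy's bounded
trust-region-reflective least-squares solver (ftol = xtol = gtol = 10⁻¹²,
≤ 2000 residual evaluations per start), the standard choice for small
nonlinear regression problems, from:

1. a deterministic data-driven start — peak-shaped families start at the
   empirical maximum (height = max rate, location = argmax age, spreads
   3/9 years, late-age constants at the mean 45–49 rate); the Gompertz
   family at m = min age − 1, α = β = 4, γ = 10 (γ = 1 base); Hadwiger at
   c = argmax age, a = TFR/2, b = 3.5; the beta-kernel families place the
   kernel mode at the argmax age with q = 2.5;
2. 19 seeded jitters of that start (default seed 20210323): multiplicative
   log-normal (sd 0.3) on positive parameters, additive ±3 years on ages,
   additive N(0,1) on the signed skewness;
3. for a modified family, the fitted base-family solution extended with
   the neutral extra parameter (a = 0, γ = 1, s = 0). For the true
   nestings (modified P-K ⊃ P-K, modified Gompertz ⊃ Gompertz) this makes
   the modified family's minimised SSE ≤ the base family's up to solver
   tolerance on every input, a property the tests enforce. (The modified
   G-P curve shifts and rescales the age axis, so its s = 0 restriction is
   not the original G-P curve; the extended start is still used, merely as
   one more start.)

Default box bounds: rate-scale parameters (10⁻⁶, 1]; late-age constants
[0, 0.05]; age locations [10, 49]; spreads and α, β (0.1, 30]; γ
(0.1, 50]; q, r (0.01, 50]; p (10⁻⁶, 10⁶); δ [−30, 30]; Hadwiger a
(0.01, 10], b (0.1, 20], c [15, 45]. These cover all bundled reference
estimates with a wide margin and keep the objective finite.

Gauss–Newton asymptotic standard errors (cov = s²(JᵀJ)⁻¹ with a central-
difference Jacobian) are available via `results.bse()` but are not shown
by `summary()` unless requested: for these strongly nonlinear, partially
non-identified families the point estimates are the useful output, and for
the ridge directions described above the SEs are meaningless.

## Model selection

AIC = 2k + n·ln(SSE/(n−k)) and AICc = AIC + 2k(k+1)/(n−k−1). Note the
degrees-of-freedom denominator n−k inside the logarithm (not the more
common n): the bundled published AICc tables are reproducible only on this
scale, and the package standardises on it throughout. A perfect fit
(SSE = 0) yields −∞ with a warning. AICc is used because n/k ≤ 12 here,
far below the n/k ≈ 40 rule of thumb for plain AIC; as n → ∞ the
correction vanishes. `compare_models` requires fits on the same number of
ages, sorts ascending by AICc, and on near-ties (|ΔAICc| < 0.01) prefers
the family with fewer parameters — encoding parsimony when fits are
practically indistinguishable. R² is defined as 1 − SSE/TSS about the mean
observed rate (a convention; other definitions exist for nonlinear fits).

## ASFR from birth histories

Dates use the DHS century-month code, CMC = 12·(year − 1900) + month, and
age is completed years (months ÷ 12). For a window of w months (default
36) before the interview, each woman contributes 1/12 woman-year of
exposure at completed age x for every month in
[interview − w, interview − 1] during which her age is x; the interview
month itself is excluded, matching the usual "three years preceding the
survey" convention. Births in the window are tallied at the mother's
completed age at delivery, and rate(x) = weighted births / weighted
woman-years. Sampling weights are supported (default 1); rates are
invariant under rescaling all weights. Ages with zero exposure receive
rate 0 and a warning flag rather than an error, so small simulations still
produce complete 35-age schedules.

## Loess smoothing

Single-year ASFRs from retrospective microdata show sampling fluctuation
and age heaping, so a loess smoother is provided (and can be applied
before fitting via `fit_to_smoothed=True`). At each age the
⌈span·n⌉ nearest ages get tricube weights (1 − (d/dmax)³)³ and a local
polynomial (degree 2 by default) is fitted by weighted least squares;
span = 0.2 (7 of 35 ages) removes the fluctuation without flattening the
peak. The smoother is linear, hence shift- and scale-equivariant, and
reproduces polynomials up to its degree exactly; negative fitted values
are clipped to 0 (rates cannot be negative). **Models are fitted to the
raw schedule by default**: smoothing before fitting changes SSE/AICc
scales and is offered as an explicit option, not silently applied.
Robustness iterations exist (bisquare reweighting) but default to 0. No
attempt is made to replicate any particular statistical package's
interpolation shortcuts; the degree-1 case is cross-checked against
statsmodels' lowess in the tests, the general case against a brute-force
oracle.

## Synthetic data

The generators emulate the survey setting the reference estimates came
from: unimodal right-skewed schedules over ages 15–49 with TFR ≈ 1.6–2.8
and peak rate 0.13–0.23 at ages 19–24 (the bundled parameter tables are
the default truth curves).

* `generate_schedule` adds seeded Gaussian noise (default sd 0.002,
  truncated at 0) to the truth curve, or draws binomial counts
  births ~ Bin(women-per-age, f(x)).
* `simulate_birth_histories` draws women whose interview ages are uniform
  over 15–49 at month resolution (interview month fixed at CMC 1396,
  April 2016, the NFHS-4 fieldwork era) and, for every month lived from
  exact age 15, a birth with independent probability f(age)/12.

The monthly Bernoulli hazard has **no gestation or birth-interval
constraint** — a deliberate biological simplification. At the rates
involved (< 0.25/yr) interval structure is immaterial to events/exposure
estimation, and the simplification makes the implied rates exactly equal
the target schedule, so the estimator can be validated against an exact
truth. Consequently the simulator does not reproduce parity progression,
marriage timing, or survey design (clustering, stratified weights), and
passing pipeline tests demonstrate correctness of the estimators under
the stated sampling model — not robustness to those real-data features.
Simulation sizes in the tests (200 000 women, vs the several hundred
thousand of a full national survey) were chosen to make binomial sampling
error small relative to the rates (exposure ≈ 17 000 woman-years per age)
while keeping the suite quick.

## Numerical choices and degenerate inputs

* Residuals are clipped to ±10⁶ (with NaN→10⁶) so that wild interior
  parameter values cannot derail the solver; bounds keep the optimum away
  from the clip region.
* Peak search: grid step 10⁻³ year, golden-section refinement to 10⁻⁸;
  exact ties go to the youngest age.
* All-zero schedules: initialisation raises (no peak to anchor);
  `summarize` returns peak_age 15 by the smallest-age tie rule.
* Constant schedules: R² is undefined and raises.
* `aic_aicc` requires n > k + 1; SSE = 0 returns −∞ with a warning.
* Determinism: every stochastic component takes a seed; refits with the
  same seed return identical results, and CLI reruns produce byte-
  identical JSON.

## Known limitations

* The published NFHS-4 goodness-of-fit tables bundled in
  `fertcurves.nfhs4` contain five AICc entries inconsistent with their own
  printed SSE beyond rounding; they are flagged `reliable=False` and
  excluded from fidelity checks (see the module's comments).
* Exact reproduction of the published NFHS-4 SSE/AICc values requires the
  survey microdata, which are not distributable; the bundled estimates
  are reference inputs, and our fits to any schedule are guaranteed only
  to be local optima at least as good as every tried start.
* Mixture models (e.g. two-component Hadwiger or P-K curves for
  populations with a secondary early-age bulge), spline and polynomial
  smoothers, cohort fertility, and order-specific rates are out of scope.
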