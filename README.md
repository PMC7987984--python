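# fertcurves

Parametric modelling of single-year age-specific fertility rates (ASFR).

Fertility schedules — the ASFR f(x) plotted against single years of age x =
15…49 — are unimodal and, in populations like India's, strongly
right-skewed: rates rise steeply to a peak around ages 19–24 and decline
slowly toward 49. Classical parametric curves developed on low-skew,
late-peaking European schedules often fit such data poorly. This package
implements nine curve families and the machinery to fit, compare and reuse
them on any single-year schedule:

| family | parameters | k |
|---|---|---|
| Hadwiger | a, b, c | 3 |
| P-K (two-sided Gaussian) | b, μ, σ₁, σ₂ | 4 |
| modified P-K | + late-age floor a | 5 |
| Gompertz | α, β, m | 3 |
| modified Gompertz | + scale exponent γ | 4 |
| skew normal | λ, σ, δ | 3 |
| modified skew normal | θ, λ, s₁, s₂, δ | 5 |
| G-P (beta kernel) | p, q, r | 3 |
| modified G-P | + late-age floor s | 4 |

For example, the modified P-K curve is

    f(x) = a + b·exp{−((x−μ)/σ₁)²}   for x ≤ μ,
    f(x) = a + b·exp{−((x−μ)/σ₂)²}   for x > μ,

with peak rate b at age μ, separate pre-/post-peak spreads, and a constant
a capturing late-age (45–49) fertility; and the modified Gompertz curve is

    f(x) = (α/β)^γ · exp[−z − α·e^(−z)],   z = (x−m)/β,

which peaks at x* = m + β·ln α. Parameters are estimated by nonlinear least
squares — minimising SSE = Σₓ (f(x) − f̂(x))² with a bounded multi-start
trust-region solver — and families are compared by the small-sample
corrected Akaike information criterion

    AIC  = 2k + n·ln(SSE/(n−k)),    AICc = AIC + 2k(k+1)/(n−k−1),

with n = 35 ages (smaller is better; near-ties go to the family with fewer
parameters). The package also computes single-year ASFR from DHS-style
retrospective birth histories (century-month codes, events/exposure over a
36-month window), loess-smooths noisy schedules (tricube local quadratic,
20% span), and simulates schedules and birth-history microdata from any
family for validation.

## Worked example

Fit a modified Gompertz curve to a schedule sampled with binomial noise
(20 000 women observed per age) around an India-like curve:

```python
import fertcurves as fc
from fertcurves import nfhs4

truth = nfhs4.MODIFIED_GOMPERTZ_ESTIMATES["India"]
cfg = fc.SimulationConfig(family="modified_gompertz", params=truth,
                          noise=fc.BinomialNoise(women_per_age=20_000),
                          seed=1)
schedule = fc.generate_schedule(cfg)

model = fc.FertilityCurveModel(schedule, "modified_gompertz")
res = model.fit()
print(res.summary())
```

```
Fertility curve fit: modified_gompertz
============================================
No. observations (ages):     35
No. parameters (k):           4
SSE:          9.29878e-05
AIC:            -437.0960
AICc:           -435.7627
R-squared:       0.999395
Converged:   True  (best of 21 starts, start #5)
--------------------------------------------
   alpha       4.39097
    beta       4.10624
   gamma       12.6015
       m       16.3904
--------------------------------------------
Peak rate 0.1950 at age 22.47; implied TFR 2.172
```

The fitted curve's peak (0.195 births/woman/year at age 22.5) and implied
total fertility rate (2.17 births per woman, the curve summed over integer
ages 15–49) recover the generating curve's values; the SSE of 9.3e-5 over
35 ages reflects the binomial sampling noise. Ranking several families on
the same schedule:

```python
fits = [fc.fit_model(schedule, name, n_starts=8)
        for name in ("hadwiger", "gompertz", "modified_gompertz",
                     "pk", "modified_pk")]
comp = fc.compare_models(fits, "synthetic India-like")
print(comp.to_frame().to_string(index=False))
```

```
           family  k      sse         aic        aicc  r_squared  best
modified_gompertz  4 0.000093 -437.096038 -435.762704   0.999395  True
      modified_pk  5 0.000450 -378.736286 -376.667321   0.997069 False
               pk  4 0.000625 -370.411155 -369.077822   0.995932 False
         hadwiger  3 0.001421 -344.785686 -344.011493   0.990754 False
         gompertz  3 0.066426 -210.209051 -209.434858   0.567647 False
best: modified_gompertz
```

The generating family wins by a wide AICc margin; the plain Gompertz curve,
whose kurtosis is fixed, cannot match the sharp peak (R² = 0.57).

The same workflow is available from the shell:

```
fertcurves simulate-schedule --model modified_gompertz --params params.json \
    --noise binomial --women-per-age 20000 --seed 1 --out schedule.csv
fertcurves fit --input schedule.csv --model modified_gompertz --out fit.json
fertcurves compare --input schedule.csv --models all --out comparison.json
```

plus `asfr` (birth histories → schedule), `smooth`, `simulate`, `interpret`
(parameter-vs-summary correlations across regions) and `reproduce`.

## Reference estimates

`fertcurves.nfhs4` bundles published fitted parameter estimates,
goodness-of-fit tables and observed summaries (TFR, peak rate/age) for
single-year NFHS-4 (India DHS 2015–16) schedules of India and six states.
These support worked examples and regression checks; the survey microdata
themselves are not distributed and must be obtained from the DHS program.

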