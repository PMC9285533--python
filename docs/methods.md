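# Methods

## Model and assumptions

`phenocount` models per-visit counts of a univoltine species as
negative-binomial draws around a separable mean: a site-level peak
abundance `n*_i`, a yearly abundance multiplier `exp(U_y)`, and a Gaussian
phenology weight in (0, 1] centred on an elevation- and year-dependent
peak day. The model assumes:

- **One flight peak per season.** Multivoltine (multi-peak) phenologies
  are out of scope; fitting them will average over the peaks.
- **A Gaussian flight curve.** Peak day and duration are the only shape
  parameters; skewed emergence is absorbed into them.
- **Separable site and year effects.** A year is good or bad (or early or
  late) by the same multiplicative factor at every site; there are no
  site-by-year interaction terms, and no spatial autocorrelation between
  sites.
- **Counts proportional to abundance.** No detectability or effort
  correction is applied; all visits are assumed equally effective.
- **NB observation error** with variance `(1 + φ)·n̄`, Poisson in the
  φ → 0 limit.

Elevation enters through `z_i`, the site elevation centred on the mean of
the site design and divided by the population SD of site elevations.
Centring at the mean is forced by the definition of `d*` (peak day *at the
mean elevation*); dividing by the SD makes `h₁`, `h₂`, `g` dimensionless
and comparable across survey designs. The fitted scaler is stored on every
`FitResult` and written into the parameter CSV header, because the
coefficients are meaningless without it.

The yearly groups `Q_y`, `R_y`, `U_y` are constrained to sum to zero
exactly, by optimizing Y−1 free values and setting the last year to minus
their sum. They are therefore deviations from the multi-year mean, and a
group contributes Y−1 free parameters to the AIC penalty.

## Parameters, units, defaults

| parameter | meaning | units | notes |
|---|---|---|---|
| `n*_i` | expected peak count at site i | individuals | log-transformed in the optimizer, > 0 |
| `d*` | peak day at mean elevation | day-of-year | 1-based, Jan 1 = 1 |
| `s_d` | flight-period SD | days | window holding ~95% of activity = 4·s_d |
| `φ` | overdispersion | — | variance = (1+φ)·mean; Poisson pmf used below 1e-8 |
| `h₁`, `h₂` | elevation trend of peak day | — | quadratic form always nests the linear term |
| `g` | elevation trend of duration | — | constrained so 1 + g·z > 0 over observed z |
| `Q_y` | yearly peak shift | days | sums to 0 |
| `R_y` | yearly duration change | log scale | sums to 0 |
| `U_y` | yearly abundance change | log scale | sums to 0; ρ_y = exp(U_y − U_{y−1}) |

Selection thresholds: retention window ΔAIC ≤ 6 with the
simpler-model rule (no model with strictly fewer parameters and lower
AIC); inference on the simplest retained model, ties broken by lower AIC.
"Simpler" is operationalized as strictly fewer free parameters — a
parameter-count approximation to nested-pair bookkeeping. Driver GLMs warn
at VIF > 3 (a conservative collinearity screen) and never drop predictors
automatically; at most 3 predictors per GLM.

## Fitting

Each candidate is maximized with L-BFGS-B on a transformed scale: logs for
`n*_i`, `s_d`, `φ`; identity for `d*`, `h₁`, `h₂`, `g`; free Y−1
parameterization for yearly groups. Day-valued coordinates (`d*`, `Q_y`)
are additionally divided by 25 inside the packed vector so all coordinates
have comparable curvature; without this the optimizer needs several times
more iterations. The gradient is computed analytically (digamma terms for
the NB part, chain rule through the mean surface), which is what makes
fitting 48 candidates per species cheap enough for simulation studies.

Initialization uses count-weighted moments: `d*` and `s_d` from the
weighted mean/SD of observation days, `n*_i` from per-site maximum counts,
φ = 1, everything else 0. Five restarts by default (the first from the
moment start, the rest jittered with the seeded RNG); the best is kept and
the optimizer's success flag is reported as `converged`. Non-convergent
fits are excluded from selection with a logged warning. Candidates the
design cannot identify (e.g. quadratic elevation with fewer than three
distinct elevations) are skipped, not fitted.

Numerical guards: expected counts are floored at 1e-10 before the NB pmf
so far-from-season zero counts contribute ≈ 0 rather than NaN (floored
records also contribute zero gradient, consistently with the flat floored
objective); parameter regions where the effective duration SD would be
nonpositive (1 + g·z ≤ 0) return a large finite penalty rather than being
clipped.

## Derived metrics

- **ρ_y** requires consecutive years (a gap would make the ratio span
  more than one generation) and is undefined for the first year; over a
  series it telescopes to exp(U_last − U_first).
- **Concordance** needs a sign convention the raw statistic does not fix:
  we use sign(Q_y) for phenology and sign(ln ρ_y) (growth vs decline) for
  abundance. Exact zeros match neither direction; a year with a zero
  community mean is dropped with a warning. Both the mean-over-years and
  the pooled species-year aggregation are reported, since they differ
  under unbalanced coverage.
- **Spearman p-values** use the exact permutation null for n ≤ 9 pairs
  (9! arrangements are enumerable; ties handled by permuting the observed
  average ranks) and the asymptotic approximation beyond. Note a
  structural ceiling worth knowing when interpreting these correlations:
  because ρ_y differences the U series, a coupling U_y = −c·Q_y with
  iid Q implies Corr(Q_y, ln ρ_y) → 1/√2 ≈ 0.71 even without noise, so
  observed |rank correlations| near 0.7–0.8 are about as strong as the
  construction permits.
- **Community slope** regresses the cross-species mean Q_y on raw mean
  March–June temperature (°C, deliberately not z-scored) so the slope is
  in days/°C; per-species driver GLMs use z-scored predictors so
  coefficients are comparable effect sizes.
- Under the **inverse link** (1/μ = Xβ) the sign of a coefficient is
  reversed relative to the direction of its effect on the mean; reported
  coefficients are on the link scale.

A caution on the driver stage: with ~10 usable years and 11–12 candidate
predictors, best-subset AIC selection over all ≤3-predictor subsets picks
a spurious non-null model on most pure-noise responses (we measure ≈ 68%
of replicates; restricted to single predictors the null survives ≈ 84%).
This is an inherent small-sample property of the procedure, not a defect
of the implementation; selected drivers at this sample size should be read
as hypotheses, not confirmations.

## Synthetic data

The generator draws surveys directly from the model: evenly spaced site
elevations over a configurable range (default 20 sites, 930–2,050 m), a
biweekly visit grid inside a season window (default days 120–300) with a
random per-site-year phase and a 5% chance of a missed visit (so the
realised design is unbalanced), and NB counts whose means come from the
*same* expected-count implementation the likelihood uses — simulation and
inference cannot drift apart. Default true parameters resemble published
estimates for an abundant montane univoltine butterfly (`d*` = 201.5,
`s_d` = 11.9 d, φ = 1, linear elevation trend h₁ = 0.035), with yearly
peak shifts of SD 5 days and abundance effects of SD 0.5 (log scale), and
site peaks lognormal around 15 individuals — a 20-site, 10-year design
then yields several thousand recorded individuals. The climate generator
produces monthly two-station series (a cool high-elevation primary
station and a warmer secondary one), shares a year-level spring anomaly
across months so springs genuinely differ between years, and can inject a
phenology–temperature coupling (default 4.4 days earlier per °C) into the
count generator's Q_y, so the full pipeline can be validated end to end.

What the simulator does **not** emulate: weather-dependent detectability,
observer effects, site covariates other than elevation, skewed or
multi-peak emergence, and spatial correlation. Passing recovery tests on
synthetic data therefore shows the estimator is consistent under the
model's own assumptions, not that those assumptions hold for any real
survey.

## Problem sizes used in the test suite

Oracle-equivalence checks run on tiny random datasets. Parameter-recovery
tests use the full 20-site × 10-year biweekly design (10 replicates).
Selection-behaviour simulations (strong support when yearly abundance
effects are present; null model chosen when simulated from the null) run
at a scaled-down 6-site × 5-year design with 50 replicates per scenario,
which preserves the qualitative behaviour while keeping the 48-candidate
refits cheap. Driver-stage coverage uses 100 replicates of the climate
generator alone.

## Known limitations

- AIC (not AICc) is used throughout, matching the selection rule the
  package implements; at n ≈ 10 responses the driver stage consequently
  overfits noise (see above).
- The likelihood treats visits as independent given the mean; within-year
  autocorrelation of counts is not modelled.
- `converged` reflects the optimizer's success flag; a flagged fit may
  still be a local optimum in principle, which is why restarts are seeded
  and the multi-start stability is tested.
- The elevation plateau (vertex of the quadratic peak-day curve) is only
  meaningful when it falls inside the observed elevation range; the
  package reports it wherever h₂ < 0 and leaves the range check to the
  user.
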