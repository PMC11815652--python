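# Methods

This note records the statistical procedures hemoval implements, the
conventions that were genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Episode detection and alert matching

Samples arrive nominally every `dt` = 20 s. All durations use a
sample-and-hold convention: a sample stamped `t` represents
`[t, t + dt)`, so a run of k qualifying samples lasts k·dt and an
episode's `end` is the time of the first non-qualifying sample (or
last sample + dt at a gap or series end). Consequences: the "at least
1 minute" hypotension rule means ≥ 3 consecutive samples at 20-s
sampling, and the two conventions ("≥ 1 min" and "≥ 2 records")
are consistent at the stated rate.

- Hypotension qualifies at MAP **strictly below** 65 mmHg (a sample at
  exactly 65 ends an episode); alerts qualify at HPI **≥** 85.
- Missing HPI is treated as below the alert threshold (device
  dropout); missing MAP terminates runs of either kind, and an
  inter-sample interval > 2·dt is treated as a recording gap that also
  breaks runs — episodes never span the transfer from operating room
  to intensive care.
- The 15-min prediction window is anchored at alert (segment) onset
  and is the half-open interval `(start, start + 900 s]`: an onset
  simultaneous with the alert start is not claimable (an alert that
  begins during ongoing hypotension is not credited with predicting
  it; the report flags when this occurs), while an onset exactly at
  +15 min is.
- Splitting proceeds left-to-right inside each raw alert: cut at
  `start + 900 s` when no hypotension onset falls in the window,
  otherwise at the end of the first such episode; a remainder
  containing at least one sample starts the next segment.
- Classification walks segments in time order. A true alert claims
  *every* not-yet-claimed onset in its window (one alert can predict
  several episodes); a segment whose window holds only claimed onsets
  is *ignored*; ignored and false segments both stay in the PPV
  denominator — PPV = true segments / all segments — with per-class
  counts logged so the alternative denominator is auditable.
- Sensitivity and PPV get Wald intervals p ± 1.96·√(p(1−p)/n) clipped
  to [0, 1]; with a zero denominator the estimate is reported absent
  with an explanatory flag. Quartiles of the alert-to-hypotension lead
  time use linear interpolation.

A deliberately naive brute-force matcher (plain sample-by-sample
scanning, no run-length logic) re-derives the whole chain and is held
to exact agreement with the production path on hundreds of randomized
series containing dropouts and gaps.

## Method-comparison statistics

Differences are defined as reference − device throughout.

**Lin's CCC** is computed pooled over all pairs with biased (1/n)
moments, ρ_c = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²). Clustering by patient
enters only through the bootstrap: patients are resampled with
replacement (as many draws as patients; a patient drawn k times
contributes its pairs k times), the CCC recomputed per resample, and
the 2.5th/97.5th percentiles of 1,000 resamples taken as the 95% CI.
A replicate-weighted CCC variant is intentionally out of scope.

**Repeated-measures Bland-Altman.** The bias is the unweighted mean of
per-patient mean differences. The SD combines variance components
from a one-way ANOVA of the differences with unequal replicate
counts n_i: within = MSW; between = (MSB − MSW)/n₀ with
n₀ = (N − Σn_i²/N)/(k − 1), truncated at zero; SD = √(between +
within). Patients with a single replicate contribute to the bias and
the between-group sum of squares only; if every patient is a
singleton the SD falls back to the SD of the patient means with a
warning. A `sd_method="simple"` option (SD of the pooled raw
differences) is provided for sensitivity analysis, since pooled and
component-based SDs differ slightly in unbalanced data.

**MOVER intervals for the limits.** For the upper limit
U = bias + 1.96·SD, the CI combines a t interval for the mean (k − 1
df, SE² = σ̂²_b/k + σ̂²_w·Σ(1/n_i)/k²) with a χ² interval for
1.96·SD whose degrees of freedom come from a Satterthwaite
approximation to σ̂² = MSB/n₀ + (1 − 1/n₀)·MSW:

    lower CI of U = U − √((bias − l_m)² + (1.96·SD − l_s)²)
    upper CI of U = U + √((u_m − bias)² + (u_s − 1.96·SD)²)

and symmetrically (with the SD term on the opposite side) for the
lower limit. With SD = 0 all intervals collapse to the point.

**Proportion within tolerance.** The indicator
1{|(ref − dev)/ref|·100 < 20} is fitted with an intercept-only GEE,
exchangeable working correlation over patients, robust sandwich SE;
CI = estimate ± 1.96·SE clipped to [0, 1]. For an intercept-only
model the variance function is constant across observations, so the
binomial-identity and Gaussian estimating equations coincide and the
identity link is fitted as Gaussian; a logit link (fitted binomial,
CI back-transformed) is available by flag. A single-patient input
falls back to a binomial Wald CI with a warning.

**Agreement verdict.** Two criteria are reported separately and both
must hold for `agrees`: the LOA point estimates inside ±CAD, and the
outer CI bounds inside ±CAD (CAD ±1 L·min⁻¹ for CO, ±200
dynes·s·cm⁻⁵ for SVR). Report rounding follows the field's
presentation: two decimals for CO and dimensionless ratios, integers
for SVR.

## Burden metrics

For each threshold τ ∈ {65, 60, 55} mmHg, computed independently
(computing the 60/55 areas only inside 65-crossing windows would make
them depend on a different threshold's crossings; the independent
reading matches standard time-weighted-average definitions):

- AUC: trapezoidal integral of max(0, τ − MAP) with crossing points
  interpolated linearly between samples, plus a dt-long hold of the
  last sample of each gap-free block (this makes a constant
  sub-threshold stretch of k samples integrate as a k·dt rectangle,
  consistent with the episode-duration convention);
- minutes below: sample-and-hold count of strictly sub-τ samples;
- TWA = AUC / total monitored time, where monitored time is the sum
  of gap-free block spans (+ dt hold each) over the whole series file
  — gaps are excluded from numerator and denominator alike.

An adaptive-quadrature oracle with numerically root-found crossings
reproduces the AUC to 1e-9 on randomized piecewise-linear signals.

## Power to conclude agreement

Differences are simulated as n independent Normal(μ, σ) draws — the
question is posed for a number of pairs, a mean, and an SD only, so no
clustering is modelled. Per replicate the 95% LOA mean ± 1.96·s are
formed and agreement is concluded when both limits' outer confidence
bounds fall inside ±CAD. The default interval for a limit is the
classical Bland-Altman approximation, SE = s·√(1/n + 1.96²/(2(n−1)))
with a two-sided normal quantile — the construction used by standard
sample-size tools for agreement studies; under it the two shipped
scenarios (n=125, σ=0.4, CAD 1; n=122, σ=81, CAD 200) have true power
≈ 0.870 and ≈ 0.816. Exact-t/χ² MOVER intervals are available
(`ci_method="mover"`; being wider, they give ≈ 0.825/0.760 on the
same scenarios), as is a point-estimate-only criterion
(`criterion="point"`, ≈ 1.00). Power is reported with its Monte-Carlo
SE √(p(1−p)/n_sims).

## Synthetic cohort generator

The generator produces data with the *statistical structure* the
analyses assume, not physiology:

- **MAP**: stationary AR(1) (discrete Ornstein-Uhlenbeck) sampled at
  dt, baseline 78 ± 7 mmHg, lag-1 autocorrelation 0.97 (≈ 11-min
  decorrelation time), floored at 20 mmHg. Hypotensive excursions are
  half-sine dips at Poisson onsets (0.9/h), depth 18 ± 6 mmHg,
  duration 300 ± 120 s (normals truncated at 0). Defaults describe a
  23-patient cohort monitored ~30 h each (surgery plus first
  post-operative day); with them the cohort yields roughly 600–750
  hypotension episodes and ~110 median minutes below 65 mmHg.
- **HPI** is constructed from the *future* of the MAP path: with
  d(t) = 65 − min MAP over (t, t + lead], the noiseless index is
  88 + 9·tanh(d/20) when d > 0 and 75/(1 + e^(−d/6)) otherwise, so it
  sits at/above the alert threshold exactly while a crossing lies
  ahead within the lead (default 300 s) and well below it otherwise.
  Gaussian observation noise (SD 5) and spurious 2–6-sample alert
  bursts (1.8/h) are then added and the result clipped to [0, 100].
  This makes prediction performance a *dial*: with zero noise and
  zero false-alert rate, sensitivity is exactly 1 by construction.
  The real device's waveform-feature analysis is explicitly not
  modelled — passing tests validate the evaluation machinery, not the
  device.
- **Pairs**: patient truth u ~ N(true_mean, between_sd), reference =
  u + noise, device = scale·u + bias + noise, replicate count uniform
  on [2, 11]. The `co_like` preset (mean 10.4, between-SD 2.8, scale
  0.5, bias 2.9, noise SDs 1.3/1.82) and `svr_like` preset (mean 531,
  between-SD 212, scale 0.8, bias 232.2, noise SDs 84/197) were
  solved analytically so the pooled device/reference means, SDs, and
  the population CCC land near the observed summaries, with the
  device reading low for CO and high for SVR. Non-positive values are
  redrawn; for these presets the truncation is negligible (< 0.1% of
  a between-SD for CO). Every analytic moment (bias, variance
  components, CCC) is exposed on the preset for parameter-recovery
  tests.
- **Determinism**: every draw comes from a generator keyed on (seed,
  CRC32(patient id), stream), so any patient's data is reproducible
  in isolation and cohort CSV output is byte-identical under a fixed
  seed. CO/SVR pairs are generated independently of the MAP series;
  no joint hemodynamic model links them.

What the synthetic tests show: the episode matcher, the agreement
statistics (including CI coverage against analytic generator truth),
and the power simulation are internally correct at realistic scales.
What they do not show: anything about a real device's accuracy, real
artifact patterns (catheter flushes, damping), or treatment feedback
— clinician interventions triggered by alerts are not modelled, which
in real data inflates false-alert counts.

## Problem sizes used in the shipped checks

Parameter-recovery checks use a 200-patient pairs cohort; CCC-coverage
uses 200 replications of 100-patient cohorts with 500-resample
bootstraps; matcher-oracle equivalence uses 500 randomized 200-sample
series; power checks use 10,000 Monte-Carlo replicates, with the CO
scenario's bound tested within the estimate's 3-SE Monte-Carlo band
(its true power sits ~0.0004 above the 0.87 bound, closer than one SE
at 10,000 replicates).

## Known limitations

- The GEE proportion assumes the exchangeable working correlation is
  adequate; with very few clusters the sandwich SE is anti-conservative
  (no small-sample correction is applied).
- The percentile bootstrap for the CCC under-covers slightly for very
  small patient counts (~23); coverage is validated at 100 patients.
- The MOVER construction assumes normally distributed differences;
  heavy tails widen the true limits faster than the intervals.
- Alert evaluation is retrospective and sample-synchronous; no
  real-time/streaming semantics.
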