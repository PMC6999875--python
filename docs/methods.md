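# Methods

This note documents the generative model, the analysis procedures, the
numerical choices, and what the synthetic data can and cannot establish.

## Task geometry and timing

The hand starts at the origin and must cross the target line `y = 20 cm`.
The target travels along that line at one of {17.5, 22.5, 27.5} cm/s, left
to right or right to left, drawn uniformly per trial.  Sampling is 125 Hz.
In the adaptation phase the cursor lags the hand by 100 ms; the baseline
phase has no added delay.  Trials run 80 + 80 per subject.

Target motion is timed so that a noise-free agent moving at its habitual
baseline speed crosses the line exactly when the target passes `x = 0`
(temporal hand error zero by construction).  This calibration pins down the
one quantity the task itself does not determine — the target's start offset —
and makes the unperturbed agent a well-defined zero point: in the adaptation
phase such an agent still has hand-TE 0 while its cursor is exactly 100 ms
late.

## Agent model

Each reach is a straight minimum-jerk trajectory (position fraction
`10τ³ − 15τ⁴ + 6τ⁵`) from the origin to an aim point 4 cm beyond the target
line, the standard smooth unimodal profile for point-to-point reaches.  The
realized mean speed is `planned + execution noise`; the planned speed is
`baseline + accumulated corrections + planning noise`.  Movement onset is
0.3 s after trial start plus timing noise; the aim direction deviates from
straight ahead by Gaussian angular noise.

The agent senses the **cursor**-vs-target temporal error at the crossing
(plus observation noise) — not the hand error — because the participant it
stands in for cannot see the hand and is unaware of the delay.  After each
trial the correction `−gain × sensed error` enters a pending pool; a
fraction `retention` of the pool is applied to the planned speed on the next
trial and the remainder drains geometrically over later trials.  A late
cursor therefore speeds the next trial up.  With `retention = 1` the update
is the classic one-step error-correction map; with `retention < 1`
corrections are spread over several trials, which produces the negative
cross-correlations at lags 2–3 that distinguish partial correctors.

Defaults (chosen once as field-realistic magnitudes; the study being
emulated reports no per-subject baseline distributions to match):

| parameter | default | unit | role |
|---|---|---|---|
| baseline speed | 35 (±1.5 across subjects) | cm/s | habitual mean speed |
| gain | spread over [0, 60] per cohort | (cm/s)/s | error-correction strength |
| retention | 0.6 | – | fraction of correction applied next trial |
| planning noise | 0.5 | cm/s | trial-to-trial planned-speed noise |
| execution noise | 1.0 | cm/s | within-trial realized-speed noise |
| observation noise | 10 | ms | sensed-error noise |
| onset noise | 20 | ms | movement-start timing noise |
| aim noise | 2 | deg | lateral heading noise |

With these values baseline TE variability is ~25–30 ms and baseline σ²(Mv)
grows roughly threefold from gain 0 to gain 60, because speed corrections
driven by noisy errors inject variance into the planned speed.  That
monotone link is the generative premise connecting error correction to
baseline variability, and it is what the replicate acceptance study checks.

## Kinematic preprocessing

Positions are linearly interpolated to a uniform 0.008 s grid and filtered
with a 6 Hz second-order Butterworth applied forward and backward (zero
phase; effective fourth order).  The filter order is configurable because
conventions differ across labs.  Edges are handled by odd-reflection padding
of one full settling length (8 × fs / cutoff samples), which makes the
forward/backward asymmetry negligible (< 1e-9).  Velocities and
accelerations are backward differences over the past two grid points
(Δt = 0.016 s) — deliberately not centered differences, to match the
convention of tablet-based interception work — with the first two samples
copied from the first computable value.

Movement onset uses a threshold of `min + 10% × (max − min)` on tangential
speed: the suprathreshold run containing the global speed peak is walked
back to the last subthreshold sample and onset is the next (grid-aligned)
sample.  This disambiguates multi-bump speed profiles in favor of the run
containing the main movement.  Line crossing is linearly interpolated
between the bracketing samples.

## Per-trial metrics and exclusions

TE uses the **hand** crossing in both phases (the cursor alternative would
shift adaptation-phase TE by exactly the delay).  Mv is the mean tangential
speed from onset to crossing; Ma is the absolute heading angle from the
y-axis over the 200 ms after onset, computed from position displacement
(the plainer reading of "between onset and onset + 200 ms"); T is the
onset-to-crossing time.  Trials whose tangential speed at the crossing is
below 20 cm/s are invalid; subjects with more than 25% invalid trials are
dropped entirely.  "Speed at the crossing" is interpolated at the crossing
instant; the instant is configurable since the original rule does not pin
it.  Invalid trials keep their index (gaps, not re-indexing), and lagged
analyses skip pairs spanning a gap.

Baseline correction subtracts each subject's mean TE over the last 30 valid
baseline trials; baseline variances σ²(Mv), σ²(Ma) use the unbiased (n−1)
estimator over valid baseline trials.

## Adaptation quantification

The two-state fit minimizes SSE of `min(a·trial, b)` (a, b ≥ 0, intercept 0)
on baseline-corrected TE in ms, with adaptation trials re-indexed from 1.
Parametrizing by the breakpoint `c = b/a` makes the conditional problem
linear, so the fit scans a dense breakpoint grid (plus every observed trial
index) with closed-form conditional least squares, then refines the best
cell by bounded 1-D minimization.  The hinge nests the pure line (`c ≥ n`)
and the immediate asymptote (`c → 0`), so its SSE never exceeds either
limit's.  All-constant series are flagged degenerate.

The exponential cross-check fits `b_e·(1 − exp(−trial/τ))` by multi-start
least squares (τ starts 1–40).  τ is parametrized as a time constant
(larger = slower), which is why it correlates negatively with the Adaptation
Score.  Fits are flagged unconverged when the optimizer fails or τ exceeds
10× the series length — the curve is then indistinguishable from a line over
the observed window, the signature of non-exponential adapters.

"Normalization" of a and b across subjects is z-standardization (mean 0,
SD 1 with the n−1 estimator); the score is `z_a + z_b`.  Min–max scaling is
available as a configurable alternative reading but z-scores are the
documented default.

## Sequential analyses

*Group split*: HIGH iff σ²(Mv) exceeds the cohort mean (a mean split, not a
median split — the groups need not be balanced).

*Variance tests*: ratio of sample variances with an F reference and
two-sided p, on baseline Mv and TE pooled within group.

*Sequential effect*: the mixed-model estimand — the group-level slope of
ΔMv(t+1) on TE(t) — is estimated by a fully specifiable two-stage procedure:
per-subject OLS slopes over consecutive valid baseline pairs, aggregated by
precision weighting; the group contrast is a weighted two-sample z.  One
caveat this simulator makes explicit: because TE depends on realized speed
within a trial, regressing the *change* in speed on the previous error has a
mean-reversion component, so even zero-gain agents show a negative slope.
The group *ordering* (HIGH more negative than LOW) is the robust corrective
signature and is what the acceptance study asserts; the operation-level test
of "no correction ⇒ slope 0" uses planted series in which TE is independent
of speed noise.

*Prewhitening*: one AR model is fitted to TE (order by AIC, max 10) and both
series are filtered with the same coefficients, dropping the first `order`
samples — the standard contract that leaves lagged cross-correlations
interpretable.  Near-unit-root fits (AR root modulus < 1.05) fall back to
first differencing and are flagged.  Gapped series are processed per
contiguous run with coefficients fitted on the longest run.

*Lagged ccf*: Pearson correlation of TE(t) with Mv(t+k), k = 0…3, with 95%
percentile bootstrap CIs from resampling whitened pairs i.i.d. (valid
because prewhitening removed the serial structure; whether to resample raw
or whitened observations is a genuinely open choice — whitened pairs were
chosen because the i.i.d. assumption is then defensible).  Profiles are
correlated with the Adaptation Score across subjects (Pearson and Spearman).

*LASSO*: coordinate-descent L1 regression in the glmnet/scikit-learn
convention `(1/2n)‖y − Xβ‖² + λ‖β‖₁`, predictors standardized to unit SD,
response centered, coefficients reported on the original scale; λ = 0 is the
OLS limit.  Bootstrap CIs refit at the same λ on resampled rows and must be
read as variability of a penalized estimate, not significance.  Canned
recipes: trial-level TE models per phase (Ma, Mv, tv, HIGH indicator, T and
all pairwise interactions; λ = 0.6; TE in ms, pooled across subjects with no
random effect) and the score model (σ²(Mv), σ²(Ma), their product;
λ = 0.37).  The penalties are conventional values for these model families
and are exposed in the configuration.

## Problem sizes

The replicate acceptance study uses 50 cohorts of 17 agents × 160 trials;
the exponential-recovery study uses 100 replicates of 80-trial series with
20 ms noise; bootstrap counts default to 1000 for ccf CIs and 200 for LASSO
CIs in the full pipeline.  These sizes give stable Monte-Carlo estimates
(binomial SE ≤ 7 points on replicate fractions) while keeping a full run in
minutes on one core.

## What the simulator does and does not establish

The generator reproduces the *structure* the analysis assumes: straight
smooth reaches, error-proportional speed corrections with partial retention,
independent subjects, and the delay manipulation.  Passing tests show the
pipeline recovers planted parameters and that the qualitative findings
(variability–adaptation correlation, corrective sequential effects, negative
lagged ccfs for correctors, selection of σ²(Mv) over σ²(Ma)) follow from
the error-correction premise.  They do not validate the premise against
human data: the simulator omits online corrections within a trial, movement
angle and interception-point strategies, target-speed generalization,
fatigue and drift, and any learned changes in noise itself.  Absolute
magnitudes (e.g. group slopes in cm/s per s) depend on the chosen noise
scales and should not be compared numerically to human estimates.

## Known limitations

* The onset-detection contract fixes one concrete reading of the
  threshold-with-backward-walk family of algorithms; other readings differ
  by a sample or two near threshold.
* The exclusion rule evaluates speed exactly at the crossing; rules based on
  a window around the crossing would classify a handful of borderline trials
  differently.
* Bootstrap CIs (ccf and LASSO) are percentile intervals; no bias
  correction.
* The two-stage sequential-effect estimator matches the mixed model in
  expectation but not in finite-sample efficiency.
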