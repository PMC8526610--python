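# Methods

## The disturbance design

The unit of observation is the inter-train gap: the train-free span
between the end of one train pass and the start of the next, at a site
recorded for 3.5 h from 30 min before sunset. A gap of duration at
least `3d` contributes three disjoint intervals of length `d`:

- **after** — the first `d` seconds of the gap (immediately following a
  train),
- **before** — the last `d` seconds (immediately preceding the next
  train),
- **between** — `d` seconds centred on the gap midpoint.

The between interval is placed at the midpoint because that maximises
its distance from both trains, making it the cleanest available
baseline; no other placement is canonical. Gaps bordering the recording
boundary lack one anchoring train and are excluded, as are gaps
adjacent to overlapping opposite-track passes (a different stimulus,
too rare to model). Interval durations of 30/60/120/240/480 s
correspond to qualifying-gap thresholds of 90/180/360/720/1440 s.

A *bat pass* is a call or call series separated from others by strictly
more than 1.0 s (a gap of exactly 1 s does not split). Passes are
assigned to intervals by start time on half-open `[start, end)`
windows, so every pass lands in at most one interval. Species streams
are segmented independently and pooled by default in the activity
response.

## Count model

Per-interval counts are NB2 (`Var = mu + mu^2/theta`, log link) with an
optional site random intercept fitted by a Laplace approximation to the
marginal likelihood: per-site conditional modes by damped Newton, outer
maximisation over `(beta, log theta, log sigma)` by BFGS with a simplex
rescue pass. The implementation reproduces glmmTMB's nbinom2 fit to
~1e-4 on all parameters and standard errors (see
`tests/test_glmm_oracle.py`). When the fitted random-intercept variance
falls below 1e-4 the random effect is removed for parsimony and the
model refitted as fixed-effects-only; a boundary-corrected LRT
(p = 0.5 chi2_1 tail) tests the variance component.

Model selection: candidate confounders (nightly pass total, time since
start, wind, humidity, temperature) are screened univariately at
p <= 0.1 (inclusive, with the same random structure); all subsets of
the survivors plus interval category are ranked by
`AICc = -2 ll + 2k + 2k(k+1)/(n-k-1)`, where `k` counts fixed
coefficients plus theta plus (if present) sigma. Models within
dAICc <= 6 of the best are averaged with Akaike weights using full
(zero-substituted) averaging: a model omitting a term contributes a
zero coefficient, and the adjusted SE folds in between-model spread,
`se_j = sum_m w_m sqrt(se_jm^2 + (b_jm - bbar_j)^2)`. Ties in AICc
break lexicographically by term names. The category term competes in
subsets like any other term rather than being forced into every model.

Pairwise category contrasts (before-vs-between, after-vs-between,
after-vs-before) are the re-levelled coefficients. Because averaging is
linear in the coefficients and the AICc ranking is invariant to the
reference level, the re-levelled average equals the weighted linear
combination of member-model contrasts (with each member's coefficient
covariance supplying the SE); the implementation computes it that way
and a test verifies equality against a literal re-level-and-re-rank.
IRRs are `exp(estimate)` with Wald 95% intervals.

Diagnostics are limited to randomised quantile residuals (uniform under
a correct model); full simulation-based residual machinery and
collinearity indices are out of scope.

## Acoustics

The SPL curve is the RMS level in sliding windows of `3.2/min_pitch`
seconds stepped by a quarter window; the default minimum pitch of 5 Hz
gives a 0.64 s window and 0.16 s step — 6.25 readings per second. Raw
curves are meaningful only up to the recorder gain; calibration shifts
the whole curve so the opening 94 dB / 1 kHz reference tone reads its
nominal level (the dB equivalent of a pressure-domain multiplication
factor). A pass's maximum SPL is taken over the pass window padded by
±5 s, since rail-joint and curvature noise can peak slightly before or
after the train is level with the detector. Maxima are standardised to
1 m by spherical spreading (`-20 log10(r2/r1)`); atmospheric absorption
and ground effects are ignored at these ranges.

Frequency grouping: per-pass magnitude spectra (Hann windows of 1024
samples, 50% overlap, unit-max normalised) are averaged per site with a
bootstrap CI over passes. The site is "high" when at least two local
maxima above 5 kHz stand 6 dB above a median-filtered (~2 kHz span)
spectral envelope — an explicit, config-exposed criterion standing in
for what is in practice a visual classification. The window length and
the 6 dB prominence are heuristics; both are parameters.

## Synthetic survey generator

The generator emulates the study conditions, with defaults fixed from
the field campaign's reported ranges:

| parameter | default | meaning |
|---|---|---|
| trains_per_hour | 1.7–19.3 across sites | homogeneous Poisson arrivals |
| baseline_rate | 47 passes/hr | ≈165 passes per 3.5 h night in gaps |
| site_effect_sd | 0.2 | log-scale site random intercept |
| time_trend | 0.41 /hr | within-night log-linear activity rise |
| factor_s, duration_tau | 0.5, 120 s | post-train suppression |
| dispersion_theta | 2 | gamma-frailty NB2 shape |
| mean_car_length | 21 m | cars 1–12, speeds 40–170 km/h |
| recording_duration | 12600 s | 3.5 h survey window |

Trains are homogeneous Poisson with minimum headway equal to the pass
duration (real timetables are not modelled; within-night arrival
structure is unknown, so Poisson is an explicit assumption). Pass
duration follows from length/speed, so the physics round-trips through
the estimators. Bat passes are an inhomogeneous Poisson process
realised by thinning: rate `lambda0 exp(b_site + beta_t t)`, multiplied
by `s` for `tau` seconds after each pass end (rectangular window,
anchored at the pass end; an exponential-recovery option exists but is
off by default, as the step shape is the simplest one consistent with
interval-wise contrasts). Overdispersion is a gamma frailty
(mean 1, shape theta) drawn independently per 30 s block of the
timeline, which makes aligned interval counts NB2 and unaligned ones
approximately so. Calibration audio is synthesized at 48 kHz mono
16-bit: a pure reference tone, then one band-limited (0.2–4 kHz) noise
burst per pass with a plateau at the requested peak SPL, optionally
with 6/9/12 kHz harmonics emulating wheel squeal. The generator does
not emulate ultrasonic call structure, detector trigger physics,
species-specific frequencies, or weather-dependent activity — weather
covariates are pure noise — so passing tests demonstrate the
statistical machinery, not ecological realism of those features.

## Recovery and null simulations

The recovery surface sets `tau` equal to the analysis interval
(`tau = d = 30 s`) so the after interval is exactly the suppression
window and the true after-vs-before log-IRR equals `log s`; with the
headline `tau = 120 s`, short gaps put their before/between intervals
inside the suppression window and the estimand is attenuated below
`log s` (visible in the worked example's 240 s row). Campaigns of 12
sites x 3 nights yield ~870–910 qualifying gaps; 200 replicates bound
the mean bias of the averaged estimate at 0.03, and a single replicate
sits within ±0.10 (its Monte-Carlo SE at these activity levels is
≈0.07–0.1, so individual replicates can land outside that band — the
bias bound is the calibrated claim).

The null calibration zeroes both the suppression and the within-night
trend (with a trend the three categories are not exchangeable even
without trains, because 'before' sits later in the night than 'after'),
then checks over 1000 single-night campaigns that category means agree
within Monte-Carlo error and the after-vs-before Wald test's rejection
rate at nominal 0.05 stays within [0.03, 0.07].

## Numerical choices

- Fixed-effects NB2: L-BFGS-B then BFGS on `(beta, log theta)` with
  analytic gradients, finished by damped Newton to gradient < 1e-10;
  agreement with an independent IRLS/profile-theta oracle to 1e-6.
- `log theta` is capped at 30 (the Poisson limit); theta is weakly
  identified there and the cap only prevents overflow.
- beta and theta are information-orthogonal in NB2, so fixed-effect
  covariance is the inverse expected information at the MLE; the mixed
  model uses a central-difference Hessian of the Laplace objective,
  falling back to conditional expected information if ill-conditioned.
- Interval boundaries and the 1 s segmentation rule are strict
  comparisons; gap qualification is `duration >= 3d` inclusive.
- Zero-count degenerate tables and subset non-convergence are excluded
  from averaging with a warning rather than failing the run.

## Known limitations

- The Laplace approximation can understate variance components with
  very few groups; the study-scale campaigns use 12 sites, where it
  agrees with TMB to three decimals.
- The closed-form exposure fraction ignores window overlap; reports
  flag sites where expected headway < effect duration, and the
  union-of-windows simulation is the reference there.
- Suppression depth and duration are confounded at a single interval
  duration; the multi-duration sweep (30–480 s) is the identifying
  design, not any single fit.
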