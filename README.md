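# railbat

Event-triggered analysis of how passing trains suppress bat activity at
rail-side sites.

## The problem

Echolocating bats — in particular common and soprano pipistrelles
(*Pipistrellus pipistrellus*, *P. pygmaeus*) — forage heavily along
wooded linear features, including railway verges. Each train pass is a
brief, intense disturbance: broadband noise, light, and the rapid
movement of a large object. `railbat` quantifies the behavioural cost of
that disturbance from passive acoustic surveys: bat-pass counts in fixed
windows *before*, *after* and *between* train passes are compared with a
negative-binomial count model, and the estimated suppression is
converted into the fraction of night a bat effectively loses.

The package is organised as an analysis project: every computation lives
in the library (`src/railbat/`), and the numbered scripts under
`analysis/` drive the narrative from simulated raw logs to the final
disturbance budget. A synthetic survey generator with known ground truth
(train schedules, a thinned inhomogeneous Poisson bat stream with
post-train suppression, and calibration audio) makes the entire pipeline
testable without any field recordings.

## The model

For interval *i* in site *s*, the bat-pass count is modelled as

    y_i ~ NB2(mu_i, theta),   log mu_i = x_i' beta + b_s,
    b_s ~ N(0, sigma^2)

with variance `mu + mu^2/theta` and a log link. `x_i` holds the interval
category (before / after / between, reference = between) plus screened
confounders (nightly pass total, time since recording start, weather).
Confounders enter the full model only if univariately associated with
activity at p <= 0.1; all subsets of the surviving fixed effects are
ranked by AICc, and coefficients are averaged over the dAICc <= 6 set
with Akaike weights (full, zero-substituted averaging). The site random
intercept is dropped for parsimony when its fitted variance falls below
1e-4. Category contrasts are reported as incidence rate ratios,
`IRR = exp(beta)`.

Acoustic severity of each pass is measured as the maximum of a
calibrated SPL curve (94 dB reference tone; RMS windows of 0.64 s
stepped 0.16 s, i.e. 6.25 readings/s) and standardised to 1 m by
spherical spreading, `SPL_2 = SPL_1 - 20 log10(r_2/r_1)`. Sites are
classified "high"/"low" frequency by harmonic wheel-squeal peaks above
5 kHz in their mean train spectra.

The headline cost metric is the suppressed time fraction
`min(1, trains_per_hour x effect_duration / 3600)`.

## Worked example

```
$ python analysis/01_simulate_survey.py
wrote 48 site-nights to .../results/raw
  1762 train passes, 14892 bat passes
  site train rates: 1.7-19.3 per hour

$ python analysis/04_interval_models.py
d= 30 s: n= 3492 intervals, screened=['nightly_total', 'time_since_start_h'], after-vs-before IRR=0.55 [0.49, 0.62] p=1.9e-24
d= 60 s: n= 2601 intervals, screened=['nightly_total', 'time_since_start_h'], after-vs-before IRR=0.53 [0.48, 0.58] p=1.1e-42
d=120 s: n= 1413 intervals, screened=['nightly_total', 'time_since_start_h'], after-vs-before IRR=0.55 [0.51, 0.60] p=6.3e-41
d=240 s: n=  471 intervals, screened=['nightly_total', 'time_since_start_h'], after-vs-before IRR=0.83 [0.75, 0.92] p=0.00032
d=480 s: n=  120 intervals, screened=['time_since_start_h'], after-vs-before IRR=0.96 [0.85, 1.09] p=0.54
```

The generator halves the bat-pass rate for 120 s after every train, and
the fitted models read that back: activity in the 30–120 s windows after
a pass is roughly half the between-train baseline (IRR ≈ 0.5), the
contrast attenuates at 240 s windows (IRR 0.83, the effect covers only
half such a window), and vanishes by 480 s — while the before-vs-between
contrast stays null throughout. `analysis/05_exposure_budget.py`
converts a 120 s effect into time lost per site: 20% at the median
traffic level (6 trains/hr), 64% at the busiest site (19.3 trains/hr),
5.7% at the quietest (1.7 trains/hr).

A one-off exposure report for your own sites:

```
$ railbat report sites.csv -d 120
```

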