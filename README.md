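# tapsync

Delay-coupled oscillator modelling of turn-taking auditory–motor
synchronization.

People synchronizing taps with a metronome tend to *anticipate* it — tap a
few milliseconds before each beat — and individuals differ widely in how well
they couple to rates far from their own spontaneous tempo.  `tapsync` is a
pipeline for studying this in turn-taking tapping experiments (alternating 8
cued beats of tapping with 8 beats of waiting, solo or with a partner).  It
is aimed at researchers in sensorimotor synchronization and joint action who
want a tested, seedable implementation of:

* **simulation** of complete synthetic experiments with known ground-truth
  dynamics (spontaneous rates, coupling regimes, motor noise, ratings);
* **preprocessing** of tap/cue onset streams into signed asynchronies
  (tap − cue, negative = anticipation), spontaneous-rate estimates and
  variability indices;
* **model fitting**: a unidirectional delay-coupled phase oscillator

      dθ₁/dt = 1/ω₁,   dθ₂/dt = 1/ω₂ + K·[θ₁(t) − θ₂(t − τ)]

  (driver = cue, driven = tapper; K = κ/(20·ω₁)) and its drift-only linear
  reduction (κ = τ = 0), fit per trial to the 8-position averaged asynchrony
  series by a seeded two-stage search (differential evolution + bounded
  L-BFGS-B) of a weighted least-squares objective, with restarts, parameter
  bounds, a fixed-median-delay refit and boundary-hit detection.  The delayed
  self-feedback makes the stable solution anticipatory: with matched rates
  the asynchrony converges to exactly −τ;
* **cross-validation**: Train/Test splitting by repetition pairing
  ({1,3} vs {2,4} turn averages) plus condition-matched *surrogate* series
  from other pairs as a chance baseline, scored by Fisher-z correlations and
  RMSE;
* **classification** of trials, participants and pairs as coupled/uncoupled
  from the RMSE comparison of the two models, with condition summaries and
  social-rating medians by coupling class.

The models are exposed as scikit-learn-style estimators
(`DelayCoupledRegressor`, `LinearDriftRegressor`: `fit(X, y)` on serial
positions/asynchronies, fitted attributes `kappa_`, `omega_diff_`, `tau_`,
`rmse_`), with functional wrappers (`fit_model`, `refit_fixed_tau`) and an
orchestrating `run_pipeline`.

## Worked example

```python
import numpy as np
from tapsync import (ExperimentDesign, FitConfig, OscParams,
                     generate_experiment, run_pipeline,
                     simulate_delay_coupled, steady_state_asynchrony)

# forward-simulate one tapper: cue period 500 ms, intrinsic period 530 ms,
# coupling 4, self-feedback delay 10.15 ms
p = OscParams.from_diff(500, 30, kappa=4, tau_ms=10.15)
print(np.round(simulate_delay_coupled(p).asynchronies_ms, 1))
print(round(steady_state_asynchrony(p), 2))

# a 3-pair synthetic experiment through the full pipeline
exp = generate_experiment(ExperimentDesign(n_pairs=3, seed=42))
res = run_pipeline(exp.trials, seed=7, fit_config=FitConfig.fast(),
                   ratings=exp.ratings_frame())
print(round(res.median_tau_ms, 2), res.counts)
print(res.cv_frame().groupby("model")[
    ["rmse_train", "rmse_test", "rmse_surrogate"]].mean().round(1))
```

prints

```
[ 25.   45.   61.2  74.3  84.8  93.4 100.4 106.1]
131.36
18.31 {'generated': 72, 'excluded_masked': 0, 'retained': 72, 'fit_failed': 0,
       'boundary_flagged': 21, 'uncoupled_trials': 12, 'uncoupled_participants': 0}
               rmse_train  rmse_test  rmse_surrogate
model
delay_coupled        10.7       12.7           128.4
linear               38.4       38.7           123.9
```

The simulated tapper, slower than the cue, starts 25 ms late and relaxes
toward its steady lag of 131 ms over the 8-tap turn.  In the pipeline run,
all 72 synchronization trials are retained; the delay-coupled model fits the
tapper's own held-out data far better (Test RMSE 12.7 ms) than
condition-matched data from other pairs (Surrogate RMSE 128.4 ms) — the fits
capture individual synchronization dynamics, not generic structure — and
beats the drift-only linear model throughout.  Twelve trials are labelled
uncoupled (the linear fit was at least as good there).

## Command line

```bash
tapsync simulate --seed 0 --out out/
tapsync report --events out/events.csv --ratings out/ratings.csv \
               --out out/ --seed 0
```

`simulate` writes the canonical long events table (one row per tap or cue
onset) plus ground-truth and ratings sidecars; `report` runs
preprocess → fit → cross-validate → classify and writes fits, CV, per-trial
results, condition-summary and ratings-summary CSVs with a JSON manifest.
`preprocess`, `fit`, `crossval` and `classify` run the individual stages.

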