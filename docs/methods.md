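# Methods

`tapsync` analyzes turn-taking auditory–motor synchronization: a tapper
alternates 8 cued beats of tapping with 8 beats of waiting, four tapped
repetitions ("turns") per trial, either alone with a metronome (Solo) or
alternating with a partner (Joint).  The package simulates such experiments
with known dynamics, reduces raw tap/cue onsets to asynchrony series, fits a
delay-coupled phase-oscillator model and a drift-only linear model per trial,
cross-validates both against held-out and surrogate data, and classifies
tappers as coupled or uncoupled to the cue.

## The models

The driver (auditory cue) and driven (tapper) oscillators carry phases in
cycles; the `omega` parameters are periods in milliseconds:

    dθ₁/dt = 1/ω₁
    dθ₂/dt = 1/ω₂ + K·[θ₁(t) − θ₂(t − τ)]

The driven oscillator compares the driver's current phase with its own
time-delayed phase — the delay-coupling mechanism of strong anticipation.
Its stable synchronized solution *leads* the driver: with matched periods the
asynchrony (tap − cue) converges to exactly −τ, and in general (constant-lag
ansatz θ₂ = θ₁ + c) to

    A∞ = −τ + ω_diff / (K·ω₂),       ω_diff = ω₂ − ω₁.

The solution is asymptotically stable iff 0 ≤ K·τ < π/2 (the deviation obeys
φ′(t) = −K·φ(t−τ)).  The *linear model* is the κ = τ = 0 special case: two
uncoupled constant-rate phase equations, i.e. constant-period drift
A(k) = a₀ + k·ω_diff.

Predicted tap times are the crossings of whole cycles by θ₂; the model's
asynchrony at serial position k (k = 1..8 within a turn) is that crossing
time minus k·ω₁.  Each turn is treated as a fresh perturbation: the driven
phase is re-initialized at the turn onset with asynchrony a₀ at the virtual
event one beat before the turn's first cue.  a₀ is fixed at 0 and is not
fitted: the heavy weighting of serial position 1 in the objective requires
the model to generate the first-tap asynchrony from its dynamics.

### Coupling-gain convention

The literature prints κ on a 0–50 scale without fixing the coupling term's
units.  This package uses

    K = κ / (20·ω₁),

i.e. the driven oscillator corrects a fraction κ/20 of its phase error per
driver cycle.  Rationale: (i) typical fitted values κ ≈ 2–8 then correspond
to per-cycle correction fractions 0.1–0.4, the range reported for human
sensorimotor synchronization; (ii) the 0–50 range spans "no correction" to
strong over-correction; (iii) under this normalization κ and ω_diff are
jointly identifiable from a single 8-position series (under a much weaker
gain, e.g. K = κ/ω₁², the per-cycle correction is ≈1% and the two parameters
collapse onto a ridge — recovery error was ~100% in simulation).  Every
qualitative property (κ = 0 reduction, −τ steady state, stability) is
convention-invariant; only the absolute κ scale depends on it.

### Integration

Fixed-step Heun (explicit trapezoidal) with default step 1 ms; the delayed
phase is read from a ring buffer with linear interpolation, and delays
shorter than the step are resolved by an Euler predictor inside the current
step, so any τ ≥ 0 is admissible.  Event (cycle-crossing) times are linearly
interpolated within a step.  Explicit Euler was tried first and rejected: at
step 1 ms its global error reached 0.17 ms per position in fast-tapper
regimes (ω₂ = 300 ms, τ = 50 ms), above the 0.1 ms target; Heun brings the
1 ms vs 0.01 ms step difference below 2e-4 ms everywhere on the stable grid.
A simulation is flagged unstable (NaN positions, no exception) if the driven
phase strays more than 10 cycles from the driver.

## Preprocessing

* **SPR** (spontaneous production rate): mean and CV of intertap intervals
  whose earlier tap lies in complete repetitions 2–3 of an uncued 4½-melody
  trial; the interval spanning into repetition 4 is excluded (the trailing
  half repetition never counts).
* **Matching**: every tap is matched to its nearest cue over the whole trial
  (tie → earlier cue); each cue keeps at most one tap (closer wins, the other
  is dropped).  A drifting tap can land nearest a waiting-block cue, leaving
  its melody position unobserved; nearest-neighbor measurement cannot
  represent asynchronies beyond half a cue period.
* **Asynchronies**: tap − cue in ms (negative = anticipation), averaged per
  serial position over a chosen set of turns; positions missing everywhere
  stay masked, and series with more than 2 masked positions are excluded from
  fitting (logged in the exclusion accounting).

## Fitting

Objective: weighted sum of squared errors over the 8 positions with weights
(4, 1, 1, 1, 1, 1, 1, 2) — the turn onset acts like a perturbation, so the
early curvature carries most of the model-discriminating information; masked
positions are dropped together with their weights.  Each fit runs
`n_restarts` independent two-stage searches: a seeded population-based global
stage (SciPy differential evolution, population 40, 80 generations at the
reference setting, no polishing) followed by bounded L-BFGS-B refinement.
The winner across restarts is the one with the lowest *plain* RMSE over
available positions (the weighted SSE is only the optimization objective).
Bounds: κ ∈ [0, 50], τ ∈ [0, 50] ms, ω₂ within ±300 ms of the cue period
(±350 ms for pairs whose spontaneous rates differ by more than 300 ms).
A parameter within 0.01 of a relevant bound is flagged as a boundary hit
(upper bound for κ and τ — zero is their meaningful value — either edge for
ω₂); flagged trials are excluded from parameter summaries and from the
median-delay computation.

Two structural guarantees are built in: the linear model's objective is
quadratic in ω₂, so its exact weighted-least-squares optimum is injected into
every restart's initial population (the linear fit is exact to float
precision); the same point, mapped to (κ = 0, ω₂), seeds the delay-coupled
search, so the nested-model property — delay-coupled weighted SSE ≤ linear
weighted SSE — holds by construction up to local-stage monotonicity.

The delay is handled in two stages, as in the original procedure: all trials
are first fit with τ free; the median fitted τ over clean (non-boundary) fits
is then fixed and every trial refit with only κ and ω₂ free.  Which stage
feeds cross-validation is not fully specified in the source procedure; this
package uses the fixed-τ model.

Search-budget presets: the reference setting (10 restarts, population 40, 80
generations) is used wherever individual parameter values matter (parameter
recovery, single-trial analyses).  Full-pipeline stages (cross-validation
orderings, classification rates over hundreds of trials) use a reduced preset
(3 restarts, population 16, 30 generations); the measured quantities there
are orderings and rates that are insensitive to the remaining optimizer
slack, and the reduction keeps a 288-trial pipeline under five minutes on one
CPU.

## Cross-validation and surrogates

Each trial's turns are collapsed into the {1,3} and the {2,4} average
(pairing first-with-third and second-with-fourth cancels serial-position
effects); one is assigned to Train, the other to Test, balanced within each
participant's trials.  Models are fit to Train only; the frozen predictions
are scored on Test by Pearson correlation (Fisher z-transformed, r clipped to
1 − 1e-12 so perfect fits stay finite) and plain RMSE.  As a chance baseline
the same predictions are scored against condition-matched *surrogates*: for
each other pair, the same task/cued-rate/trial-number trial of one partner
(seeded random choice when both match), averaged over the same repetition set
as the Test data.  Surrogate correlations are averaged in z-space (a config
switch to r-space exists); surrogate RMSEs are averaged directly.  A model
that captures individual dynamics fits its own tapper's Test data better than
other people's: on the default synthetic experiment mean RMSE orders
Train < Test < Surrogate and mean z orders the other way.

## Classification

A trial is *coupled* iff the delay-coupled fit's plain RMSE is strictly lower
than the linear fit's; ties go to uncoupled.  RMSE differences below 1e-6 ms
are treated as ties: on noise-free drift data both optimizers bottom out near
machine precision and a strict float comparison would be a coin flip.  A
participant is uncoupled iff at least one of the four Task × Cued-Rate
conditions has no coupled trial among its retained trials (conditions with no
retained trials are excluded from the quantifier); a pair is uncoupled if
either member is.

A known statistical limitation, measured and documented rather than patched:
because the delay-coupled model nests the linear model, on truly uncoupled
(drift + noise) trials the extra parameter wins the in-sample RMSE comparison
in roughly 30% of trials *at any noise scale* — the rule's false-positive
rate is geometric, not noise-limited.  Trial-level agreement with
ground-truth regime is therefore ≈100% on noise-free data but ≈80–85% under
realistic motor noise, and the package reports the measured rate.  A held-out
RMSE basis was evaluated and performed worse (overfitting penalized, but the
comparison inherits the Test noise), so the in-sample rule is kept.

## Synthetic data generator

The generator reproduces the study layout: 12 pairs (musicians paired with
musicians, nonmusicians with nonmusicians), 3 uncued SPR trials per
participant, and 3 trials × 2 cued rates (Self = own SPR, Partner = partner's
SPR) × 2 tasks (Solo, Joint) of synchronization per participant — 288
synchronization trials.  Joint trials use both members' SPRs as cue periods.
Everything is deterministic given the design (including its seed).

Distributional choices, where only summary values are reported:

* SPR uniform on [305, 838] ms (only the range is printed);
* CV of ITI normal per group: musician (0.034, 0.009), nonmusician
  (0.060, 0.029), floored at 0.005;
* motor noise: additive i.i.d. Gaussian on tap onsets, SD 10 ms (musician) /
  20 ms (nonmusician) — stand-ins at the order of the groups'
  asynchrony-variability difference, exposed in the design;
* a participant is uncoupled (κ = 0, pure drift at the intrinsic period)
  with probability 7/24, matching the study's 7 of 24 non-adapters;
* baseline κ normal per group — musician (5.3, 2.5), nonmusician (2.2, 1.2),
  clipped to [0.5, 15] — centered on the reported group means; τ = 10.15 ms
  for every coupled tapper (the reported median);
* ratings: three 7-point ordinal draws per participant, centered per
  coupling class on the reported medians (coupled 6/5/6, uncoupled 5/3.5/5).

Two behavioral caps keep extreme rate differences physical.  A coupled
tapper's per-trial κ is raised above its baseline when the cue is far from
the tapper's own rate, so that the steady-state asynchrony stays near 150 ms
(capped at κ = 45): coupling must grow with the rate difference for synchrony
to be maintained at all, and the cap reproduces the positive κ/ω_diff
association seen in fitted parameters.  An uncoupled tapper's drift period is
capped at twice the cue period: a tapper taking 8-beat turns cannot drift an
entire turn past their window.

What the generator does *not* emulate: melody pitch content and audio,
reaction-time onset latencies, serial-position effects within turns,
correlated (e.g. drifting or 1/f) motor noise, and any mechanistic influence
of the partner in Joint trials — the Joint/Solo distinction is metadata plus
an optional extra-noise term (default 0), because each tapper is modeled
unidirectionally against the cue.  Passing tests on synthetic data therefore
validate the pipeline's correctness and the models' identifiability, not the
behavioral claims themselves.

## Numerical and degenerate-input policy

* Simulation: step 1 ms, Heun, deterministic, no randomness in the module.
* Matching ties: tap equidistant between cues → earlier cue; two taps nearest
  one cue → closer tap kept.
* Correlation undefined (zero variance, <3 shared positions) → NaN, masked
  with reason, excluded from z averages.
* Optimizer restart failure → restart dropped; all dropped → fit marked
  failed and the trial excluded from labels (counted in the accounting).
* Exclusion accounting per run: generated = retained + masked-excluded +
  fit-failed; boundary-flagged trials stay classified but leave parameter
  summaries.

## Known limitations

* τ is weakly identified from a single 8-position series when fit jointly
  with κ and ω₂; the median fitted τ over a noisy experiment is biased toward
  the middle of its [0, 50] box (measured ≈16 ms for a true 10.15 ms at the
  reduced search preset).  The two-stage fixed-τ procedure exists precisely
  because of this.
* The classification rule's ≈30% geometric false-positive rate on null
  trials (above).
* Nearest-neighbor asynchronies wrap at half a cue period, so strongly
  drifting uncoupled tappers at large partner-rate differences produce
  masked/garbled positions — mirroring the measurement limit any event-based
  analysis of such trials faces.
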