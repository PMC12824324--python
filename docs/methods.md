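# Methods

This note documents the models, estimators and numerical choices behind
`chronobeh`, in the order data flows through the pipeline.

## 1. The synthetic behavioral generator

The generator produces raw traces (lever positions at 250 samples/s,
treadmill body position at 100 samples/s) whose statistical structure
mimics trained rats in the three paradigms, with two separately
controllable distortions per dose:

- `clock_gain g ≤ 1`: subjective time accumulates at rate `1/g`.  A fast
  subjective clock (g < 1) reaches the subjective 30 s target at objective
  `30·g` seconds — elapsed time is overestimated and fixed-interval
  pressing begins and peaks early.
- `motor_scale m ≤ 1`: every limb and locomotion speed is multiplied by
  `m` (lever rise speed, treadmill peak running speed, reaction time).

### Fixed-interval pressing model

Press-bout onsets follow an inhomogeneous Poisson process whose rate is a
scalar-timing ramp: a Gaussian rise of subjective width
`weber_fraction × 30 s` toward the subjective target, a peak there, and a
sustained level (half the peak, subjective time constant 3 s) until the
reward arrives — trained animals do not stop pressing once they believe
the interval has elapsed.  Timing imprecision additionally places a
fraction `lapse_coefficient × (1 − g)` of intervals in an untimed state
with flat pressing at `lapse_press_rate`; this mixture (standard in
peak-interval modeling) is what produces the near-homogeneous press
distributions and elevated pre-reward AUC at high doses.  A pure shift of
a Gaussian bump cannot do this once reward gating truncates each interval.

Presses far from the subjective target are short sub-threshold touches
(0.8–2.2 cm, 50–200 ms dwell); the probability of committing to a full
coordinated hold follows the squared timing bump and saturates at 1 past
the target.  Full presses are trapezoids: linear rise at
`26 × m` cm/s to 3.0 cm, a hold, and a linear fall, with white positional
jitter (0.02 cm) and an inter-lever onset lag ~ Normal(0, 0.05 s).

### Two-interval hold model

Rewarded holds are planned durations with multiplicative (scalar) noise:

    hold = (required + margin + distortion) × (1 + weber · Z)

- `production_mode = "motor_slowing"`: `distortion = τ·(1/m − 1)` ms with
  movement-time constant τ = 600 ms — additive, independent of the
  required interval.
- `production_mode = "timing_scaling"`: `distortion =
  (required + margin)·(1/g − 1)` — proportional to the interval.

A `reactive_release_fraction` (default 0.05) of trials instead release as
a reaction to reward delivery: `hold = required + RT/m` with RT ~
Normal(300, 45) ms, reflecting the ~300 ms rodent reaction time that
separates pre-planned from reactive releases.  Holds drawn below the
requirement are failed attempts and are retried — observed rewarded
overshoots are therefore left-censored at zero (see §4).

Defaults are calibration choices for a well-trained animal: planned margin
200 ms (failure rate ≈ 4 % on the short interval), Weber fraction 0.12
(within the 0.1–0.2 range typical of rat interval timing), 5 % reactive
releases, 10 % spontaneous extra short attempts.

### Treadmill kinematics

Each trial solves a three-phase plan for a target duration
`7 s + margin + jitter`: passive transport rearward at belt speed to the
rear position (75 cm), a stationary hold, and a final run whose speed
ramps linearly to `v_peak = (60 + 1.5·(belt − 30)) × m` cm/s and decays to
`0.4·v_peak` at the goal-zone entrance (a transversal crossing, so the
entrance time is sharply defined).  Under slowing, one of two compensation
strategies keeps the duration near 7 s: shorten the hold (same rear
position) or truncate the transport (hold duration kept at its control
value, rear position solved from the time budget).  Plans whose hold would
go negative, or whose transport would exceed the belt, raise
`InfeasibleKinematics`; in auto mode a partial-transport trial that does
not fit falls back to the shortened-hold solution.

### Determinism

One master seed; per-session streams derive via
`numpy.random.SeedSequence(master, spawn_key=counters)` (see
`chronobeh.config.derive_seed`), so any session is reproducible in
isolation and identical (config, seed) pairs are bit-identical.

## 2. Event detection

Presses are segmented by threshold crossing with hysteresis: onset at the
upward crossing of 0.1 cm (the touch threshold), offset when the trace
falls below 0.08 cm; crossing times are refined by linear interpolation
between samples.  The span above the 2.6 cm spatial threshold is recorded
per press; bilateral attempts are intersections of left/right spans.
Rewards are resolved either by walking the schedule (fixed-interval gate
or alternating 20-trial blocks, sessions starting with 1250 ms; the first
gate is open at t = 0) or, preferably, against the acquisition system's
logged reward times.  The logged path exists because a hold that grazes
the temporal threshold can be scored differently by re-analysis than by
the rig (sub-millisecond measurement jitter), and on a block schedule a
single disagreement would shift every subsequent block label.

## 3. Timing and kinematic metrics

All aggregates are medians with 25th/75th percentiles; undefined values
(e.g. a zero-variance correlation window) are missing, never zero.

- **Overshoot** `joint release − reward` (ms); **overshoot fraction**
  divides by the required interval.
- **Interlimb correlation**: Pearson r of the two lever positions from the
  successful bilateral movement onset to reward.
- **BMOV**: variance across trials of the absolute inter-lever onset lag
  (s²; the square root is also emitted since the field sometimes reports
  seconds).
- **Movement speed**: |Δposition| per 4 ms bin.  The *maximum* press speed
  is estimated from 60 ms position differences instead: a per-bin maximum
  is an extreme-value statistic that transducer jitter inflates in a
  speed-dependent (hence ratio-distorting) way, while the lever rise lasts
  ≥ 115 ms at every simulated dose, so a 60 ms window still sees the pure
  slope.
- **Trajectory variability**: mean over time of the across-trial IQR of
  onset-aligned traces (1.349·σ for Gaussian jitter).
- **Peri-reward histogram**: press onsets re-referenced to each reward,
  window [−30, +5] s, 1 s bins, normalized to presses/trial/bin.  The
  histogram uses *exploratory* presses — the press that triggered each
  reward is excluded, since it contributes a deterministic count just
  before t = 0 in every trial and would mask the timing signal.
- **AUC**: trapezoidal area of the rate over [−30, 0] s.
- **Peak interval**: 30 s + the time of the maximum of the 3-bin
  moving-average-smoothed rate, ties resolved by the raw rate then to the
  earliest bin, with a parabolic sub-bin refinement through the maximum
  and its neighbours (without it, dose shifts smaller than one 1 s bin are
  unmeasurable).
- **Splits**: session halves (odd trial goes to the second half),
  first/last 100 trials, and first/last 10 trials of each 20-trial block.

## 4. Recovering generator parameters

- `motor_scale`: ratio of dose to control median max press speed.
- planned margin / hold location: observed rewarded overshoots are a
  normal truncated at zero (failures are retried, never recorded), so the
  raw mean is biased upward — by ≈ 20 % for the long interval at the
  default noise level.  `planned_hold_location` inverts the truncation by
  moment matching (`E = μ + σλ(α)`, `Var = σ²(1 − δ)` with `α = −μ/σ`),
  iterated with damping and clamped to a sane box for robustness to the
  small reactive-release component.
- production mode: the dose increments of the overshoot-fraction location,
  pooled over treatment doses, give the ratio described in the README;
  the classification threshold is the geometric midpoint
  `√(1250/750) ≈ 1.291`.

## 5. Treadmill scoring

The goal entrance is the first interpolated downward crossing of the 10 cm
photogate line after the animal has clearly left the zone; duration is
entrance − trial start, correct ⇔ duration ≥ 7 s.  Phase boundaries anchor
on the rear plateau: transport ends at the first arrival within a
noise-scaled band (4σ of the plateau interior, ≥ 0.01 cm) of the rear-most
position, the final run starts at the last departure from it, and the hold
is the span between.  Velocity (centered differences, 50 ms box smoothing)
serves for quality control (near-stationary hold, monotone final run;
|v| < 3 cm/s hold tolerance) and for the peak speed of the final run.
Strategy labels compare each trial to control distributions: hold duration
below the control 5th percentile → `shortened_hold`; rear-most reach below
the control 5th percentile → `partial_transport`; both → the larger
deviation in control-referenced z-units.  Trajectory stereotypy is the
median aligned trajectory per belt speed minus the median at 30 cm/s,
summarized by mean absolute difference.  Incorrect (early-entrance) trials
are excluded from trajectory averages by default (flag to include).
Pixel-unit traces convert at 9 pixels/cm.

## 6. Rank statistics

Kruskal–Wallis, Scheirer–Ray–Hare (SRH), Conover-style LSD post hoc,
Mann–Whitney and a Kolmogorov–Smirnov normality check, all with mid-ranks
for ties.  SRH ranks all N observations jointly, computes two-way ANOVA
sums of squares on the ranks and refers `H = SS_effect / (SS_total/(N−1))`
to chi-square with the effect's df; tie correction enters through the
total mean square computed from the actual mid-ranks.  Unbalanced designs
use Type-II sums of squares on the ranks (via nested least-squares model
comparisons; identical to the classical decomposition when balanced) — the
original SRH description assumes balance, so this is a documented
extension.  "LSD after a rank test" is otherwise undefined, so the post
hoc follows the Conover–Iman formulation: t statistics on rank means with
the pooled rank variance `S²(N−1−H)/(N−k)`, unadjusted p values, gated on
omnibus significance.  Mann–Whitney uses the tie-corrected normal
approximation with continuity correction; the KS test estimates the normal
moments from the sample (the classical p is then conservative — the
Lilliefors caveat — and is reported as such).  No multiple-testing
correction beyond omnibus gating.

Calibration: under a null balanced 2×5 design (n = 10/cell, 2000 reps) the
empirical SRH type-I error at α = 0.05 lies within the binomial 99% band
for all three effects (see `tests/test_acceptance.py`).

## 7. Problem sizes and what the tests show

Simulation-based checks run at: 100–200 trials/session for two-interval
recovery and mode discrimination (100 seeded discrimination runs), 150
trials/session for the fixed-interval dose ladder, 30–60 trials/session on
the treadmill.  These sizes match a realistic behavioral session (the
animals' engaged first ~100 trials) and give the estimators the precision
the acceptance bands assume.

The generator reproduces the *structure* of the phenomena (scalar noise,
censoring, reactive releases, compensation strategies) but not everything
about real data: no learning or satiety drift within sessions, no
rat-level random effects (each session is an independent animal), no
licking or reward-port dynamics, trapezoidal rather than biomechanical
press waveforms, and no pharmacokinetics — the dose enters only through
the two multipliers.  Passing tests therefore validate the estimators and
the dissociation logic under these idealizations, not drug effects in real
rats.  Interlimb correlation is scale-invariant, so the generator's motor
slowing does not degrade it; the dose effect the original experiments saw
on coordination would need an extra noise term.

## 8. Known limitations

- The SRH chi-square reference is asymptotic; cells below ~5 observations
  are not protected.
- The truncation-inversion estimator assumes a single dominant normal
  component; heavy contamination (reactive fraction ≫ 10 %) would bias it.
- The logged-reward trial resolution trusts the rig's event log; with no
  log, a single near-threshold disagreement shifts block labels from that
  trial onward.
- Treadmill strategy classification needs an adequate control reference
  (≥ 5 trials; percentiles stabilize around 30+).
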