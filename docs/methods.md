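# Methods

## The detection problem

A finite-state controller for an active knee/ankle prosthesis consumes a
phase identifier: which of the states quiet standing, gait initiation,
left single stance, left-right double stance, right single stance,
right-left double stance, or gait termination the wearer is currently
in.  The detectors in this package estimate that identifier online, one
100 Hz sample at a time, from eight wearable-sensor signals: per-foot
vertical GRF (N) and longitudinal COP (mm, toe origin, increasing toward
the heel) from instrumented insoles, the summed hip+knee flexion
`sumAng` (deg) from IMU-derived joint angles, and per-foot sagittal
angular velocity (rad/s).  Two derived quantities carry most of the
discriminative load: `grfDiff`, the mean absolute left/right GRF
difference over the past 50 samples (0.5 s), a smoothed measure of
lateral loading asymmetry that is near zero in standing and large
throughout walking; and `sumAng`, which is near zero with extended legs
and oscillates strongly during walking.

## Rule-based state machine

Each detectable state has one conjunctive threshold row (README table).
Per sample, every row is evaluated; the next state is chosen among the
rows that fire, and if none fires the previous flag is retained.  A
sentinel (NaN) COP — the foot is unloaded — makes any COP comparison
false, so an airborne foot can never satisfy a double-stance row.

Three arbitration rules resolve simultaneous firings:

1. **Transition sources.** The quiet-standing rows and the termination
   row are transitions with designated source states (quiet standing is
   entered from initiation or termination; termination from a double
   stance) and are only considered from those states.  Without this,
   stable symmetric standing satisfies the termination row forever and
   the machine could never settle in quiet standing.  The walking rows
   and the initiation row are considered from any state ("free" mode):
   the detector deliberately does not enforce the stride cycle, so a
   missed phase is skipped and detection resumes at the next one.
2. **Priority.** Among applicable fired rows: double-stance rows, then
   single-stance rows, then initiation, termination, quiet standing.
   Double-stance conditions strictly imply the foot-contact part of the
   single-stance conditions, and a single stance always also satisfies
   the initiation row (the swing foot is below `QSgrf`); without this
   ordering those states would shadow each other.
3. **Strict mode** additionally accepts only transitions present in the
   state diagram (5→6, 6→5/11/13, 11→12, 12→13/4, 13→14, 14→11/4, 4→5),
   modelling a downstream controller that pauses on out-of-sequence
   input.  Free mode is the default.

The detector starts in UNKNOWN and leaves it at the first firing row; a
trial that begins with quiet standing is classified immediately.

### Thresholds

The thirteen thresholds are subject-specific tuning parameters.  The
defaults express forces as fractions of body weight `W` and COP
positions as fractions of insole length `L` (260 mm): `QSgrf` = 0.30 W,
`stanceL` = `stanceR` = 0.05 W, `init1` = 0.15 W, `init2` = 0.10 W,
`midCOP` = 0.45 L, `toeCOP` = 0.30 L, `sumQS` = 15°, `sumAngInit` = 25°,
`sumAngTerm` = 20°, `minAng` = 10°, `minG` = 0.2 rad/s, `termG` =
0.3 rad/s.  The contact thresholds sit well above sensor noise but far
below single-stance loading (~0.8–1.1 W); `init1`/`init2` form a
hysteresis band on `grfDiff`; the COP band splits the insole into a toe
region and the rest so the two double-stance types are distinguished by
which foot is on its toes.  All values are implementation defaults,
overridable via a YAML/JSON config, and validated (`init2 ≤ init1`,
`toeCOP ≤ midCOP`).

## HMM classifier

The supervised alternative trains one 3-state HMM per walking phase on
labelled phase segments.  Emissions are single Gaussians with diagonal
covariance — continuous sensor observations, small training sets.
Features per sample: both GRFs, `grfDiff`, both COPs, `sumAng`, both
gyros, plus a binary "loaded" indicator per foot; a sentinel COP is
replaced by the mid-insole position (the indicator carries the contact
information), and all features are z-scored with training-set statistics,
making classification invariant to per-channel affine rescaling.

Training is Baum-Welch (via hmmlearn) from a deterministic
initialisation: emission moments from a partition of each segment into
three temporal thirds, a left-to-right transition prior with self-loops,
start mass on the first state.  Stopping: absolute log-likelihood
improvement < 1e-6 or 200 iterations.  Classification slides a
10-sample window (the current and past 9 samples); each phase model's
forward-algorithm log-likelihood is computed with the package's own
log-space recursion and the maximal model wins, ties breaking to the
lowest flag.  Windows before sample 10 emit UNKNOWN rather than padding.
Quiet standing, initiation and termination are not HMM classes.

**Variance floor.** Fitted variances are floored at 1e-2 in z-scored
units, i.e. no state may claim a standard deviation below 10% of a
feature's training spread.  Clean synthetic segments are exactly
constant in several features (a swing foot's GRF is identically zero);
with a looser floor the fitted Gaussians become near-singular and
windows straddling a phase boundary are decided by a lottery among
astronomically unlikely models — empirically, noise-free phase recovery
drops from 100% to 50%.  The floor encodes that real sensors are noisy
even when a training set is not.

Three training-set designs mirror how such a classifier would be
deployed: *intra* (per-subject models), *inter* (models trained on the
other subjects only, testing transfer), *pooled* (one bank for all
subjects), each using a small number of training walks (default 3) per
subject.

## Synthetic gait generator

Each trial follows one manoeuvre: quiet standing → initiation (weight
shift onto the right leg over 0.25 s, first left swing 0.35 s, first
double stance) → n steady strides → termination → quiet standing.
Defaults describe an unhurried walk: body weight 600 N, 1 stride/s,
per-leg stance fraction 0.62 with 0.12 of the stride in each double
stance (the generator enforces stance = 0.5 + double-stance fraction,
which is an identity for alternating gait without a flight phase), and
a mild prosthetic-side asymmetry of 0.9 scaling both the prosthetic
single-stance duration and its GRF amplitude.

Waveforms are qualitative models of real morphology, not fits: stance
GRF is a double bump (peaks ≈ 1.1 W at 25%/75% of stance, valley
≈ 0.8 W) with a 10%-of-stance edge ramp; COP travels linearly from
0.85 L at heel strike to 0.10 L at toe-off and is NaN whenever the foot
carries < 20 N; `sumAng` follows a flat-topped, sharp-bottomed
oscillation between 5° (double-stance minima) and 70° (mid-swing
maxima); swing-phase gyro is one biphasic ±3 rad/s sine cycle.
Per-channel Gaussian noise is added last (GRFs clipped at zero, COP
re-masked below the contact epsilon).  Labels come analytically from
the phase schedule; the initiation label extends through the first
double stance so the first walking label is a single stance, keeping
ground truth on the state diagram.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: compensatory movement patterns of prosthesis
users, step-to-step timing variability, sensor drift and axis
misalignment, COP dropouts under partial loading, and slopes or stairs.
Results on synthetic trials demonstrate correctness of the detection
logic under the stated signal model, not clinical performance.

## Evaluation

Flag streams are run-length encoded; runs shorter than a debounce
(default 3 samples ≙ 30 ms, about the shortest physiologically
meaningful phase fragment) are absorbed into the longer neighbouring
run *before* restricting to walking flags, so a one-sample blip cannot
split a stance in two.  A ground-truth phase counts as correctly
recognised when a detected segment of the same flag overlaps it by at
least one sample and that segment's neighbours respect the cyclic order
11→12→13→14 with at most one skipped phase.  Ratios are reported per
sound/prosthetic-mapped phase type in percent; cross-trial and
cross-subject aggregation pools counts (the ratio of sums, not the mean
of ratios), and the summary reports both the phase-averaged mean and
the phase-count-weighted mean, which differ when phase counts are
unbalanced.

Because `grfDiff` is a 50-sample average, it necessarily fills in over
~0.1–0.3 s after gait onset and drains over ~0.4 s after the last foot
fall; detection of initiation and termination therefore lags their
ground-truth onsets by construction.  Per-sample agreement statements
in the tests are accordingly made over steady-walking samples; the
non-steady states are exercised through their transition logic.

## Problem sizes and determinism

Everything is seeded: the generator takes an explicit seed, HMM
initialisation is deterministic, and the benchmark derives per-subject
draws and consecutive per-trial seeds from one base seed.  The test
suite uses 3-6-stride trials and a handful of walks (about half a
minute total); the acceptance benchmark uses 4 subjects × 20 walks ×
10 strides (3 200 ground-truth phases, a few seconds).  These sizes
give stable ratios — each phase type occurs 800 times in the benchmark
— while keeping runs interactive.

## Known limitations

* Default thresholds are heuristics on the synthetic signal model; real
  deployments tune them per subject.
* The HMM path classifies every sample into one of the four walking
  phases, including standing spans; scoring is restricted to walking
  ground truth.
* The rule engine evaluates the initiation row from any state, so brief
  initiation flags can appear inside noisy stances (the evaluation
  debounce absorbs them); a stricter gating would trade responsiveness
  at gait onset.
* Strict mode reconstructs a plausible controller topology; prosthesis
  hardware behaviour (locking, torque control) is out of scope.
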