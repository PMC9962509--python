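# Methods

## Problem and model

`gaitesn` predicts two quantities from the tri-axial accelerometer channels of
a single inertial sensor worn on the lower limb during treadmill walking:

1. **Ground reaction force (GRF)** — the anterior-posterior (AP),
   medio-lateral (ML) and vertical (V) force components, expressed as
   fractions of the participant's body weight `W_p`:
   `y(t) = [R_AP, R_ML, R_V] / W_p`.
2. **Gait event detection (GED)** — five stance-phase events per gait cycle:
   heel strike (HS), heel push (HP, first vertical-force maximum), foot flat
   (FF, mid-stance minimum), toe push (TP, last maximum) and toe off (TO),
   encoded as a 5-row binary target with exactly one non-zero sample per
   event per cycle.

The predictor is a leaky **echo state network** (ESN): a fixed random
recurrent layer

    x~(t) = tanh(W_in u(t) + W x(t-1))
    x(t)  = alpha x~(t) + (1 - alpha) x(t-1)
    y(t)  = W_out x(t)

whose only trained component is the linear readout `W_out`, fit in closed
form by ridge regression on streaming normal equations
`W_out = (sum_p Y_p P_p X_p^T)(sum_p X_p P_p X_p^T + gamma I)^{-1}`.
`P_p` is a per-sample diagonal importance matrix: the identity for *standard*
training, or a Gaussian record weight
`exp(-(v_p - c_k)^2 / (2 w^2))` for *kernel* training, where `v_p` is the
record's mean gait temporal parameter (cycle duration, stance duration or
stance proportion), producing a bank of readouts each specialized to a
cadence regime.  At prediction time the readout whose centre is nearest to
the record's parameter — estimated from the *predicted* HS/TO events of the
GED task on the test split — is selected (ties go to the lower centre).
Nearest-centre hard selection was chosen over soft blending as the simplest
rule consistent with per-record specialization; it is the package's
documented choice where the operating rule was genuinely open.

The input vector is `u(t) = [1, a_axes...]` — a constant bias plus one to
three acceleration axes.  With five sensor locations (top of shoe TS, heel H,
medial malleolus MM, mid-front tibia MFT, medial shank near knee MK) and
seven axis subsets, the sweep evaluates 35 input configurations per group,
task and training method.

## Hyperparameters

| parameter | symbol | default | notes |
|---|---|---|---|
| reservoir nodes | N | 100 | |
| leak rate | alpha | 0.1053 | convex combination; see below |
| spectral radius of W | rho | 0.7471 | pinned exactly by rescaling |
| sparsity of W | — | 0.21 | Bernoulli support, values U(-1,1) |
| ridge regularization | gamma | 1e-6 | fixed across configurations |
| input scaling | s | 1.0 | W_in dense U(-s, s) |
| washout | — | 200 samples (1 s at 200 Hz) | excluded from the normal equations |
| train fraction | — | 0.70 | contiguous record prefix |
| kernel centres | k | 5, equally spaced over the [5th, 95th] pct of the training parameter | width = half the centre spacing |
| event edge threshold | — | 20 N (~3% BW at 70 kg) | HS/TO rising/falling edges |
| peak-finder separation | — | 0.7 x group mean training cycle duration | |
| peak height floor | — | 0.3 x row maximum | suppresses readout ripple |

Numerical choices: the leak update uses the standard convex combination
`(1 - alpha) x(t-1)`; a variant retaining `(alpha - 1) x(t-1)` is available
via `leak_variant="printed"` for comparison but destroys the fading-memory
interpretation at small alpha.  The ridge solve goes through a symmetric
positive-definite `scipy.linalg.solve`, never an explicit inverse; a singular
system at `gamma = 0` raises an error naming the remedy.  Inputs are
z-scored per channel with training-split statistics before entering the
reservoir (tanh saturation control).  Flat-topped force maxima are assigned
their plateau-centre sample; the FF midpoint fallback uses the
round-half-up midpoint `(HP + TP + 1) // 2`, which is invariant under index
translation.  Event matching is greedy one-to-one by increasing time
distance; on adversarial spacings this can exceed the optimal-assignment
total (the tests document the divergence), but with one predicted peak per
cycle it attains it.  Unmatched target events are excluded from the MAE and
counted separately.

## Error metric

All scores are **record-weighted mean absolute errors**: the mean over
records of the per-record mean over samples (events: milliseconds over
matched pairs; forces: body-weight fractions over masked samples), so long
records do not dominate.  Force errors are additionally restricted to
gait-cycle percentage zones — full cycle (0, 100), weight acceptance
(10, 18) and push-off (44, 52) — with the cycle phase defined HS-to-HS on
the force-derived (target) events.  A (0, 18) variant of the first zone is
available through `SweepConfig.zones`.  Summaries report, per
(group, task, method, axis/event, zone) cell, the minimum-MAE
(location, axes) pair and its distance below the cell mean in *population*
standard deviations (the 35 configurations are the full universe, not a
sample), plus the fraction of force cells each location wins.

Stance duration is HS-to-TO by default; an HS-to-FF reading is exposed as
`stance_end_event="FF"` without endorsement, since it contradicts the
conventional stance definition.

## Synthetic data generator

No public dataset accompanies this problem setting, so the package ships a
seeded generator whose statistical structure matches what the analysis
assumes.  Group profiles: healthy (self-selected speed 1.28 ± 0.13 m/s,
cycle ≈ 1.05 s, stance 62% of cycle, mid-stance valley 0.35 BW deep) and
medial knee osteoarthritis (0.75 ± 0.23 m/s, cycle ≈ 1.30 s, stance 66%,
**flat valley** — no interior force minimum, triggering the FF midpoint
fallback).  Each participant receives one record per speed condition
(0.8x, 1.0x, 1.2x their self-selected speed; cycle duration scales as
speed^-0.5), a body weight drawn once from the group mass distribution
(73.1 ± 16.5 kg healthy, 80.5 ± 15.3 kg MKOA, times g), and cycle-to-cycle
duration jitter (CV 4-6%).

The vertical force of a cycle is composed from cosine primitives on the
stance grid: steep quarter-cosine contact edges (so the above-threshold span
tracks the constructed stance duration), two maxima at 22% and 78% of stance
(1.15 BW when a valley exists), and either a raised-cosine valley at 47% or
an exactly flat plateau at 1.0 BW with small (3%) shoulder bumps for the
flat-valley profile.  AP force is a braking/propulsion lobe pair with zero
net impulse; ML is a small single lobe.  GRF is generated at 1000 Hz,
accelerations at 200 Hz, sharing t = 0 (no cross-correlation
synchronization is modelled).  The force channels are noiseless by
construction so that swing-phase samples are exactly zero and event truth is
exactly recoverable; measurement noise enters through the accelerometers.

Accelerations are deterministic functions of the cycle: a GRF-coupled
component (the cycle's normalized force curves interpolated onto the IMU
clock), raised-cosine impact transients locked to the true HS and TO times,
and three phase-locked harmonics — each location with its own gains, pulse
widths and phases — plus Gaussian noise proportional to the channel's
noiseless scale.  Because per-channel standardization removes amplitude
information, the feature that differentiates locations for a linear readout
is the **relative noise level**: the top-of-shoe sensor is planted as the
most informative location (noise factor 1.0, rising to 4.0 at the medial
shank), mirroring the empirical observation that distal sensors carry the
sharpest gait information.  Records end wherever the configured duration
falls, possibly mid-cycle, like a real recording; ground truth lists only
cycles whose stance fits inside the record.

**What passing tests do and do not show.**  The generator guarantees a
learnable, phase-locked acceleration-to-force mapping and a planted location
ordering; real gait adds sensor drift, soft-tissue artifacts, stride-length
variability decoupled from cadence, and between-subject waveform differences
none of which are modelled.  Green tests therefore validate the machinery
(event rules, weighted ridge algebra, reservoir contracts, sweep logic), not
clinical-grade force prediction; the published error levels on measured data
cannot be reproduced without that data.

## Problem sizes used by the test suite and acceptance script

The suite uses 3-10 participants per group, 3 speed conditions and 10-30 s
records (e.g. the learnability check uses 10+10 participants x 3 speeds x
30 s at 200 Hz; the planted-location check uses 10 dataset seeds of
3+3 participants x 12 s), and the acceptance script 6+6 participants x
3 speeds x 20 s with a 15-configuration sweep.  These sizes are the
package's default desk-scale experiment; all of them regenerate from seeds
at run time.

## Known limitations

- The generator is artifact-defined, not a biomechanically validated
  simulation (no belt dynamics, no gyroscope/magnetometer channels, no
  sensor drift).
- Single-sample binary GED targets make the readout least-squares problem
  spike-fragile; an optional triangular target widening exists but is OFF by
  default to keep the strict binary definition.
- Kernel readout selection depends on the GED task's predicted events; if a
  test segment yields fewer than two predicted heel strikes the group-mean
  training parameter is used as a fallback.
- Greedy event matching is not globally optimal on pathological peak
  configurations (documented above).
- One model is trained per group by default; pooled training is a config
  flag (`pooled_groups=True`).
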