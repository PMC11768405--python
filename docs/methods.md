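# Methods

## Problem and scope

`gaitkit` analyzes walking from markerless motion capture: time series of
3D positions (meters) for 17 body keypoints (head, shoulders, elbows,
wrists, hips, knees, ankles, heels, big toes; COCO-WholeBody naming).
Such trajectories typically come from an RGB-D sensor plus a 2D pose
estimator whose keypoints are lifted to 3D through the depth stream; the
pose-inference stage itself is out of scope — `gaitkit` starts at the
keypoint trajectories (or at 2D pixels + depth, via the pinhole
deprojection helper) and ends at clinical gait parameters and
agreement statistics against a reference system.

## Preprocessing

Order is fixed: **resample → gap-fill → low-pass filter**. Filtering an
unfilled gap boundary would ring, so gaps are closed first; resampling
first puts everything on the uniform grid the other two steps require.

- **Resampling** interpolates each keypoint coordinate with a cubic
  spline onto a uniform grid (default 30 Hz, the native rate of current
  RGB-D sensors; reference systems recording at e.g. 178 Hz are brought
  down to the common rate). A resampled frame is valid only when
  bracketed by valid source frames at most one source period apart, so
  occlusions are never interpolated away silently.
- **Gap filling** closes invalid runs *strictly shorter* than 250 ms
  (with valid data on both sides) by cubic-spline interpolation. Edge
  gaps are never extrapolated — cubic extrapolation is unstable.
- **Filtering** is a 4th-order Butterworth low-pass, 7 Hz cutoff,
  applied forward–backward (zero phase) per contiguous valid segment.
  Zero-phase application is a deliberate choice: contact timing must
  not be lagged when comparing against a time-aligned reference. The
  effective attenuation is therefore the squared magnitude response.
  Segments shorter than the filter warm-up pass through unfiltered with
  a warning.

Velocities are central differences on the uniform grid (one-sided at
segment edges), and all speed thresholds act on the Euclidean norm of
the 3D derivative — hence detection is invariant to rigid transforms of
the world frame and to the walking direction.

## Contact detection

Initial contact (IC): the 3D **heel** speed falls below
`ic_factor × walking speed` (default 0.5). Final contact (FC): the 3D
**toe** speed rises above `fc_factor × walking speed` (default 0.8).
The downward crossing anchors heel strike; for toe-off the upward
crossing is chosen because the toe is quasi-static throughout stance
and accelerates out of it. Crossing times are refined below the frame
grid by linear interpolation of the speed series — at 30 Hz this
halves the worst-case quantization error.

The threshold adapts in two passes: pass 1 assumes 1 m/s; the walking
speed is then re-estimated as the **median** over successive same-side
IC pairs of heel displacement / time difference (median rather than
mean: robust to turning strides and outlier cycles), and detection is
re-run. Same-kind crossings closer than `min_event_separation`
(default 0.4 s — shorter than any physiological stride at normal speed,
longer than threshold jitter) are debounced keeping the earlier one.
Finally, per-side sequences are cleaned so IC and FC strictly
alternate; of two same-kind neighbors the one with the weaker threshold
margin is dropped, since a single spurious crossing would otherwise
shift every downstream cycle parameter.

A known, inherent property of velocity-threshold detection: the
crossing precedes the true touchdown (the heel is still decelerating)
and follows the true lift-off slightly, so detected stance is a few
tens of milliseconds longer than the true stance. Mean absolute timing
error on the noiseless simulator is ≈ 20 ms (under one 30 Hz frame);
stance-derived quantities (swing, double support) inherit the bias,
stride times and lengths do not (the bias cancels between successive
ICs).

## Gait-cycle parameters

One record per same-side IC→IC interval (records crossing an analysis
window boundary are dropped entirely, not truncated). Temporal
parameters are event arithmetic; spatial parameters are computed in the
ground plane (configurable up-axis, default +z), because the vertical
component of heel positions at contact would contaminate lengths.
Definitions as in the module docstring; choices worth noting:

- **Stride width**: perpendicular distance of the intervening
  opposite-foot IC to the stride's line of progression (the segment
  between its two IC positions).
- **FPA**: unsigned (0–90°) angle between the line of progression and
  the stance-time-average heel→toe axis. Averaging over stance
  suppresses per-frame noise; the sign (in-/out-toeing) is discarded
  because aggregation (means, asymmetry ratios) presumes positive
  values.
- **Arm swing ROM**: the shoulder→wrist vector is projected onto the
  sagittal plane (walking direction × up-axis); ROM = max − min of its
  inclination within the cycle. Purely mediolateral motion projects to
  zero by construction.
- **Knee ROM**: flexion = 180° − interior hip-knee-ankle angle
  (straight leg = 0°, clinical convention); ROM = max − min over the
  cycle.
- **Per-stride velocity** = stride_length / stride_time (exact by
  construction).

Aggregation: the mean pools both sides' cycles; CV = 100 × sample
(ddof = 1) std / mean, pooled; asymmetry = 100 × (1 − smaller-side
mean / larger-side mean), computed from per-side means and requiring at
least 3 valid strides per side (configurable).

## Agreement statistics

Events are matched one-to-one per (kind, side) stratum, greedily by
smallest |Δt| under a 250 ms tolerance (ties toward the earlier
reference event). Greedy equals the optimal assignment whenever jitter
is small against the inter-event spacing — the regime any usable
detector operates in — and is auditable. Recall, precision and F1
follow the standard count formulas; signed timing error is
t_reference − t_candidate (positive = candidate early).

Parameter agreement over subjects: absolute RMSE; relative RMSE
normalized by the reference mean (the natural scale-free choice when
the reference is the trusted system); and ICC(3,1) — two-way mixed
model, single measures, **consistency** form,
(MS_rows − MS_err) / (MS_rows + MS_err) for two raters — which ignores
fixed offsets between systems (relative agreement). No confidence
intervals are computed.

## Synthetic gait generator

The simulator is kinematic: joint profiles are prescribed, not
physically simulated, which is sufficient because every downstream
computation consumes positions only.

- **Schedule**: alternating step durations ~ Normal(stride_time/2, σ)
  truncated at ±3σ, with σ set so stride times realize the commanded
  CV. IC/FC times come from this schedule exactly and are stored as
  ground truth — never re-derived from the trajectory.
- **Feet**: flat and motionless during stance (stance fraction default
  0.6 of the cycle); during swing the foot translates by the drawn
  stride length with a half-sine forward-velocity profile (zero speed
  at lift-off/touchdown, mid-swing peak ≈ 3.9× walking speed) and a
  5 cm sin² vertical clearance. Heel speed in mid-stance is < 0.3× and
  toe speed in mid-swing > 1× walking speed, so the default thresholds
  are discriminative by construction.
- **Body**: pelvis/shoulders/head advance at the mean speed; thighs
  swing ±20° about vertical; the shank adds a two-peak knee-flexion
  profile (stance wave at 25 % of the range, swing peak at 100 %) whose
  max − min equals the commanded knee ROM exactly; arms are anti-phase
  sagittal pendulums with per-cycle ROM equal to the commanded value;
  feet realize the commanded FPA and step width.
- **Degradations**: isotropic Gaussian keypoint noise and Poisson-count
  dropouts shorter than 250 ms. All randomness flows from one seeded
  generator; the output is bit-reproducible per seed.
- **Defaults** describe typical healthy adult gait at self-selected
  speed: 1.2 m/s, 1.1 s stride time (1.32 m strides), 60 % stance,
  0.18 m step width, 7° FPA, 30° arm-swing ROM, 40° knee ROM, 3 %
  stride-time/length CV, 30 Hz.

Commanded asymmetry scales the right side down by the given percent.
For stride length this makes the two feet's forward positions diverge
over a long bout — kinematically impossible for a real walker — but no
computed parameter depends on the inter-foot forward distance, so the
commanded asymmetry is still recovered exactly by the pipeline.

**What the simulator does not emulate**: pose-estimator outliers and
identity swaps (noise is Gaussian, not heavy-tailed), depth-dependent
noise anisotropy, soft-tissue and footwear dynamics (heel pitch,
roll-off), turning, stopping, pathological patterns, and correlated
left-right timing disturbances. Passing the recovery tests therefore
demonstrates correctness of the algorithms under clean assumptions, not
field performance on clinical recordings.

## Numerical choices and problem sizes

- Gap limit comparisons are strict (`gap < 250 ms`); threshold
  crossings use half-open frame intervals so a crossing is counted
  exactly once; arccos arguments are clipped to [−1, 1].
- ICC returns NaN (undefined) on zero between-subject variance; CV is
  NaN for zero means; missing keypoints yield NaN parameter fields that
  aggregation skips.
- Recovery and detection checks run on bouts of 100 recorded cycles
  (50 per side, ≈ 57 s at 30 Hz) — large enough that CV/asymmetry
  sampling error is well inside the asserted bands, small enough that
  the full suite runs in seconds.
- At 30 Hz, sampled extrema of smooth angle profiles undershoot the
  true ROM by up to ~1.5 % (quadratic peak-sampling error); the
  recovery tolerance (2 % noiseless) accommodates this.

## Known limitations

- Detection assumes roughly straight-path walking between analysis
  windows; turns must be excluded via windows (no automatic turn
  detection).
- Stance-phase-derived parameters (swing, double support) carry the
  systematic threshold-crossing bias discussed above; comparisons
  between two systems both using this detector are unaffected, absolute
  stance durations are slightly overestimated.
- C3D input is not supported; keypoint CSV/JSON dialects are.
- No normalization to body height/leg length, no time-normalized curve
  averaging, no multi-person tracking.
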