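# gaitkit

Markerless 3D gait analysis from body-keypoint trajectories.

Clinical gait assessment needs objective, granular measures —
spatiotemporal step parameters, their stride-to-stride variability and
left-right asymmetry, and whole-body coordination such as arm swing and
knee range of motion. Marker-based optical motion capture delivers them
but is lab-bound and resource-intensive; modern pose tracking on a
single RGB-D sensor can produce 3D body-keypoint trajectories almost
anywhere. `gaitkit` is the analysis layer for such data: it turns
timestamped 3D positions of 17 body keypoints into foot-contact events,
per-gait-cycle parameters, and agreement statistics against a reference
system. A built-in kinematic walking simulator generates
ground-truth-bearing trajectories, so the whole pipeline is testable
without any recordings.

Intended users: movement scientists and biomedical engineers validating
or deploying markerless gait capture, and anyone needing a transparent,
scriptable implementation of standard gait-cycle computations.

## Method

**Preprocessing.** Trajectories are resampled to a common rate (default
30 Hz) by cubic splines, occlusion gaps shorter than 250 ms are closed
by cubic-spline interpolation, and each coordinate is smoothed with a
zero-phase 4th-order Butterworth low-pass at 7 Hz.

**Contact detection** (two-pass adaptive threshold). With walking speed
v, an initial contact (IC) is detected where the 3D heel speed falls
below 0.5 v, and a final contact (FC, toe-off) where the 3D toe speed
rises above 0.8 v, with sub-frame refinement of each crossing. The
first pass assumes v = 1 m/s; v is then re-estimated as the median of
per-stride heel displacement over duration from the first-pass ICs, and
detection is repeated.

**Gait-cycle parameters.** For each stride (same-side IC→IC interval):
stride time; swing time t_IC(k+1) − t_FC(k); double-support time (sum of
the two both-feet-on-ground intervals); stride length ‖p_IC(k+1) −
p_IC(k)‖ in the ground plane; stride width (perpendicular distance of
the opposite-foot IC to the line of progression); velocity = stride
length / stride time; foot progression angle (line of progression vs
stance-average heel→toe axis); arm-swing ROM (sagittal-plane
inclination range of the shoulder→wrist line); knee ROM (flexion range,
straight leg = 0°). Aggregates per parameter: mean, CV = 100·σ/μ [%],
and side asymmetry = 100·(1 − μ_smaller/μ_larger) [%].

**Agreement.** Candidate events are matched one-to-one to reference
events of the same type and side within 250 ms; recall = TP/(TP+FN),
precision = TP/(TP+FP), F1 = their harmonic mean, plus signed/absolute
timing errors. Parameter agreement over subjects: absolute and relative
RMSE and the consistency intraclass correlation ICC(3,1) =
(MS_rows − MS_err)/(MS_rows + MS_err) from the two-way mixed model.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from gaitkit import (GaitSimConfig, simulate, preprocess, detect_events,
                     build_strides, summarize, match_events,
                     detection_performance)

cfg = GaitSimConfig(n_strides=20, noise_std=0.005, seed=42)
traj, truth = simulate(cfg)                   # 40 cycles, 5 mm keypoint noise

clean = preprocess(traj)                      # 30 Hz, gap-fill, 7 Hz low-pass
events = detect_events(clean)                 # two-pass adaptive thresholds
strides = build_strides(events, clean)
summary = summarize(strides)
print(summary.table.round(2))

perf = detection_performance(match_events(events, truth.events))
print(f"F1 = {perf.f1:.3f}, mean |dt| = {perf.mean_abs_time_error*1000:.1f} ms")
```

Output:

```
                      mean  cv_pct  asymmetry_pct   n
parameter
stride_time           1.10    2.22           0.12  40
swing_time            0.40    1.91           0.19  40
double_support_time   0.30    5.68           0.37  40
stride_length         1.32    2.23           0.52  40
stride_width          0.18    1.61           0.13  40
velocity              1.19    3.32           0.43  40
fpa_deg               6.98    5.80           2.54  40
arm_swing_rom_deg    30.48    1.66           1.00  40
knee_rom_deg         39.42    2.31           0.43  40
F1 = 1.000, mean |dt| = 19.3 ms
```

Every ground-truth contact is recovered (F1 = 1.000) with a mean timing
error of 19.3 ms — under one frame at 30 Hz — and the commanded gait
(1.1 s strides of 1.32 m at 1.2 m/s, 30° arm swing, 40° knee ROM) is
read back within a few percent despite the noise. Swing and
double-support durations carry the small systematic stance-lengthening
bias inherent to velocity-threshold detection (see `docs/methods.md`).

## Command line

```sh
gaitkit simulate out/ --n-strides 20 --noise-std 0.005 --seed 42
gaitkit analyze out/keypoints.csv results/ --reference-events out/events_truth.csv
gaitkit validate results/events.csv out/events_truth.csv
gaitkit deproject pixels.csv points.csv --fx 504 --fy 504 --cx 320 --cy 288
```

`analyze` writes `events.csv`, `strides.csv`, `summary.json` and, when a
reference is given, `detection_report.json`.

### File dialects

Keypoint CSV: one row per frame, `time_s` then `<keypoint>_x,_y,_z` per
keypoint (meters), NaN = invalid sample. Keypoint JSON: `{"rate": …,
"frames": [{"time": …, "keypoints": {label: [x,y,z] | null}}]}`. Events
CSV: `time_s, kind, side, x, y, z`.

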