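# irisvel

Video-based detection of small eye movements from **iris-texture motion**.

Conventional video eye trackers localize the pupil and/or corneal
reflection per frame; for microsaccades (rapid movements under 0.5° of
visual angle) that signal sits at the tracker's noise floor, which is why
reports of very small — especially monocular — microsaccades are
contested. `irisvel` implements the alternative: estimate eye **velocity**
directly from the motion of many local iris texture features between
consecutive frames, after compensating head motion with a planar
similarity transform, and classify events with an adaptive velocity
threshold. A population of features beats a single landmark: the per-frame
motion estimate is the geometric median of ~10² matched keypoint shifts,
robust to outlying matches and precise to hundredths of a pixel.

The package is aimed at eye-movement researchers who want a desk-scale,
fully testable implementation of this methodology: every stage runs on
synthetic eye video with exact ground truth, so the whole chain can be
validated without any recordings.

## Method at a glance

For each eye and frame pair, with iris mask M and CLAHE-equalized frames:

1. detect sub-pixel Harris corners in M, describe by normalized intensity
   patches; brute-force match, Lowe ratio 0.75, RANSAC (translation model);
2. motion vector `d[k]` = geometric median of matched shifts;
   velocity `v[k] = g · d[k] · fps` (g = calibration gain, deg/px, from
   OLS regression on a 9-point target grid); position = ∫ v;
3. total-variation denoising (exact solver, λ = 0.1) on position;
4. cyclopean speed `s[k] = |½ (v_L[k] + v_R[k])|`;
5. adaptive I-VT: two-component Gaussian mixture on `s < 20` deg/s,
   threshold `max(μ_noise + 3σ_noise, 3.84)` deg/s; peaks closer than
   5 frames (52 ms @ 96 fps) merge; peaks ≥ 50 deg/s are saccades;
   amplitude = displacement between the flanking speed minima.

Head motion is removed beforehand by cascading per-frame-pair similarity
transforms estimated from one geometric-median correspondence per each of
four facial patches, with direct realignment to a new keyframe every 480
frames. See `docs/methods.md` for the full account.

## Worked example

Run the full pipeline on a short synthetic scene — 8 s of two-eye video at
96 fps with seven injected microsaccades, drift, sensor noise and 12 px /
1 Hz head motion — and score the detections against ground truth:

```python
from irisvel import PipelineConfig, run_pipeline

config = PipelineConfig(duration_s=8.0, n_events=7, seed=7)
result = run_pipeline(config, out_dir="out")

print("threshold:", result.threshold)
print("hits/misses/false alarms:", result.score.hits,
      result.score.misses, result.score.false_alarms)
for ev in result.microsaccades:
    print(f"  peak {ev.peak_speed:5.1f} deg/s  amplitude {ev.amplitude:.3f} deg")
```

which prints (about two minutes on one CPU):

```
threshold: 3.84
hits/misses/false alarms: 7 0 0
  peak  13.9 deg/s  amplitude 0.281 deg
  peak  14.0 deg/s  amplitude 0.301 deg
  peak   9.1 deg/s  amplitude 0.186 deg
  peak   9.6 deg/s  amplitude 0.216 deg
  peak  17.7 deg/s  amplitude 0.406 deg
  peak  20.8 deg/s  amplitude 0.472 deg
  peak  13.4 deg/s  amplitude 0.295 deg
```

The adaptive threshold resolved to the 3.84 deg/s floor (the tracker noise
component of the mixture sits near 0.2 deg/s), all seven injected events
were found with no false alarms, and the recovered amplitudes track the
injected 0.2–0.5 deg range; peak speed ≈ 47 × amplitude, the main-sequence
relation the generator enforces. `out/` then contains the stage artifacts
(`traces.csv`, `events.csv`, `transforms.csv`, `score.json`,
`manifest.json`).

The same stages are available as a CLI for file-based runs:

```bash
irisvel simulate --out sim --seed 2 --duration 5 --n-events 4
irisvel run --config pipeline.yaml --out results
irisvel detect --traces traces.csv --out events.csv --floor 3.84 --min-sep 5
```

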