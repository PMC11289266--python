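# icgperf

Continuous organ-perfusion monitoring from repeated low-dose indocyanine
green (ICG) boluses.

During abdominal surgery, a single intravenous ICG bolus gives only a
transient, qualitative impression of organ perfusion before the dye is
cleared by the liver. A high-frequency (one per minute), low-dose
(0.008 mg/kg) bolus regimen instead produces a *continuous oscillating*
fluorescence signal in perfused tissue: each bolus adds one wash-in/wash-out
wave to the time–intensity curve of a tracked region of interest (ROI).
When an organ-supplying artery is occluded, the oscillation flattens or
disappears — and this can be detected quantitatively, in real time, even
after accumulated dye has made the organ so bright that visual assessment is
useless.

`icgperf` implements the full analysis chain for this monitoring method,
plus a synthetic-recording generator with known ground truth for validating
every stage:

- **`icgperf.synthgen`** — synthetic laparoscopic NIR recordings:
  gamma-variate bolus kinetics, progressive dye accumulation ("visual
  saturation"), respiratory/peristaltic motion, inverse-square camera-distance
  attenuation (7.5 vs 15 cm), sensor noise; every latent variable exposed as
  ground truth.
- **`icgperf.track_extract`** — ROI tracking by normalized cross-correlation
  and time–intensity curve extraction.
- **`icgperf.bolus_metrics`** — per-bolus segmentation and the six standard
  wash-in metrics (below).
- **`icgperf.detect_stats`** — per-condition hypoperfusion classification,
  streaming per-bolus flagging, paired t-test, cohort reports.
- **`icgperf.pipeline` / `icgperf.cli`** — end-to-end drivers and the
  `icgperf` command-line tool.

## Perfusion metrics

For each injection window, relative to the local pre-injection baseline
`F0` (median of the preceding 10 s, which absorbs accumulation drift):

| metric | definition |
| --- | --- |
| `F_max` | peak fluorescence rise above `F0` (a.u.) |
| `T_0` | injection → first detectable signal (s) |
| `T_max` | first signal → peak (s) |
| `T_1/2max` | first signal → 50 % of peak rise (s) |
| `Slope` | mean wash-in rate, `F_max / T_max` (a.u./s) |
| `TR` | time ratio `T_1/2max / T_max` (dimensionless) |

The first detectable signal is a noise-floor crossing: intensity above
`F0 + 3·σ̂` for 3 consecutive samples, with `σ̂ = 1.4826·MAD` of the
pre-injection span. A window with no crossing is reported *not detected*
(all metrics undefined) — the signature of absent perfusion.

A condition is classified against the subject's own baseline recording:
**absent** if fewer than half of the expected boluses are detected,
**decreased** if mean `Slope` falls below 0.7× the baseline mean, otherwise
**normal**. The same rule applied per bolus gives a real-time monitor with
a latency of one bolus period (60 s).

## Worked example

```python
import icgperf as g

# three virtual subjects: 6 min baseline, then severe (central) arterial
# occlusion, full imaging pipeline (render -> track -> extract -> classify)
res = g.run_cohort(3, ("baseline", "severe"), seed=7, use_frames=True)
print(g.format_report_text(res.report))
```

prints

```
Cohort report — 3 subject(s)

Condition 'baseline' (detected 36/36 boluses):
  f_max       (M = 9.75, SD = 6.88, n = 36)
  t_0         (M = 2.51, SD = 0.63, n = 36)
  t_max       (M = 7.75, SD = 1.09, n = 36)
  t_half_max  (M = 2.80, SD = 0.45, n = 36)
  slope       (M = 1.25, SD = 0.88, n = 36)
  tr          (M = 0.36, SD = 0.02, n = 36)

Condition 'severe' (detected 36/36 boluses):
  f_max       (M = 2.68, SD = 2.30, n = 36)
  t_0         (M = 2.53, SD = 0.68, n = 36)
  t_max       (M = 7.13, SD = 1.09, n = 36)
  t_half_max  (M = 2.48, SD = 0.49, n = 36)
  slope       (M = 0.36, SD = 0.30, n = 36)
  tr          (M = 0.35, SD = 0.03, n = 36)

Hypoperfusion detection (decreased or absent), per organ:
  severe: 3/3 organ

Paired t-test on mean Slope, baseline (M = 1.25, SD = 0.32) vs severe
(M = 0.36, SD = 0.09): t(2) = 6.73, P = 0.0214, n = 3 pairs
```

Each of the 36 pooled boluses (3 subjects × 6 injections × 2 ROIs) carries
its own metrics; under occlusion the mean wash-in slope collapses from
1.25 to 0.36 a.u./s and every subject's occluded condition is flagged. The
per-bolus metric table and machine-readable report are available as
`res.subjects[i].metrics` and `res.report`.

The same chain runs from the shell and from file artifacts (multi-frame
TIFF + JSON sidecar, curve/metric CSVs):

```
icgperf run-all --out-dir out/            # default 5-condition protocol
icgperf metrics --curve curve_central.csv --sidecar stack.tiff.json --out m.csv
```

The curves CSV (`time_s,intensity,roi_label`) is a first-class entry point,
so the analytics can be applied to curves exported from real recordings
without the imaging layer.

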