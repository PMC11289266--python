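# Methods

This note documents the generative model behind `icgperf.synthgen`, the
estimators in `bolus_metrics`/`detect_stats`, the calibration of their
defaults, and the numerical choices that a maintainer would otherwise have
to reverse-engineer from the code.

## 1. The monitoring problem

A high-frequency (1/min), low-dose (0.008 mg/kg) ICG bolus train produces an
oscillating fluorescence time–intensity curve in perfused tissue. Arterial
occlusion flattens or abolishes the oscillation. The pipeline quantifies
each bolus wave with six nonparametric metrics (`F_max`, `T_0`, `T_max`,
`T_1/2max`, `Slope = F_max/T_max`, `TR = T_1/2max/T_max`) and classifies each
experimental condition against the subject's own baseline.

Two definitional points are deliberate choices, since the quantities are
conventionally named but not always given formulas:

- **Slope** is the *mean* wash-in rate `F_max/T_max`, not the maximum
  pointwise derivative. The derivative definition amplifies sensor noise at
  any realistic frame rate; the ratio definition is scale-equivariant,
  robust, and produces values of the magnitude reported for this regimen
  (~1.4 a.u./s at baseline).
- **`T_1/2max`** is measured from the first-signal time (the same origin as
  `T_max`), which forces `0 < T_1/2max ≤ T_max` and hence `TR ∈ (0, 1]`.
  The half-rise search starts strictly *after* the first-signal sample:
  when `F_max < 2·k_detect·σ̂` the crossing sample itself can already
  exceed half of the peak rise, and the strict search keeps `T_1/2max`
  positive rather than producing a degenerate zero.

## 2. Generative model

### Per-bolus kinetics

Each bolus contributes a gamma-variate indicator-dilution wave

    f(t) = A · x^α · exp(α(1 − x)),   x = (t − t₀)/τ,   t > t₀,

zero during the transit delay `t₀`, peaking at exactly `A` at `t₀ + τ`.
Defaults: `α = 2` (a typical tissue transit-function shape), `τ ~ U(6, 10)` s,
`t₀ ~ U(1, 3)` s. The generator draws the *true slope* `S` first and sets
`A = S·τ`, so ground-truth `Slope = A/τ` holds exactly by construction.

### Slope calibration and its hierarchy

Condition-level per-bolus slope statistics (a.u./s) are calibrated to
reported porcine measurements under this regimen:

| condition | pooled mean | pooled SD |
| --- | --- | --- |
| baseline | 1.39 | 1.24 |
| mild (peripheral occlusion) | 0.7363 | 0.7130 |
| severe (central occlusion) | 0.39 | 0.41 |

The mild condition is the *geometric* midpoint of baseline and severe —
the natural interpolation for a positive, occlusion-scaled quantity; it is
an invented default (no pooled mild statistics are available to calibrate
against) and is exposed in `ConditionSpec`.

Slopes are gamma-distributed. A zero-truncated normal cannot represent
these calibrations: naive truncation shifts the baseline mean by +22 %, and
no truncated normal attains the severe condition's coefficient of variation
(0.41/0.39 > 1, while a zero-truncated normal's CV is strictly below 1).
The gamma family matches both stated moments exactly and is naturally
non-negative.

The pooled dispersion mixes animal-to-animal and bolus-to-bolus
variability. The generator splits it hierarchically:

    slope_ij = s_i · g_ij,
    s_i  ~ lognormal, mean 1, CV 0.4      (animal factor)
    g_ij ~ gamma, mean m_c, CV derived     (within-condition residual)

with the within-condition CV solved so the *pooled* mean/SD equal the
calibration exactly: `CV_w² = (1 + CV_pooled²)/(1 + CV_s²) − 1`. The split
matters: with all dispersion at the bolus level, a single subject's 6-bolus
condition mean would be far too noisy for the immediate per-subject
occlusion detection that motivates the method, and with all dispersion at
the animal level the bolus train would be implausibly rigid. A
between-animal CV of 0.4 keeps the subject-level paired comparison strongly
powered while leaving realistic bolus-to-bolus scatter. `within_cv_scale`
(default 1.0) scales the residual CV; the `ventricle_like_scenario` preset
uses 0.6 to model a single clean, well-primed organ, whose bolus train is
more repeatable than the heterogeneous multi-organ pool that produces the
pooled SD of 1.24.

### Balanced virtual cohorts

`run_cohort` builds study cohorts with a quasi-Monte Carlo design rather
than i.i.d. draws, so that a 12-animal virtual study is representative of
the population it samples:

- animal factors are drawn by jittered stratified inverse-CDF sampling
  (one quantile stratum per subject, seeded random order);
- within each condition, the `n` bolus slopes occupy `n` quantile blocks,
  and each block's sub-stratum rotates cyclically against the subject's
  animal-factor rank, so the cohort-wide pool covers every sub-stratum of
  the slope distribution exactly once and the pairing of animal effect with
  bolus quantiles is balanced rather than left to chance;
- jittered quantiles are clamped half a sub-stratum from both ends — the
  lognormal/gamma tails are unbounded, and an uncapped top stratum would
  occasionally inject an animal or bolus far outside any plausible cohort.

All marginal distributions are unchanged by this design; only the joint
sampling pattern is controlled. Standalone `ScenarioConfig` simulations
(no `cohort_seed`) use plain jittered stratified draws per condition.

### Accumulation ("visual saturation")

Repeated boluses leave residual dye that raises the organ's baseline
brightness after every injection — eventually defeating visual assessment.
The per-bolus accumulation *level* follows the saturating envelope
`C_inf·(1 − e^{−i/κ})` (defaults `C_inf = 30` a.u., `κ = 8` boluses;
`accumulation_offset` computes it in closed form). In the renderer, each
bolus's increment is

- scaled by the dye that bolus actually delivered (`min(1, A_i/A_ref)`,
  `A_ref` the nominal well-perfused amplitude): an occluded organ receives
  little dye and accumulates little — otherwise an undetectable bolus would
  still brighten the organ, which is physically wrong and would corrupt the
  slope calibration;
- accrued during the bolus's *washout* (a smoothstep ramp 20–45 s after
  injection), after the wave's peak and completing before the next
  pre-injection baseline window. An accumulation step inside the wash-in
  phase would add to `F_max` of that bolus and bias `Slope` upward by tens
  of percent; accruing it during washout leaves per-bolus metrics clean
  while the pre-injection baselines rise monotonically, which is the
  saturation phenomenon the model exists to reproduce.

### Scene, motion, distance, noise

The scene is a static smooth texture (Gaussian-filtered noise, mean 30,
SD 8, smoothing 3 px) on an enlarged canvas; the physiological signal
(bolus waves + accumulation) is spatially uniform and added to every pixel.
Motion is rigid: a respiratory sinusoid (default amplitude 4 px, period
4 s) plus a bounded peristaltic random walk (0.2 px/s, clamped at ±6 px),
quantized to whole pixels; `GroundTruth.displacement` records the applied
integer shift per frame (apparent tissue motion in image coordinates).
Camera distance scales all intensities by `(7.5/d)²` — exactly 1/4 at
15 cm — while sensor noise (i.i.d. Gaussian per pixel per frame, clipped at
zero) does not scale with distance. Intensities are floats on a nominal
0–255 scale with no top clip, so saturation remains an accumulation
phenomenon rather than a sensor artifact. Frame rate defaults to 5 Hz,
image size 128×128 px; neither is dictated by the protocol, which specifies
only bolus frequency, condition length and camera distances.

Random streams are keyed per purpose (background, motion, noise, subject,
per-condition kinetics) from a single seed, so adding conditions does not
perturb earlier draws and identical configurations are bit-identical.

## 3. Tracking and extraction

The tracker follows an ROI with exhaustive normalized cross-correlation
matching (integer-pixel, search radius 8 px by default) against the
*previous frame's* tracked patch. NCC is invariant to the global intensity
drift caused by accumulation; the previous-frame template tolerates slow
appearance change, at the cost of a drift risk that the tests bound. Ties
break toward the smallest displacement, then row-major order; a constant
template (undefined correlation) holds the previous center with score 0.
On noiseless scenes with the generator's integer motion, recovery is exact;
the contract tested is trajectory RMSE ≤ 0.5 px. No sub-pixel refinement,
deformable registration, or multi-ROI coupling is attempted.

Extraction is the arithmetic ROI mean per frame, hence exactly linear in
the pixel values when no clipping occurs.

## 4. Estimator behavior and known biases

The onset threshold (`F0 + 3σ̂` for 3 consecutive samples) necessarily
fires slightly *after* the true transit delay, shortening the measured
`T_max` and inflating `Slope` by roughly the fractional crossing point of
the wave. Under the high-SNR cohort preset (noise 0.25 a.u./px, 31×31 px
ROIs) this bias is ~2 % at baseline amplitudes and ~5 % for severe-occlusion
amplitudes; time-grid quantization at 5 Hz adds up to ~4 %. These are
properties of the estimator definition itself — any implementation that
measures `T_max` from a detectable-signal threshold shares them — and the
study-level checks budget for them.

Two second-order interactions are worth knowing:

- consecutive boluses leave a washout tail in the next window's
  pre-injection span; the MAD-based noise floor then reads slightly high
  even in noiseless data, delaying onset detection by a sample or two. The
  noiseless 5 %-recovery test therefore uses well-separated boluses (120 s
  spacing), where the bound is pure grid quantization;
- conditions recorded at 15 cm have 4× lower signal with unchanged sensor
  noise, so amplitude-based metrics (`F_max`, `Slope`) are not comparable
  across distances. Classification assumes matched distance; the default
  occlusion protocol's 15 cm segments exist to exercise the attenuation
  model, not the classifier.

`F0` handling of the recording's first bolus: with no pre-injection samples
the baseline falls back to the first 10 s of the window itself and the
segment is flagged — contaminated by the wash-in when the transit delay is
short. Cohort presets avoid this with a 15 s lead-in before the first
injection, mirroring the priming period before a real bolus train.

## 5. Classification thresholds

`theta_dec = 0.70` and `detect_frac_min = 0.5` were calibrated on the
synthetic protocol (design stage, before the test suite was frozen) such
that a mild-occlusion transition is flagged in essentially every clean
high-SNR subject (per-subject sensitivity 99.7 % in a 300-subject pilot,
3/3 subjects in 100/100 three-subject replicates) while a repeated baseline
is never flagged (0/300). Both are configurable; the slope ratio itself is
always reported so users can apply their own cutoff. Online (per-bolus)
and offline (condition-level) flagging use the same threshold; they agree
in the low-dispersion operating regime but are not mathematically
equivalent — with heavy bolus-to-bolus scatter, individual boluses of a
healthy baseline dip below 0.7× the mean roughly 45 % of the time, which is
why condition-level classification uses the condition *mean* and the online
flag is an early-warning signal rather than a diagnosis.

The paired t-test is subject-level (each animal contributes one baseline
and one occlusion mean slope) — the only defensible pairing unit when
conditions are recorded sequentially within animals. Two-sided p-values
throughout; no multiple-testing correction (a single pre-specified
comparison). Zero-variance differences are reported explicitly (t = 0,
p = 1 when the mean difference is also zero; otherwise p = 0 with a
degeneracy flag) instead of propagating NaNs.

## 6. Problem sizes and determinism

The study-level checks simulate 12 subjects × 2 conditions × 6 min at 5 Hz
and 128×128 px through the full imaging pipeline (~43k frames, ~1 min on
one CPU), plus a 3-subject mild-occlusion cohort. The 20-replicate
significance check runs in curve-space (`simulate_curves`), which shares
every kinetic and scheduling draw with the renderer and differs only by
ROI-averaged instead of per-pixel noise — rendering thousands of frames
adds nothing to a statistic of per-bolus slopes. Per-bolus measurement
bias agrees between the two paths to within 0.5 %.

Every output is a deterministic function of (configuration, seed): fixed
seeds give bit-identical frame stacks, tracks, metric CSVs and reports.

## 7. What the synthetic validation does and does not show

Passing tests demonstrate that the estimators recover known kinetics under
motion, noise, accumulation and distance changes, and that the study-level
statistics are reproduced when the generator is calibrated to the reported
slope distributions. They do not validate the generator against real
laparoscopic video: tissue deformation (the model's motion is rigid),
spatially heterogeneous perfusion within an ROI, illumination
inhomogeneity, specular highlights, and organ-specific priming failures
(the under-primed spleen case) are all outside the model. The curves-CSV
entry point exists precisely so the analytic layers can be applied to real
exported data without the imaging model.
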