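"""Synthetic laparoscopic NIR fluorescence recordings with known ground truth.

The generator emulates a continuous perfusion-monitoring experiment: a train
of low-dose indocyanine-green (ICG) boluses, one per minute, each producing a
transient wash-in/wash-out wave in the organ's fluorescence.  Per-bolus
kinetics follow the classical gamma-variate indicator-dilution shape.  On top
of the oscillation the model renders

* progressive dye accumulation ("visual saturation") — each bolus leaves a
  residual that raises the organ's baseline brightness,
* rigid tissue motion (respiratory sinusoid plus a slow peristaltic drift),
* inverse-square intensity attenuation with camera distance (7.5 vs 15 cm),
* per-pixel Gaussian sensor noise, clipped at zero.

Everything the downstream pipeline estimates (per-bolus Slope, F_max, onset
times, the motion trajectory, condition labels) is available as ground truth,
so the analysis modules can be tested against a generator-side oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import ndimage, stats

__all__ = [
    "BolusKinetics",
    "ConditionSpec",
    "ScenarioConfig",
    "Schedule",
    "GroundTruth",
    "FrameStack",
    "SLOPE_CALIBRATION",
    "bolus_response",
    "accumulation_offset",
    "make_experiment_schedule",
    "draw_ground_truth",
    "render_frames",
    "simulate_recording",
    "simulate_curves",
    "oracle_signal",
    "stratified_subject_factors",
    "default_protocol",
    "high_snr_scenario",
    "ventricle_like_scenario",
]

# Reference per-bolus Slope statistics (a.u./s) used as condition defaults:
# a well-perfused organ under the 1/min low-dose regimen, complete central
# arterial occlusion, and a mild (peripheral) occlusion placed at the
# geometric midpoint of the two — the midpoint on the ratio scale, which is
# the natural interpolation for a positive, occlusion-scaled quantity.
SLOPE_CALIBRATION: dict[str, tuple[float, float]] = {
    "baseline": (1.39, 1.24),
    "mild": (0.7363, 0.7130),
    "severe": (0.39, 0.41),
}

_REFERENCE_DISTANCE_CM = 7.5

# Sub-stream identifiers for the per-purpose RNG streams (kept stable so that
# adding conditions or frames never perturbs draws made by earlier streams).
_STREAM_BACKGROUND = 1
_STREAM_MOTION = 2
_STREAM_NOISE = 3
_STREAM_SUBJECT = 4
_STREAM_KINETICS = 10  # + condition index


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BolusKinetics:
    """Gamma-variate kinetic parameters for a single bolus.

    The fluorescence response ``t`` seconds after injection is
    ``A * x**alpha * exp(alpha*(1-x))`` with ``x = (t - onset)/tau`` for
    ``t > onset`` and 0 otherwise: zero during the transit delay, a single
    peak of exactly ``amplitude`` at ``onset + tau``, then washout.
    """

    amplitude: float  # A, a.u. — peak rise above the local baseline
    onset: float  # t0, s — transit delay from injection to first signal
    tau: float  # s — time from onset to peak
    alpha: float  # dimensionless shape exponent (> 0)

    def __post_init__(self) -> None:
        if not (self.amplitude >= 0 and self.onset >= 0):
            raise ValueError("amplitude and onset must be non-negative")
        if not (self.tau > 0 and self.alpha > 0):
            raise ValueError("tau and alpha must be positive")

    @property
    def slope(self) -> float:
        """Mean wash-in slope A/tau (a.u./s), the generator's true Slope."""
        return self.amplitude / self.tau


class ConditionSpec(BaseModel):
    """One experimental condition: a perfusion state at a camera distance."""

    model_config = ConfigDict(extra="forbid")

    label: Literal["baseline", "mild", "severe"] = "baseline"
    camera_distance_cm: float = 7.5
    slope_mean: float | None = None  # a.u./s; None -> SLOPE_CALIBRATION[label]
    slope_sd: float | None = None
    perfusion_level: float = Field(default=1.0, ge=0.0, le=1.0)
    name: str | None = None  # unique key; auto-derived when omitted

    @model_validator(mode="after")
    def _check(self) -> "ConditionSpec":
        if self.camera_distance_cm not in (7.5, 15.0):
            raise ValueError("camera_distance_cm must be 7.5 or 15")
        if self.slope_mean is None:
            object.__setattr__(self, "slope_mean", SLOPE_CALIBRATION[self.label][0])
        if self.slope_sd is None:
            object.__setattr__(self, "slope_sd", SLOPE_CALIBRATION[self.label][1])
        if self.slope_mean < 0 or self.slope_sd < 0:
            raise ValueError("slope_mean and slope_sd must be non-negative")
        return self


def _default_conditions() -> list[ConditionSpec]:
    return [ConditionSpec(label="baseline", camera_distance_cm=7.5)]


class ScenarioConfig(BaseModel):
    """Full description of one synthetic recording (one subject)."""

    model_config = ConfigDict(extra="forbid")

    conditions: list[ConditionSpec] = Field(default_factory=_default_conditions)
    bolus_period: float = Field(default=60.0, gt=0)  # s between injections
    condition_duration: float = Field(default=360.0, gt=0)  # s per condition
    lead_in: float = Field(default=0.0, ge=0)  # s of recording before bolus 1

    # hierarchy of slope variability: pooled (mean, sd) per condition is split
    # into a multiplicative per-subject factor (lognormal, mean 1, CV
    # subject_cv) and within-condition gamma residuals.
    subject_cv: float = Field(default=0.4, ge=0)
    subject_factor: float | None = Field(default=None, gt=0)  # explicit override
    # scales the derived within-condition CV: 1.0 reproduces the pooled
    # calibration across a heterogeneous multi-organ cohort; <1 models a
    # single clean, well-primed organ whose bolus train is more repeatable
    within_cv_scale: float = Field(default=1.0, ge=0, le=1)

    # balanced-cohort context: when cohort_seed is set, per-bolus slope
    # quantiles are allocated in a randomized block design shared across the
    # cohort (each subject draws one jittered quantile per block, every
    # cohort-wide stratum covered exactly once), so a small virtual cohort is
    # representative at both the subject and the cohort level
    cohort_seed: int | None = None
    cohort_index: int = Field(default=0, ge=0)
    cohort_size: int = Field(default=1, ge=1)

    # kinetic nuisance parameters, drawn per bolus
    tau_range: tuple[float, float] = (6.0, 10.0)  # s, onset -> peak
    onset_range: tuple[float, float] = (1.0, 3.0)  # s, transit delay
    alpha: float = Field(default=2.0, gt=0)

    # dye accumulation: saturating envelope C_inf*(1-exp(-i/kappa)) over bolus
    # index i, accrued during each bolus's washout in proportion to the dye
    # that bolus actually delivered.
    accumulation_c_inf: float = Field(default=30.0, ge=0)  # a.u.
    accumulation_kappa: float = Field(default=8.0, gt=0)  # boluses
    accumulation_ramp: tuple[float, float] = (20.0, 45.0)  # s post-injection

    # rigid motion: respiratory sinusoid + bounded peristaltic random walk
    motion_amplitude_px: float = Field(default=4.0, ge=0)
    motion_period_s: float = Field(default=4.0, gt=0)
    drift_rate_px_s: float = Field(default=0.2, ge=0)
    drift_max_px: float = Field(default=6.0, ge=0)

    noise_sd: float = Field(default=2.0, ge=0)  # a.u. per pixel per frame
    frame_rate: float = Field(default=5.0, gt=0)  # Hz
    image_size: tuple[int, int] = (128, 128)  # rows, cols

    background_mean: float = Field(default=30.0, ge=0)  # a.u.
    background_texture_sd: float = Field(default=8.0, ge=0)
    background_smooth_px: float = Field(default=3.0, gt=0)

    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if not self.conditions:
            raise ValueError("at least one condition is required")
        n = self.condition_duration / self.bolus_period
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "condition_duration must be an integer multiple of bolus_period"
            )
        if self.tau_range[0] > self.tau_range[1] or self.tau_range[0] <= 0:
            raise ValueError("invalid tau_range")
        if self.onset_range[0] > self.onset_range[1] or self.onset_range[0] < 0:
            raise ValueError("invalid onset_range")
        margin = self._canvas_margin()
        if min(self.image_size) <= 2 * margin + 8:
            raise ValueError("image too small for the configured motion amplitude")
        # assign unique condition names (labels may repeat across distances)
        names: list[str] = []
        for c in self.conditions:
            name = c.name or c.label
            if name in names:
                name = f"{c.label}@{c.camera_distance_cm:g}cm"
            k = 2
            while name in names:
                name = f"{c.label}@{c.camera_distance_cm:g}cm#{k}"
                k += 1
            object.__setattr__(c, "name", name)
            names.append(name)
        return self

    def _canvas_margin(self) -> int:
        return int(math.ceil(self.motion_amplitude_px + self.drift_max_px)) + 1

    @property
    def boluses_per_condition(self) -> int:
        return int(round(self.condition_duration / self.bolus_period))

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.condition_duration * len(self.conditions)


@dataclass(frozen=True)
class Schedule:
    """Ordered condition/injection plan, all times in s from recording start."""

    injection_times: np.ndarray  # (n_inj,)
    injection_condition: list[str]  # condition name per injection
    condition_names: list[str]
    condition_labels: list[str]
    condition_starts: np.ndarray  # (n_cond,)
    condition_distances_cm: np.ndarray  # (n_cond,)
    condition_duration: float
    bolus_period: float
    lead_in: float
    total_duration: float

    @property
    def n_injections(self) -> int:
        return len(self.injection_times)

    def condition_index_at(self, t: np.ndarray) -> np.ndarray:
        """Index of the active condition at each time (lead-in -> condition 0)."""
        t = np.asarray(t, dtype=float)
        idx = np.floor((t - self.lead_in) / self.condition_duration).astype(int)
        return np.clip(idx, 0, len(self.condition_names) - 1)

    def distance_factor_at(self, t: np.ndarray) -> np.ndarray:
        """Inverse-square intensity factor relative to the 7.5 cm reference."""
        d = self.condition_distances_cm[self.condition_index_at(t)]
        return (_REFERENCE_DISTANCE_CM / d) ** 2


@dataclass
class GroundTruth:
    """Generator-side truth for oracle tests and parameter-recovery checks."""

    schedule: Schedule
    kinetics: list[BolusKinetics]  # one per injection
    subject_factor: float
    accumulation_increments: np.ndarray  # (n_inj,) residual left by each bolus
    displacement: np.ndarray  # (n_frames, 2) int (dy, dx): apparent tissue
    # shift in image coordinates — a tracked ROI moves by exactly this
    background_canvas: np.ndarray  # (H+2M, W+2M) static scene, 7.5 cm scale
    canvas_margin: int

    @property
    def true_slopes(self) -> np.ndarray:
        return np.array([k.slope for k in self.kinetics])

    def slopes_for(self, condition_name: str) -> np.ndarray:
        sel = [
            k.slope
            for k, c in zip(self.kinetics, self.schedule.injection_condition)
            if c == condition_name
        ]
        return np.array(sel)


@dataclass
class FrameStack:
    """Time-ordered single-channel fluorescence image sequence."""

    frames: np.ndarray  # (T, H, W) float32, >= 0, nominally 0-255 a.u.
    timestamps: np.ndarray  # (T,) s, strictly increasing, uniform
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("timestamps length must equal frame count")
        dt = np.diff(self.timestamps)
        if len(dt) and (dt <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if len(dt) and np.abs(dt - 1.0 / self.frame_rate).max() > 1e-9:
            raise ValueError("timestamps must be uniformly spaced at frame_rate")
        if np.min(self.frames) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


# ---------------------------------------------------------------------------
# kinetic primitives
# ---------------------------------------------------------------------------


def bolus_response(t: np.ndarray | float, k: BolusKinetics) -> np.ndarray | float:
    """Gamma-variate fluorescence response ``t`` seconds after injection.

    Returns ``A * x**alpha * exp(alpha*(1-x))`` with ``x=(t-onset)/tau`` for
    ``t > onset`` and 0 otherwise.  Continuous in ``t`` with a single maximum
    of exactly ``A`` at ``t = onset + tau``.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.isfinite(t_arr).all():
        raise ValueError("bolus_response: t must be finite")
    x = (t_arr - k.onset) / k.tau
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = k.amplitude * np.power(xp, k.alpha) * np.exp(k.alpha * (1.0 - xp))
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out) if out.ndim == 0 else float(out[()])
    return out


def accumulation_offset(bolus_index: int, c_inf: float, kappa: float) -> float:
    """Saturating dye-accumulation level after ``bolus_index`` boluses.

    ``C_inf * (1 - exp(-i/kappa))``: non-decreasing in the 1-based index and
    bounded by ``C_inf`` — the brightness plateau once wash-out and residual
    binding balance.
    """
    if bolus_index < 1:
        raise ValueError("bolus_index is 1-based and must be >= 1")
    if c_inf < 0 or kappa <= 0:
        raise ValueError("require c_inf >= 0 and kappa > 0")
    return c_inf * (1.0 - math.exp(-bolus_index / kappa))


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# schedule and ground truth
# ---------------------------------------------------------------------------


def make_experiment_schedule(config: ScenarioConfig) -> Schedule:
    """Expand a ScenarioConfig into the ordered condition/injection plan.

    Conditions run back to back, each ``condition_duration`` long with one
    injection every ``bolus_period`` starting at the condition start (shifted
    by ``lead_in`` seconds of injection-free recording at the head).
    """
    n_b = config.boluses_per_condition
    starts = config.lead_in + config.condition_duration * np.arange(
        len(config.conditions), dtype=float
    )
    inj: list[float] = []
    inj_cond: list[str] = []
    for c, s in zip(config.conditions, starts):
        for j in range(n_b):
            inj.append(s + j * config.bolus_period)
            inj_cond.append(c.name)  # type: ignore[arg-type]
    return Schedule(
        injection_times=np.array(inj),
        injection_condition=inj_cond,
        condition_names=[c.name for c in config.conditions],  # type: ignore[misc]
        condition_labels=[c.label for c in config.conditions],
        condition_starts=starts,
        condition_distances_cm=np.array(
            [c.camera_distance_cm for c in config.conditions]
        ),
        condition_duration=config.condition_duration,
        bolus_period=config.bolus_period,
        lead_in=config.lead_in,
        total_duration=config.total_duration,
    )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def stratified_subject_factors(n: int, cv: float, seed: int) -> np.ndarray:
    """Lognormal (mean 1, given CV) subject factors via jittered stratification.

    Each of the ``n`` subjects receives one quantile stratum of the factor
    distribution (in seeded random order, jittered within the stratum), so a
    small virtual cohort is representative of the animal-to-animal spread
    while the marginal distribution is unchanged.
    """
    if cv == 0:
        return np.ones(n)
    rng = _rng(seed, 900)
    u = (rng.permutation(n) + rng.uniform(size=n)) / n
    # half-stratum clamp: the lognormal tail is unbounded and a jittered top
    # stratum would occasionally produce an animal far outside any plausible
    # cohort
    u = np.clip(u, 0.5 / n, 1.0 - 0.5 / n)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return stats.lognorm.ppf(u, s=sigma, scale=math.exp(-sigma2 / 2.0))


def _within_condition_cv(pooled_cv: float, subject_cv: float) -> float:
    """Residual CV so that subject x residual has the target pooled CV."""
    v = (1.0 + pooled_cv**2) / (1.0 + subject_cv**2) - 1.0
    if v < -1e-12:
        raise ValueError(
            "subject_cv exceeds the pooled slope CV of a condition; "
            "lower subject_cv or raise the condition's slope_sd"
        )
    return math.sqrt(max(v, 0.0))


def _draw_condition_slopes(
    config: ScenarioConfig, cond: ConditionSpec, cond_idx: int
) -> np.ndarray:
    """Within-subject per-bolus slope residuals for one condition.

    Gamma-distributed with mean ``slope_mean * perfusion_level`` and the
    within-subject CV implied by the pooled calibration, drawn by jittered
    stratified inverse-CDF sampling so each bolus train is representative.
    In balanced-cohort mode (``cohort_seed`` set) each stratum's jittered
    quantile is offset by the subject's design rank, rotated evenly from
    stratum to stratum, so the cohort-wide pool covers every sub-stratum
    exactly once, each subject still spans the distribution, and the pairing
    of animal effect with bolus quantiles is balanced rather than left to
    chance — a quasi-Monte Carlo cohort construction.
    """
    n_b = config.boluses_per_condition
    mean = cond.slope_mean * cond.perfusion_level  # type: ignore[operator]
    if mean <= 0:
        return np.zeros(n_b)
    pooled_cv = cond.slope_sd / cond.slope_mean  # type: ignore[operator]
    cv = _within_condition_cv(pooled_cv, config.subject_cv) * config.within_cv_scale
    if cv == 0:
        return np.full(n_b, mean)
    rng = _rng(config.seed, _STREAM_KINETICS, cond_idx)
    jitter = rng.uniform(size=n_b)
    if config.cohort_seed is not None and config.cohort_size > 1:
        m = config.cohort_size
        blocks = np.arange(n_b)
        shifts = np.round(blocks * m / n_b).astype(int)
        ranks = (config.cohort_index + shifts) % m
        u = (blocks + (ranks + jitter) / m) / n_b
    else:
        u = (np.arange(n_b) + jitter) / n_b
    # keep draws half a sub-stratum away from the ends: the gamma tail is
    # unbounded and an uncapped top-stratum jitter would occasionally inject
    # extreme slopes no finite animal cohort exhibits
    m_eff = config.cohort_size if config.cohort_seed is not None else 1
    half = 0.5 / (n_b * m_eff)
    u = np.clip(u, half, 1.0 - half)
    u = u[rng.permutation(n_b)]
    shape = 1.0 / (cv * cv)
    scale = mean * cv * cv
    return stats.gamma.ppf(u, a=shape, scale=scale)


def draw_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Draw all latent variables of a recording (kinetics, motion, scene)."""
    schedule = make_experiment_schedule(config)
    seed = config.seed
    n_b = config.boluses_per_condition

    # subject factor: explicit override (cohort stratification) or own draw
    if config.subject_factor is not None:
        s_fac = float(config.subject_factor)
    elif config.subject_cv == 0:
        s_fac = 1.0
    else:
        sigma2 = math.log(1.0 + config.subject_cv**2)
        z = _rng(seed, _STREAM_SUBJECT).standard_normal()
        s_fac = math.exp(-sigma2 / 2.0 + math.sqrt(sigma2) * z)

    kinetics: list[BolusKinetics] = []
    for ci, cond in enumerate(config.conditions):
        slopes = s_fac * _draw_condition_slopes(config, cond, ci)
        rng_n = _rng(seed, _STREAM_KINETICS, ci, 1)  # nuisance draws
        taus = rng_n.uniform(*config.tau_range, size=n_b)
        onsets = rng_n.uniform(*config.onset_range, size=n_b)
        for j in range(n_b):
            kinetics.append(
                BolusKinetics(
                    amplitude=float(slopes[j] * taus[j]),
                    onset=float(onsets[j]),
                    tau=float(taus[j]),
                    alpha=config.alpha,
                )
            )

    # accumulation: envelope increments scaled by delivered dye (relative to
    # the amplitude a nominal well-perfused bolus would deliver)
    n_inj = schedule.n_injections
    a_ref = s_fac * config.conditions[0].slope_mean * float(np.mean(config.tau_range))  # type: ignore[operator]
    inc = np.zeros(n_inj)
    if config.accumulation_c_inf > 0 and n_inj:
        env = config.accumulation_c_inf * (
            1.0 - np.exp(-np.arange(n_inj + 1) / config.accumulation_kappa)
        )
        steps = np.diff(env)
        if a_ref > 0:
            deliver = np.minimum(
                1.0, np.array([k.amplitude for k in kinetics]) / a_ref
            )
        else:
            deliver = np.zeros(n_inj)
        inc = steps * deliver

    # motion trajectory, quantized to whole pixels (what the renderer applies)
    n_frames = int(round(config.total_duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate
    rng_m = _rng(seed, _STREAM_MOTION)
    phase = rng_m.uniform(0, 2 * np.pi, size=2)
    resp = config.motion_amplitude_px * np.stack(
        [
            np.sin(2 * np.pi * t / config.motion_period_s + phase[0]),
            np.sin(2 * np.pi * t / config.motion_period_s + phase[1]),
        ],
        axis=1,
    )
    if config.drift_rate_px_s > 0 and n_frames > 1:
        dt = 1.0 / config.frame_rate
        steps2 = rng_m.normal(
            0.0, config.drift_rate_px_s * math.sqrt(dt), size=(n_frames, 2)
        )
        steps2[0] = 0.0
        drift = np.clip(
            np.cumsum(steps2, axis=0), -config.drift_max_px, config.drift_max_px
        )
    else:
        drift = np.zeros((n_frames, 2))
    disp = np.rint(resp + drift).astype(int)

    # static background scene on an enlarged canvas (7.5 cm intensity scale)
    margin = config._canvas_margin()
    h, w = config.image_size
    rng_b = _rng(seed, _STREAM_BACKGROUND)
    field = rng_b.standard_normal((h + 2 * margin, w + 2 * margin))
    field = ndimage.gaussian_filter(field, config.background_smooth_px)
    sd = field.std()
    if sd > 0:
        field /= sd
    canvas = np.clip(
        config.background_mean + config.background_texture_sd * field, 1.0, None
    )

    return GroundTruth(
        schedule=schedule,
        kinetics=kinetics,
        subject_factor=s_fac,
        accumulation_increments=inc,
        displacement=disp,
        background_canvas=canvas,
        canvas_margin=margin,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def oracle_signal(gt: GroundTruth, config: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    """Spatially uniform physiological signal (bolus waves + accumulation).

    This is the noise-free rise above the static background at the 7.5 cm
    reference scale; the renderer adds it to every pixel before distance
    scaling.  Exposed so tests can build oracle curves from ground truth.
    """
    t = np.asarray(t, dtype=float)
    sig = np.zeros_like(t)
    r0, r1 = config.accumulation_ramp
    for inj, k, dc in zip(
        gt.schedule.injection_times, gt.kinetics, gt.accumulation_increments
    ):
        rel = t - inj
        sig += bolus_response(rel, k)
        if dc > 0:
            sig += dc * _smoothstep((rel - r0) / (r1 - r0))
    return sig


def render_frames(gt: GroundTruth, config: ScenarioConfig) -> FrameStack:
    """Render a FrameStack from drawn ground truth (deterministic per seed)."""
    n_frames = len(gt.displacement)
    t = np.arange(n_frames) / config.frame_rate
    sig = oracle_signal(gt, config, t)
    fac = gt.schedule.distance_factor_at(t)
    h, w = config.image_size
    m = gt.canvas_margin
    rng_noise = _rng(config.seed, _STREAM_NOISE)
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    for i in range(n_frames):
        # tissue shifted by +d in image coords = crop the canvas at -d
        dy, dx = -gt.displacement[i]
        view = gt.background_canvas[m + dy : m + dy + h, m + dx : m + dx + w]
        f = (view + sig[i]) * fac[i]
        if config.noise_sd > 0:
            f = f + config.noise_sd * rng_noise.standard_normal((h, w))
        frames[i] = np.clip(f, 0.0, None)
    return FrameStack(frames=frames, timestamps=t, frame_rate=config.frame_rate)


def simulate_recording(config: ScenarioConfig) -> tuple[FrameStack, GroundTruth]:
    """Draw ground truth and render the full synthetic recording."""
    gt = draw_ground_truth(config)
    return render_frames(gt, config), gt


def simulate_curves(
    config: ScenarioConfig,
    roi_pixels: int = 961,
    labels: Sequence[str] = ("central", "peripheral"),
) -> tuple[dict[str, "np.ndarray"], GroundTruth]:
    """Fast curve-level simulation bypassing the imaging layer.

    Produces the ROI-mean time-intensity curves a perfect tracker would
    extract: background mean + physiological signal, distance-scaled, with
    ROI-averaged sensor noise (sd ``noise_sd/sqrt(roi_pixels)``).  Returns
    ``{label: (time, intensity) arrays packed as TimeIntensityCurve)}`` via
    the track_extract container.  Used for statistical replications where
    rendering thousands of frames would add nothing.
    """
    from .track_extract import TimeIntensityCurve

    gt = draw_ground_truth(config)
    n_frames = int(round(config.total_duration * config.frame_rate))
    t = np.arange(n_frames) / config.frame_rate
    sig = oracle_signal(gt, config, t)
    fac = gt.schedule.distance_factor_at(t)
    base = (config.background_mean + sig) * fac
    rng_noise = _rng(config.seed, _STREAM_NOISE, 7)
    sd = config.noise_sd / math.sqrt(roi_pixels)
    curves: dict[str, TimeIntensityCurve] = {}
    for li, lab in enumerate(labels):
        noise = sd * rng_noise.standard_normal(n_frames) if sd > 0 else 0.0
        curves[lab] = TimeIntensityCurve(
            time=t.copy(),
            intensity=np.clip(base + noise, 0.0, None),
            roi_label=lab,
        )
    return curves, gt


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def default_protocol(**overrides) -> ScenarioConfig:
    """The standard occlusion protocol: baseline at 7.5 cm, then mild and
    severe hypoperfusion each recorded at 7.5 and 15 cm, 6 min per condition,
    one bolus per minute (5 conditions, 30 injections)."""
    conditions = [
        ConditionSpec(label="baseline", camera_distance_cm=7.5),
        ConditionSpec(label="mild", camera_distance_cm=7.5),
        ConditionSpec(label="mild", camera_distance_cm=15.0),
        ConditionSpec(label="severe", camera_distance_cm=7.5),
        ConditionSpec(label="severe", camera_distance_cm=15.0),
    ]
    return ScenarioConfig(conditions=conditions, **overrides)


def high_snr_scenario(
    labels: Sequence[str] = ("baseline", "severe"),
    seed: int = 0,
    subject_factor: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """High-SNR single-distance scenario used for cohort studies.

    Low sensor noise (0.25 a.u./px) and a 15 s lead-in before the first
    injection, so per-bolus onset detection is near-certain and the first
    bolus has a clean pre-injection baseline.
    """
    conditions = [ConditionSpec(label=lab, camera_distance_cm=7.5) for lab in labels]
    kwargs = dict(
        conditions=conditions,
        noise_sd=0.25,
        lead_in=15.0,
        seed=seed,
        subject_factor=subject_factor,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def ventricle_like_scenario(
    labels: Sequence[str] = ("baseline", "mild"),
    seed: int = 0,
    subject_factor: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """A clean, well-primed single organ (gastric ventricle wall): high SNR
    and a more repeatable bolus train (within-subject CV scaled to 0.6 of the
    heterogeneous multi-organ calibration)."""
    overrides.setdefault("within_cv_scale", 0.6)
    return high_snr_scenario(
        labels=labels, seed=seed, subject_factor=subject_factor, **overrides
    )
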