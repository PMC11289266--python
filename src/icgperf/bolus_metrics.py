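"""Per-bolus segmentation of time-intensity curves and perfusion metrics.

Each injection opens a half-open window ``[t_inj, t_inj + period)``.  Within
a window the six standard ICG wash-in metrics are computed non-parametrically
from the samples:

* ``F_max`` — peak fluorescence rise above the local pre-injection baseline,
* ``T_0`` — injection to first detectable signal,
* ``T_max`` — first detectable signal to peak,
* ``T_half_max`` — first detectable signal to 50% of the peak rise,
* ``Slope`` — mean wash-in rate, defined here as ``F_max / T_max``,
* ``TR`` — the dimensionless time ratio ``T_half_max / T_max``.

The local baseline ``F0`` (median of the pre-injection window) absorbs the
slow brightness drift caused by dye accumulation, so no global detrending is
applied.  Onset detection is a noise-floor crossing: the robust noise SD of
the pre-injection span (1.4826 x MAD) sets a threshold ``F0 + k_detect*sd``
that must be exceeded by ``m_consec`` consecutive samples.  A bolus with no
crossing — a flat-lined curve under severe hypoperfusion — is reported as
*not detected* with all metrics undefined (NaN), never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .track_extract import TimeIntensityCurve

__all__ = [
    "BolusSegment",
    "BolusMetrics",
    "ConditionSummary",
    "METRIC_NAMES",
    "segment_boluses",
    "compute_metrics",
    "condition_summary",
]

METRIC_NAMES = ("f_max", "t_0", "t_max", "t_half_max", "slope", "tr")


@dataclass
class BolusSegment:
    """Samples of one injection window plus its local baseline estimate."""

    injection_time: float
    time: np.ndarray
    intensity: np.ndarray
    f0: float  # local baseline, a.u.
    noise_sd_hat: float  # robust noise SD of the pre-injection span
    index: int = 0  # 1-based bolus index within the recording
    condition: str | None = None
    roi_label: str = "other"
    baseline_from_window: bool = False  # True when no pre-injection span existed

    def __post_init__(self) -> None:
        if len(self.time) != len(self.intensity):
            raise ValueError("time and intensity must have equal length")
        if len(self.time) > 1 and (np.diff(self.time) <= 0).any():
            raise ValueError("segment timestamps must be strictly increasing")
        if not np.isfinite(self.f0):
            raise ValueError("F0 must be finite")
        if self.noise_sd_hat < 0:
            raise ValueError("noise_sd_hat must be non-negative")


@dataclass
class BolusMetrics:
    """The six per-bolus perfusion metrics; NaN-valued when not detected."""

    detected: bool
    f_max: float = float("nan")
    t_0: float = float("nan")
    t_max: float = float("nan")
    t_half_max: float = float("nan")
    slope: float = float("nan")
    tr: float = float("nan")
    index: int = 0
    condition: str | None = None
    roi_label: str = "other"

    def value(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class ConditionSummary:
    """Mean/SD/n of each metric over the detected boluses of one condition."""

    label: str
    n_expected: int
    n_detected: int
    mean: dict[str, float] = field(default_factory=dict)  # NaN when n_detected=0
    sd: dict[str, float] = field(default_factory=dict)  # NaN when n_detected<2

    @property
    def detected_fraction(self) -> float:
        return self.n_detected / self.n_expected if self.n_expected else 0.0

    @property
    def slope_mean(self) -> float:
        return self.mean.get("slope", float("nan"))


def segment_boluses(
    curve: TimeIntensityCurve,
    injection_times: np.ndarray,
    period: float,
    pre_window: float = 10.0,
    conditions: list[str] | None = None,
) -> list[BolusSegment]:
    """Split a curve into per-injection half-open windows with local baselines.

    ``F0`` is the median intensity over the ``pre_window`` seconds before the
    injection (clipped to the available samples) and ``noise_sd_hat`` the
    matching robust SD.  The first bolus of a recording that has no
    pre-injection samples falls back to the first ``pre_window`` seconds of
    its own window and is flagged ``baseline_from_window``.
    """
    inj = np.asarray(injection_times, dtype=float)
    if len(inj) == 0:
        return []
    if (np.diff(inj) <= 0).any():
        raise ValueError("injection times must be sorted and distinct")
    t, y = curve.time, curve.intensity
    if inj[0] < t[0] - 1e-9 or inj[-1] > t[-1] + 1e-9:
        raise ValueError("injection times must lie within the curve time span")
    if conditions is not None and len(conditions) != len(inj):
        raise ValueError("conditions must align with injection_times")

    segments: list[BolusSegment] = []
    for i, ti in enumerate(inj):
        in_win = (t >= ti) & (t < ti + period)
        pre = (t >= ti - pre_window) & (t < ti)
        flagged = False
        if not pre.any():
            pre = (t >= ti) & (t < ti + pre_window)
            flagged = True
        ref = y[pre]
        f0 = float(np.median(ref))
        sd_hat = float(1.4826 * np.median(np.abs(ref - f0)))
        segments.append(
            BolusSegment(
                injection_time=float(ti),
                time=t[in_win],
                intensity=y[in_win],
                f0=f0,
                noise_sd_hat=sd_hat,
                index=i + 1,
                condition=None if conditions is None else conditions[i],
                roi_label=curve.roi_label,
                baseline_from_window=flagged,
            )
        )
    return segments


def compute_metrics(
    seg: BolusSegment,
    k_detect: float = 3.0,
    m_consec: int = 3,
    eps_abs: float = 1e-6,
) -> BolusMetrics:
    """Compute the six wash-in metrics for one bolus window.

    The first-signal time is the first sample after the injection whose
    intensity exceeds ``F0 + k_detect*noise_sd_hat`` (or ``F0 + eps_abs``
    for a noise-free segment) for ``m_consec`` consecutive samples.  The
    half-rise sample is searched strictly after the first-signal sample so
    ``T_half_max`` is always positive for a detected bolus.  No crossing, or
    a peak coincident with the first signal (``T_max = 0``), means the bolus
    is not detected and every metric is NaN.
    """
    if len(seg.time) < max(m_consec, 1):
        return _undetected(seg)
    t, y = seg.time, seg.intensity
    thr = seg.f0 + (k_detect * seg.noise_sd_hat if seg.noise_sd_hat > 0 else eps_abs)

    after = t > seg.injection_time
    above = (y > thr) & after
    first = _first_run(above, m_consec)
    if first is None:
        return _undetected(seg)
    t_first = t[first]

    peak_idx = int(np.argmax(y))  # first maximum on ties
    if peak_idx <= first:
        # Peak not after the onset: no resolvable wash-in.
        return _undetected(seg)
    f_max = float(y[peak_idx] - seg.f0)
    t_max = float(t[peak_idx] - t_first)

    half = seg.f0 + f_max / 2.0
    half_idx = None
    for j in range(first + 1, len(y)):
        if y[j] >= half:
            half_idx = j
            break
    if half_idx is None:  # cannot happen for f_max > 0, defensive
        return _undetected(seg)
    t_half = float(t[half_idx] - t_first)

    return BolusMetrics(
        detected=True,
        f_max=f_max,
        t_0=float(t_first - seg.injection_time),
        t_max=t_max,
        t_half_max=t_half,
        slope=f_max / t_max,
        tr=t_half / t_max,
        index=seg.index,
        condition=seg.condition,
        roi_label=seg.roi_label,
    )


def _first_run(mask: np.ndarray, m: int) -> int | None:
    """Index of the first element opening a run of >= m consecutive True."""
    if m <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if len(idx) else None
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= m:
            return i - m + 1
    return None


def _undetected(seg: BolusSegment) -> BolusMetrics:
    return BolusMetrics(
        detected=False,
        index=seg.index,
        condition=seg.condition,
        roi_label=seg.roi_label,
    )


def condition_summary(metrics: list[BolusMetrics], label: str) -> ConditionSummary:
    """Mean and sample SD (n-1) of each metric over detected boluses only.

    Zero detected boluses yields NaN means (a flat-lined condition is a
    legitimate result, not an exception); SDs are NaN unless >= 2 detected.
    """
    if not metrics:
        raise ValueError("metrics list must be non-empty")
    det = [m for m in metrics if m.detected]
    out = ConditionSummary(
        label=label, n_expected=len(metrics), n_detected=len(det)
    )
    for name in METRIC_NAMES:
        vals = np.array([m.value(name) for m in det], dtype=float)
        out.mean[name] = float(np.mean(vals)) if len(vals) else float("nan")
        out.sd[name] = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return out
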