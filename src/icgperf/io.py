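"""File formats: multi-frame TIFF stacks with JSON sidecars, CSV curves and
tracks, CSV per-bolus metric tables, JSON summaries and reports.

The curves CSV (``time_s, intensity, roi_label``) is the stable interchange
format: the analytics run unchanged on curves exported from real recordings,
without the imaging layer.  All round trips are lossless to float precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .bolus_metrics import BolusMetrics
from .synthgen import FrameStack, Schedule
from .track_extract import ROITrack, TimeIntensityCurve

__all__ = [
    "write_stack",
    "read_stack",
    "write_curve",
    "read_curve",
    "write_track",
    "read_track",
    "write_metrics",
    "read_metrics",
    "write_json",
    "read_json",
    "schedule_to_dict",
    "schedule_from_dict",
]

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# frame stacks (TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def schedule_to_dict(s: Schedule) -> dict:
    return {
        "injection_times": s.injection_times.tolist(),
        "injection_condition": list(s.injection_condition),
        "condition_names": list(s.condition_names),
        "condition_labels": list(s.condition_labels),
        "condition_starts": s.condition_starts.tolist(),
        "condition_distances_cm": s.condition_distances_cm.tolist(),
        "condition_duration": s.condition_duration,
        "bolus_period": s.bolus_period,
        "lead_in": s.lead_in,
        "total_duration": s.total_duration,
    }


def schedule_from_dict(d: dict) -> Schedule:
    return Schedule(
        injection_times=np.asarray(d["injection_times"], dtype=float),
        injection_condition=list(d["injection_condition"]),
        condition_names=list(d["condition_names"]),
        condition_labels=list(d["condition_labels"]),
        condition_starts=np.asarray(d["condition_starts"], dtype=float),
        condition_distances_cm=np.asarray(d["condition_distances_cm"], dtype=float),
        condition_duration=float(d["condition_duration"]),
        bolus_period=float(d["bolus_period"]),
        lead_in=float(d["lead_in"]),
        total_duration=float(d["total_duration"]),
    )


def write_stack(
    path: str | Path,
    stack: FrameStack,
    schedule: Schedule | None = None,
    extra: dict | None = None,
) -> None:
    """Write a single-channel 32-bit float multi-frame TIFF plus sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    sidecar = {
        "frame_rate": stack.frame_rate,
        "n_frames": int(stack.n_frames),
        "timestamps": stack.timestamps.tolist(),
    }
    if schedule is not None:
        sidecar["schedule"] = schedule_to_dict(schedule)
    if extra:
        sidecar.update(extra)
    write_json(_sidecar_path(path), sidecar)


def read_stack(path: str | Path) -> tuple[FrameStack, dict]:
    """Read a TIFF stack and its sidecar, validating their agreement."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = read_json(sidecar_path)
    ts = np.asarray(sidecar["timestamps"], dtype=float)
    if sidecar.get("n_frames") != len(frames) or len(ts) != len(frames):
        raise ValueError(
            f"{path}: sidecar frame count {sidecar.get('n_frames')} does not "
            f"match TIFF frame count {len(frames)}"
        )
    stack = FrameStack(
        frames=np.asarray(frames, dtype=np.float32),
        timestamps=ts,
        frame_rate=float(sidecar["frame_rate"]),
    )
    return stack, sidecar


# ---------------------------------------------------------------------------
# curves and tracks (CSV)
# ---------------------------------------------------------------------------


def write_curve(path: str | Path, curve: TimeIntensityCurve) -> None:
    df = pd.DataFrame(
        {
            "time_s": curve.time,
            "intensity": curve.intensity,
            "roi_label": curve.roi_label,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve(path: str | Path) -> TimeIntensityCurve:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"time_s", "intensity", "roi_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: curve CSV must have columns {sorted(required)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and (np.diff(t) <= 0).any():
        bad = int(np.argmax(np.diff(t) <= 0)) + 1
        raise ValueError(f"{path}: non-monotone timestamps at row {bad}")
    return TimeIntensityCurve(
        time=t,
        intensity=df["intensity"].to_numpy(dtype=float),
        roi_label=str(df["roi_label"].iloc[0]) if len(df) else "other",
    )


def write_track(path: str | Path, track: ROITrack) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(track.centers)),
            "row": track.centers[:, 0],
            "col": track.centers[:, 1],
            "score": track.scores,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_track(path: str | Path, half_size: tuple[int, int]) -> ROITrack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return ROITrack(
        centers=df[["row", "col"]].to_numpy(dtype=int),
        scores=df["score"].to_numpy(dtype=float),
        half_size=half_size,
    )


# ---------------------------------------------------------------------------
# metrics and reports
# ---------------------------------------------------------------------------

_METRIC_COLS = [
    "condition",
    "bolus_index",
    "roi_label",
    "detected",
    "f_max",
    "t_0",
    "t_max",
    "t_half_max",
    "slope",
    "tr",
]


def write_metrics(path: str | Path, metrics: list[BolusMetrics]) -> None:
    rows = [
        {
            "condition": m.condition,
            "bolus_index": m.index,
            "roi_label": m.roi_label,
            "detected": m.detected,
            "f_max": m.f_max,
            "t_0": m.t_0,
            "t_max": m.t_max,
            "t_half_max": m.t_half_max,
            "slope": m.slope,
            "tr": m.tr,
        }
        for m in metrics
    ]
    pd.DataFrame(rows, columns=_METRIC_COLS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_metrics(path: str | Path) -> list[BolusMetrics]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(_METRIC_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metrics CSV missing columns {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            BolusMetrics(
                detected=bool(r["detected"]),
                f_max=float(r["f_max"]),
                t_0=float(r["t_0"]),
                t_max=float(r["t_max"]),
                t_half_max=float(r["t_half_max"]),
                slope=float(r["slope"]),
                tr=float(r["tr"]),
                index=int(r["bolus_index"]),
                condition=None if pd.isna(r["condition"]) else str(r["condition"]),
                roi_label=str(r["roi_label"]),
            )
        )
    return out


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: corrupt JSON ({e})") from e
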