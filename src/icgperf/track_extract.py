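"""ROI tracking through a fluorescence frame stack and curve extraction.

Tissue in laparoscopic recordings moves with respiration and peristalsis, so
a fixed image-coordinate ROI samples different tissue over time.  The tracker
follows the ROI with integer-pixel normalized cross-correlation matching
against the previous frame's tracked patch: NCC is invariant to the global
additive/multiplicative intensity drift caused by dye accumulation, and the
previous-frame template tolerates slow appearance change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthgen import FrameStack

__all__ = ["ROI", "ROITrack", "TimeIntensityCurve", "track_roi", "extract_curve"]

ROI_LABELS = ("central", "peripheral", "other")


@dataclass(frozen=True)
class ROI:
    """A closed pixel block ``center +/- half_size`` (0-based row/col)."""

    center: tuple[int, int]
    half_size: tuple[int, int]

    def __post_init__(self) -> None:
        if min(self.half_size) < 0:
            raise ValueError("half_size must be non-negative")

    def validate_in(self, shape: tuple[int, int]) -> None:
        r, c = self.center
        hr, hc = self.half_size
        if r - hr < 0 or c - hc < 0 or r + hr >= shape[0] or c + hc >= shape[1]:
            raise ValueError(f"ROI {self} does not fit inside frame shape {shape}")


@dataclass
class ROITrack:
    """Per-frame tracked ROI center and NCC match score in [-1, 1]."""

    centers: np.ndarray  # (T, 2) int, (row, col)
    scores: np.ndarray  # (T,)
    half_size: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.scores):
            raise ValueError("centers and scores must have equal length")


@dataclass
class TimeIntensityCurve:
    """Mean ROI fluorescence vs time for one region of interest."""

    time: np.ndarray  # s
    intensity: np.ndarray  # a.u.
    roi_label: str = "other"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.time) != len(self.intensity):
            raise ValueError("time and intensity must have equal length")
        if len(self.time) > 1 and (np.diff(self.time) <= 0).any():
            raise ValueError("timestamps must be strictly increasing")
        if len(self.intensity) and np.min(self.intensity) < 0:
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.time)


def _patch(frame: np.ndarray, center: tuple[int, int], half: tuple[int, int]):
    r, c = center
    hr, hc = half
    return frame[r - hr : r + hr + 1, c - hc : c + hc + 1]


def _clamp_center(
    center: tuple[int, int], half: tuple[int, int], shape: tuple[int, int]
) -> tuple[int, int]:
    r = int(np.clip(center[0], half[0], shape[0] - 1 - half[0]))
    c = int(np.clip(center[1], half[1], shape[1] - 1 - half[1]))
    return r, c


def track_roi(frames: FrameStack, init: ROI, search_radius: int = 8) -> ROITrack:
    """Track ``init`` through the stack by exhaustive NCC matching.

    Frame 0 keeps the initial center.  For each later frame the template is
    the previous frame's tracked patch and every candidate center within
    ``search_radius`` (Chebyshev) is scored with the normalized
    cross-correlation coefficient; ties break toward the smallest
    displacement, then row-major order.  Centers are clamped so the ROI stays
    in bounds.  A constant template (undefined correlation) holds the
    previous center with score 0.
    """
    if search_radius < 1:
        raise ValueError("search_radius must be >= 1")
    shape = frames.shape
    hr, hc = init.half_size
    if 2 * hr + 1 > shape[0] or 2 * hc + 1 > shape[1]:
        raise ValueError("ROI larger than frame")
    init.validate_in(shape)

    n = frames.n_frames
    centers = np.zeros((n, 2), dtype=int)
    scores = np.ones(n)
    centers[0] = init.center
    prev = tuple(init.center)

    for i in range(1, n):
        template = _patch(frames.frames[i - 1], prev, init.half_size).astype(float)
        t0 = template - template.mean()
        tnorm = np.sqrt((t0 * t0).sum())
        if tnorm < 1e-12:
            centers[i] = prev
            scores[i] = 0.0
            continue

        # candidate center grid, clamped to keep the ROI inside the frame
        r_lo = max(prev[0] - search_radius, hr)
        r_hi = min(prev[0] + search_radius, shape[0] - 1 - hr)
        c_lo = max(prev[1] - search_radius, hc)
        c_hi = min(prev[1] + search_radius, shape[1] - 1 - hc)
        window = frames.frames[i][
            r_lo - hr : r_hi + hr + 1, c_lo - hc : c_hi + hc + 1
        ].astype(float)
        wins = sliding_window_view(window, (2 * hr + 1, 2 * hc + 1))
        npix = (2 * hr + 1) * (2 * hc + 1)
        wsum = wins.sum(axis=(-2, -1))
        wss = np.einsum("abij,abij->ab", wins, wins)
        num = np.einsum("abij,ij->ab", wins, t0)  # t0 is zero-mean
        wvar = wss - wsum * wsum / npix
        den = np.sqrt(np.clip(wvar, 0.0, None)) * tnorm
        with np.errstate(invalid="ignore", divide="ignore"):
            ncc = np.where(den > 1e-12, num / np.maximum(den, 1e-300), 0.0)

        best = float(ncc.max())
        tied = np.argwhere(ncc == best)
        rows = tied[:, 0] + r_lo
        cols = tied[:, 1] + c_lo
        d2 = (rows - prev[0]) ** 2 + (cols - prev[1]) ** 2
        order = np.lexsort((cols, rows, d2))  # min displacement, then row-major
        j = order[0]
        prev = (int(rows[j]), int(cols[j]))
        centers[i] = prev
        scores[i] = min(max(best, -1.0), 1.0)

    return ROITrack(centers=centers, scores=scores, half_size=init.half_size)


def extract_curve(
    frames: FrameStack, track: ROITrack | ROI, roi_label: str = "other"
) -> TimeIntensityCurve:
    """Mean intensity over the (tracked) ROI at each frame.

    Accepts either a full ROITrack or a static ROI (no motion compensation);
    timestamps are copied from the stack.
    """
    if isinstance(track, ROI):
        track.validate_in(frames.shape)
        centers = np.tile(np.asarray(track.center), (frames.n_frames, 1))
        half = track.half_size
    else:
        if len(track.centers) != frames.n_frames:
            raise ValueError("track length must equal frame count")
        centers = track.centers
        half = track.half_size
    vals = np.empty(frames.n_frames)
    for i in range(frames.n_frames):
        vals[i] = _patch(frames.frames[i], tuple(centers[i]), half).mean()
    return TimeIntensityCurve(
        time=frames.timestamps.copy(), intensity=vals, roi_label=roi_label
    )
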