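"""Rotation correction and peak detection on annular landmark tracks.

The mitral annulus does not generally move along the image y-axis, so each
wall's coordinate scatter is rotated (about its centroid) to align the first
principal axis of motion with the y-axis.  The rotated y-coordinate is the
quantity whose maxima and minima define end-diastole and end-systole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .localization import LandmarkTrack

__all__ = ["YSeries", "PeakSet", "rotation_correct", "detect_peaks"]

log = logging.getLogger(__name__)

# principal/secondary-axis standard-deviation ratio below which a track is
# closer to circular than linear motion and the projected range understates
# the true path
LOW_ANISOTROPY_RATIO = 2.0


@dataclass
class YSeries:
    """Rotated per-wall annular trajectory in mm.

    ``y_mm`` is the projection on the principal motion axis, oriented so that
    end-diastole is a maximum; ``x_mm`` is the orthogonal projection (kept so
    the rotation remains an isometry of the original 2D track).
    """

    y_mm: np.ndarray            # (T,) NaN where invalid
    x_mm: np.ndarray            # (T,) NaN where invalid
    times_s: np.ndarray
    valid: np.ndarray           # (T,) bool
    rotation_deg_applied: float
    anisotropy: float
    low_anisotropy: bool
    wall: int

    @property
    def n_frames(self) -> int:
        return len(self.y_mm)

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times_s)))

    def to_frame(self):
        """Long-format table: frame, time_s, wall, y_mm, valid."""
        import pandas as pd
        return pd.DataFrame({"frame": np.arange(self.n_frames),
                             "time_s": self.times_s, "wall": self.wall,
                             "y_mm": self.y_mm, "valid": self.valid})


@dataclass
class PeakSet:
    """Alternating maxima (ED candidates) and minima (ES candidates)."""

    maxima_frames: np.ndarray
    minima_frames: np.ndarray
    prominences_mm: np.ndarray  # prominence per maximum

    @property
    def is_empty(self) -> bool:
        return len(self.maxima_frames) == 0 or len(self.minima_frames) == 0

    def to_dict(self) -> dict:
        return {"maxima_frames": [int(f) for f in self.maxima_frames],
                "minima_frames": [int(f) for f in self.minima_frames],
                "prominences_mm": [float(p) for p in self.prominences_mm]}


def rotation_correct(track: LandmarkTrack, wall: int) -> YSeries:
    """Align a wall's annular displacement with the y-axis.

    The rotation angle is estimated per wall from the principal axis of the
    valid (row, col) scatter in mm.  The sign of the principal axis is chosen
    by a dwell rule: the annulus spends most of diastole near its
    end-diastolic position, so the orientation placing the majority of samples
    above the robust midrange makes end-diastole the maximum.  Tracks whose
    motion is closer to circular than linear (anisotropy below
    ``LOW_ANISOTROPY_RATIO``) are flagged: the projected range then
    understates the true excursion path.
    """
    valid = track.valid[:, wall]
    if valid.sum() < 2:
        raise ValueError(f"degenerate track: wall {wall} has "
                         f"{int(valid.sum())} valid frames (need >= 2)")
    pts = track.coords_mm[valid, wall, :]  # (n, 2) as (row, col)
    centroid = pts.mean(0)
    centred = pts - centroid
    cov = centred.T @ centred / max(len(pts) - 1, 1)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    major = eigvec[:, 1]
    minor = eigvec[:, 0]
    anisotropy = float(np.sqrt(max(eigval[1], 0.0)
                               / max(eigval[0], 1e-12)))

    proj = centred @ major
    p5, p95 = np.percentile(proj, [5, 95])
    mid = 0.5 * (p5 + p95)
    if np.mean(proj > mid) < 0.5:
        major, minor = -major, -minor
        proj = -proj

    y = np.full(track.n_frames, np.nan)
    x = np.full(track.n_frames, np.nan)
    y[valid] = proj + centroid[0]
    x[valid] = centred @ minor + centroid[1]

    # angle between the principal axis and the image y-axis (row direction)
    angle = float(np.degrees(np.arctan2(major[1], major[0])))
    if angle > 90.0:
        angle -= 180.0
    elif angle < -90.0:
        angle += 180.0

    low = anisotropy < LOW_ANISOTROPY_RATIO
    if low:
        log.info("wall %d: low-anisotropy track (ratio %.2f < %.1f); "
                 "projected range may understate excursion",
                 wall, anisotropy, LOW_ANISOTROPY_RATIO)
    return YSeries(y_mm=y, x_mm=x, times_s=track.times_s.copy(), valid=valid,
                   rotation_deg_applied=angle, anisotropy=anisotropy,
                   low_anisotropy=low, wall=wall)


def _alternate(max_f: np.ndarray, min_f: np.ndarray, y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict maxima/minima alternation, keeping the more extreme of
    any same-kind run."""
    events = [(f, 1) for f in max_f] + [(f, -1) for f in min_f]
    events.sort()
    kept: list[tuple[int, int]] = []
    for f, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (y[f] > y[prev]) if kind == 1 else (y[f] < y[prev])
            if better:
                kept[-1] = (f, kind)
        else:
            kept.append((f, kind))
    maxima = np.array([f for f, k in kept if k == 1], dtype=int)
    minima = np.array([f for f, k in kept if k == -1], dtype=int)
    return maxima, minima


def detect_peaks(ys: YSeries, hr_bounds_bpm: tuple[float, float] = (30.0, 200.0),
                 prominence_floor_mm: float = 1.0) -> PeakSet:
    """Detect alternating ED/ES candidate peaks on a rotated y-series.

    Invalid frames are bridged by linear interpolation for detection only.
    Peaks must be separated by at least one minimal cycle (60 / hr_max s) and
    have prominence >= max(``prominence_floor_mm``, 20% of the robust y-range).
    Boundary samples never count as peaks.  An empty :class:`PeakSet` (no
    maxima/minima pair) signals non-feasibility downstream rather than raising.
    """
    valid_idx = np.flatnonzero(ys.valid)
    if len(valid_idx) < 3:
        raise ValueError("need at least 3 valid frames for peak detection")
    lo, hi = valid_idx[0], valid_idx[-1]
    frames = np.arange(lo, hi + 1)
    bridged = np.interp(frames, valid_idx, ys.y_mm[valid_idx])

    fps = ys.frame_rate_hz
    distance = max(1, int(round(60.0 / hr_bounds_bpm[1] * fps)))
    p5, p95 = np.percentile(bridged, [5, 95])
    prominence = max(prominence_floor_mm, 0.2 * (p95 - p5))

    imax, props = find_peaks(bridged, distance=distance, prominence=prominence)
    imin, _ = find_peaks(-bridged, distance=distance, prominence=prominence)
    prom_by_frame = dict(zip(imax + lo, props["prominences"]))

    # snap each detected peak to the nearest observed (valid) frame
    def snap(idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return idx.astype(int)
        pos = np.searchsorted(valid_idx, idx + lo)
        pos = np.clip(pos, 0, len(valid_idx) - 1)
        left = np.clip(pos - 1, 0, len(valid_idx) - 1)
        choose_left = (np.abs(valid_idx[left] - (idx + lo))
                       <= np.abs(valid_idx[pos] - (idx + lo)))
        return np.unique(np.where(choose_left, valid_idx[left],
                                  valid_idx[pos]))

    maxima = snap(imax)
    minima = snap(imin)
    ybr = np.full(ys.n_frames, np.nan)
    ybr[lo:hi + 1] = bridged
    maxima, minima = _alternate(maxima, minima, ybr)

    prominences = np.array([prom_by_frame.get(f, prominence) for f in maxima])
    return PeakSet(maxima_frames=maxima, minima_frames=minima,
                   prominences_mm=prominences)
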