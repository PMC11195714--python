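"""From landmark probability maps to per-frame annulus coordinates.

A landmark localization is valid in a frame when at least one pixel of its
probability map reaches the fixed 50% threshold; the coordinate is then the
centre of mass of all supra-threshold pixels.  Frames with no supra-threshold
pixel are flagged invalid and carry no coordinate (they are not interpolated
here; downstream filters act on raw validity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["HeatmapSequence", "LandmarkTrack", "extract_track",
           "validity_fraction"]

WALL_LABELS = ("left", "right")


@dataclass
class HeatmapSequence:
    """Per-frame, per-wall landmark probability maps with timing metadata."""

    maps: np.ndarray                 # (T, 2, H, W) probabilities in [0, 1]
    times_s: np.ndarray              # (T,) strictly increasing
    pixel_spacing_mm: float
    wall_labels: tuple[str, str] = WALL_LABELS

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.maps.ndim != 4 or self.maps.shape[1] != 2:
            raise ValueError("maps must have shape (T, 2, H, W)")
        if self.maps.shape[0] < 2:
            raise ValueError("sequence needs at least 2 frames")
        if len(self.times_s) != self.maps.shape[0]:
            raise ValueError("times_s length must match number of frames")
        if not np.all(np.diff(self.times_s) > 0):
            raise ValueError("times_s must be strictly increasing")
        lo, hi = float(self.maps.min()), float(self.maps.max())
        if lo < 0.0 or hi > 1.0 + 1e-6:
            raise ValueError(f"map values outside [0, 1]: [{lo}, {hi}]")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def frame_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times_s)))


@dataclass
class LandmarkTrack:
    """Per-wall coordinate time series with per-frame validity flags.

    ``coords_px[t, wall]`` is (row, col) or NaN where invalid; ``coords_mm``
    is the same scaled by the pixel spacing.
    """

    coords_px: np.ndarray            # (T, 2, 2) NaN where invalid
    coords_mm: np.ndarray
    valid: np.ndarray                # (T, 2) bool
    times_s: np.ndarray
    pixel_spacing_mm: float
    threshold: float = 0.5
    wall_labels: tuple[str, str] = WALL_LABELS

    @property
    def n_frames(self) -> int:
        return self.coords_px.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, time_s, wall, row_px, col_px, valid."""
        rows = []
        for wall, label in enumerate(self.wall_labels):
            rows.append(pd.DataFrame({
                "frame": np.arange(self.n_frames),
                "time_s": self.times_s,
                "wall": label,
                "row_px": self.coords_px[:, wall, 0],
                "col_px": self.coords_px[:, wall, 1],
                "valid": self.valid[:, wall],
            }))
        return pd.concat(rows, ignore_index=True)


def extract_track(seq: HeatmapSequence, threshold: float = 0.5,
                  weighting: str = "probability") -> LandmarkTrack:
    """Centre-of-mass landmark extraction with a fixed validity threshold.

    For each frame and wall, the set S of pixels with probability >=
    ``threshold`` (inclusive) determines validity: empty S discards the
    landmark for that frame; otherwise the coordinate is the centre of mass of
    S, weighted by probability (default) or unweighted (``weighting="uniform"``).
    The centre-of-mass rule deliberately fuses multimodal maps (e.g. a clutter
    blob plus the true landmark) instead of choosing one mode; the resulting
    jumps are caught downstream by the displacement filter.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if weighting not in ("probability", "uniform"):
        raise ValueError("weighting must be 'probability' or 'uniform'")

    t = seq.n_frames
    coords = np.full((t, 2, 2), np.nan)
    valid = np.zeros((t, 2), dtype=bool)
    for i in range(t):
        for wall in range(2):
            m = seq.maps[i, wall]
            idx = np.argwhere(m >= threshold)
            if idx.size == 0:
                continue
            wgt = m[idx[:, 0], idx[:, 1]] if weighting == "probability" \
                else np.ones(len(idx))
            coords[i, wall] = (idx * wgt[:, None]).sum(0) / wgt.sum()
            valid[i, wall] = True

    return LandmarkTrack(coords_px=coords,
                         coords_mm=coords * seq.pixel_spacing_mm,
                         valid=valid, times_s=seq.times_s.copy(),
                         pixel_spacing_mm=seq.pixel_spacing_mm,
                         threshold=threshold, wall_labels=seq.wall_labels)


def validity_fraction(track: LandmarkTrack, wall: int,
                      frame_range: tuple[int, int] | None = None) -> float:
    """Unweighted fraction of valid frames in ``[start, end)`` for one wall."""
    start, end = frame_range if frame_range is not None else (0, track.n_frames)
    if end <= start:
        raise ValueError("empty frame range")
    return float(np.mean(track.valid[start:end, wall]))
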