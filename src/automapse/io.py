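"""Recording container IO.

One HDF5 file per recording holds the heatmap sequence (``heatmaps``,
T x 2 x H x W float32 in [0, 1]), frame times (``times_s``), the pixel
spacing and wall labels as attributes, an optional ``rwave_times_s`` dataset
(absent when no ECG was recorded), and an optional ``truth/`` group carrying
the simulator's ground truth for recovery tests.  R-wave event lists are also
accepted as a CSV with a ``time_s`` column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .localization import HeatmapSequence
from .simdata import GroundTruth, KinematicsConfig

__all__ = ["Recording", "RecordingFormatError", "write_recording",
           "read_recording", "read_rwave_csv", "write_rwave_csv"]


class RecordingFormatError(RuntimeError):
    """The file is not a readable recording container."""


@dataclass
class Recording:
    seq: HeatmapSequence
    rwave_times_s: np.ndarray | None = None
    truth: GroundTruth | None = None

    @property
    def has_ecg(self) -> bool:
        return self.rwave_times_s is not None


def write_recording(path, seq: HeatmapSequence,
                    rwave_times_s: np.ndarray | None = None,
                    truth: GroundTruth | None = None) -> Path:
    """Write one recording; arrays round-trip bitwise."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("heatmaps", data=np.asarray(seq.maps,
                                                     dtype=np.float32))
        f.create_dataset("times_s", data=np.asarray(seq.times_s,
                                                    dtype=np.float64))
        f.attrs["pixel_spacing_mm"] = float(seq.pixel_spacing_mm)
        f.attrs["walls"] = list(seq.wall_labels)
        if rwave_times_s is not None:
            f.create_dataset("rwave_times_s",
                             data=np.asarray(rwave_times_s, dtype=np.float64))
        if truth is not None:
            g = f.create_group("truth")
            g.create_dataset("positions_mm", data=truth.positions_mm)
            g.create_dataset("rwave_times_s", data=truth.rwave_times_s)
            g.create_dataset("mapse_truth_mm",
                             data=np.asarray(truth.mapse_truth_mm))
            g.create_dataset("ed_frames", data=truth.ed_frames)
            g.create_dataset("es_frames", data=truth.es_frames)
            g.attrs["heart_rate_bpm"] = truth.config.heart_rate_bpm
            g.attrs["frame_rate_hz"] = truth.config.frame_rate_hz
            g.attrs["n_cycles"] = truth.config.n_cycles
            g.attrs["pixel_spacing_mm"] = truth.config.pixel_spacing_mm
            g.attrs["image_size_px"] = list(truth.config.image_size_px)
            g.attrs["systole_fraction"] = truth.config.systole_fraction
            g.attrs["atrial_kick_mm"] = truth.config.atrial_kick_mm
            g.attrs["rotation_deg"] = truth.config.rotation_deg
            g.attrs["seed"] = truth.config.seed
    return path


def read_recording(path) -> Recording:
    """Read a recording container; raises RecordingFormatError when unreadable."""
    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except (OSError, IOError) as exc:
        raise RecordingFormatError(
            f"{path} is not a readable recording container: {exc}") from exc
    with f:
        try:
            maps = f["heatmaps"][...]
            times = f["times_s"][...]
            spacing = float(f.attrs["pixel_spacing_mm"])
            walls = tuple(str(w) for w in f.attrs.get("walls",
                                                      ("left", "right")))
        except KeyError as exc:
            raise RecordingFormatError(
                f"{path} misses required dataset/attribute: {exc}") from exc
        rw = f["rwave_times_s"][...] if "rwave_times_s" in f else None
        truth = None
        if "truth" in f:
            g = f["truth"]
            cfg = KinematicsConfig(
                heart_rate_bpm=float(g.attrs["heart_rate_bpm"]),
                frame_rate_hz=float(g.attrs["frame_rate_hz"]),
                n_cycles=int(g.attrs["n_cycles"]),
                mapse_truth_mm=tuple(float(v)
                                     for v in g["mapse_truth_mm"][...]),
                pixel_spacing_mm=float(g.attrs["pixel_spacing_mm"]),
                image_size_px=tuple(int(v)
                                    for v in g.attrs["image_size_px"]),
                systole_fraction=float(g.attrs["systole_fraction"]),
                atrial_kick_mm=float(g.attrs["atrial_kick_mm"]),
                rotation_deg=float(g.attrs["rotation_deg"]),
                seed=int(g.attrs["seed"]))
            truth = GroundTruth(
                positions_mm=g["positions_mm"][...], times_s=times,
                rwave_times_s=g["rwave_times_s"][...],
                mapse_truth_mm=cfg.mapse_truth_mm,
                ed_frames=g["ed_frames"][...], es_frames=g["es_frames"][...],
                config=cfg)
    seq = HeatmapSequence(maps=maps, times_s=times, pixel_spacing_mm=spacing,
                          wall_labels=walls)
    return Recording(seq=seq, rwave_times_s=rw, truth=truth)


def read_rwave_csv(path) -> np.ndarray:
    """R-wave event times from a CSV with a ``time_s`` column."""
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise RecordingFormatError(
            f"{path}: R-wave CSV needs a 'time_s' column")
    return df["time_s"].to_numpy(dtype=float)


def write_rwave_csv(path, rwave_times_s) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": np.asarray(rwave_times_s, dtype=float)}
                 ).to_csv(path, index=False)
    return path
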