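"""Cycle segmentation, quality filters, per-cycle MAPSE, and feasibility.

Two cycle definitions are supported.  With an ECG, each cardiac cycle is one
R-R interval and the per-cycle validity check is weighted around the R-wave
with a normalized exponential kernel (lambda = 0.1 per frame by default), so
frames near end-diastole count more.  Without an ECG, cycles run between
consecutive maxima of the rotated y-coordinate plot and the validity check is
unweighted.

Three quality rules guard each cycle, applied in order:

1. validity — a cycle is discarded when valid landmark localizations cover
   less than 60% of its frames (weighted in ECG mode);
2. jump — a frame-to-frame annular displacement exceeding 5 mm discards the
   containing cycle (ECG mode) or the nearest peak and hence both adjacent
   cycles (peak mode);
3. physiology — the excursion must be positive, with end-systole following
   end-diastole, and below a configurable ceiling.

A wall is feasible when at least one per-cycle estimate survives; the wall
MAPSE is the mean over surviving cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .localization import HeatmapSequence, LandmarkTrack, extract_track
from .trajectory import PeakSet, YSeries, detect_peaks, rotation_correct

__all__ = [
    "FilterConfig", "Cycle", "CycleSet", "WallResult", "MapseResult",
    "segment_cycles_ecg", "segment_cycles_peaks", "validity_filter",
    "jump_filter", "mapse_per_cycle", "aggregate", "estimate_wall",
    "estimate_recording",
]

log = logging.getLogger(__name__)

DISCARD_VALIDITY = "validity"
DISCARD_JUMP = "jump"
DISCARD_UNPHYSIOLOGICAL = "unphysiological"
DISCARD_NO_PEAK_PAIR = "no_peak_pair"


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter thresholds.

    ``validity_min`` uses a strict ``<`` (a cycle with exactly 60% valid
    frames is retained); ``jump_max_mm`` uses a strict ``>`` (a jump of
    exactly 5 mm is retained).  ``lambda_per_frame`` sets the exponential
    R-wave weighting w(d) ∝ exp(-lambda·d) on the frame distance d to the
    cycle's R-wave; the normalization makes the kernel scale-free.
    """

    validity_min: float = 0.6
    lambda_per_frame: float = 0.1
    jump_max_mm: float = 5.0
    mapse_physiological_max_mm: float = 30.0
    use_rwave_weighting: bool | None = None  # None: weighted iff ECG mode
    jump_use_2d: bool = True
    discard_both_adjacent: bool = True       # peak-mode jump rule

    def __post_init__(self) -> None:
        if not 0.0 < self.validity_min <= 1.0:
            raise ValueError("validity_min must lie in (0, 1]")
        if self.lambda_per_frame <= 0:
            raise ValueError("lambda_per_frame must be positive")
        if self.jump_max_mm <= 0:
            raise ValueError("jump_max_mm must be positive")
        if self.mapse_physiological_max_mm <= 0:
            raise ValueError("mapse_physiological_max_mm must be positive")


@dataclass
class Cycle:
    start: int                      # first frame (inclusive)
    end: int                        # one past last frame
    rwave_frame: int | None = None
    passed_validity: bool | None = None
    passed_jump: bool | None = None
    estimate_mm: float | None = None
    ed_frame: int | None = None
    es_frame: int | None = None
    discard_reason: str | None = None

    def frames(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class CycleSet:
    mode: str                       # "ecg" | "peaks"
    cycles: list[Cycle] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("ecg", "peaks"):
            raise ValueError("mode must be 'ecg' or 'peaks'")
        for a, b in zip(self.cycles, self.cycles[1:]):
            if a.end > b.start:
                raise ValueError("cycle boundaries overlap or are unordered")

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass
class WallResult:
    wall: int
    label: str
    mode: str
    cycle_estimates_mm: list[float]
    mean_mm: float | None
    n_cycles: int
    n_valid_cycles: int
    feasible: bool
    discard_counts: dict[str, int]
    rotation_deg_applied: float | None = None
    error: str | None = None


@dataclass
class MapseResult:
    mode: str
    walls: list[WallResult]

    @property
    def n_walls_feasible(self) -> int:
        return sum(w.feasible for w in self.walls)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_walls_feasible": self.n_walls_feasible,
            "walls": [{
                "wall": w.label,
                "mode": w.mode,
                "cycle_estimates_mm": w.cycle_estimates_mm,
                "mean_mm": w.mean_mm,
                "n_cycles": w.n_cycles,
                "n_valid_cycles": w.n_valid_cycles,
                "feasible": w.feasible,
                "discard_counts": w.discard_counts,
                "rotation_deg_applied": w.rotation_deg_applied,
                "error": w.error,
            } for w in self.walls],
        }


def segment_cycles_ecg(ys: YSeries, rwave_times_s: np.ndarray) -> CycleSet:
    """One cycle per consecutive R-R pair; boundaries at the nearest frames."""
    times = ys.times_s
    rw = np.asarray(rwave_times_s, dtype=float)
    in_span = rw[(rw >= times[0] - 0.5 / ys.frame_rate_hz)]
    clipped = in_span[in_span > times[-1] + 0.5 / ys.frame_rate_hz]
    if len(clipped):
        log.warning("%d R-wave(s) beyond the last frame clipped to the "
                    "recording end", len(clipped))
    rw = np.clip(in_span, times[0], times[-1])
    frames = np.unique(np.abs(times[None, :] - rw[:, None]).argmin(axis=1))
    if len(frames) < 2:
        raise ValueError("insufficient ECG events: need >= 2 R-waves within "
                         "the recording span")
    cycles = [Cycle(start=int(a), end=int(b), rwave_frame=int(a))
              for a, b in zip(frames, frames[1:])]
    return CycleSet(mode="ecg", cycles=cycles)


def segment_cycles_peaks(peaks: PeakSet) -> CycleSet:
    """One cycle per consecutive maxima pair; empty set when < 2 maxima.

    Too few maxima is a non-feasibility outcome, not an error.
    """
    maxima = np.asarray(peaks.maxima_frames, dtype=int)
    if len(maxima) < 2:
        return CycleSet(mode="peaks", cycles=[])
    cycles = [Cycle(start=int(a), end=int(b))
              for a, b in zip(maxima, maxima[1:])]
    return CycleSet(mode="peaks", cycles=cycles)


def rwave_weights(n_frames: int, rwave_offset: int,
                  lam: float) -> np.ndarray:
    """Normalized exponential weights w(d) ∝ exp(-lam·|d|) over a cycle.

    ``rwave_offset`` is the R-wave's position within the cycle's frame range.
    """
    d = np.abs(np.arange(n_frames) - rwave_offset)
    w = lam * np.exp(-lam * d)
    return w / w.sum()


def validity_filter(track: LandmarkTrack, wall: int, cycles: CycleSet,
                    cfg: FilterConfig) -> CycleSet:
    """Flag cycles whose (possibly R-wave-weighted) validity is below 60%."""
    weighted = cfg.use_rwave_weighting
    if weighted is None:
        weighted = cycles.mode == "ecg"
    for cyc in cycles.cycles:
        valid = track.valid[cyc.start:cyc.end, wall]
        if len(valid) == 0:
            cyc.passed_validity = False
        elif weighted and cyc.rwave_frame is not None:
            w = rwave_weights(len(valid), cyc.rwave_frame - cyc.start,
                              cfg.lambda_per_frame)
            cyc.passed_validity = bool(float(w @ valid) >= cfg.validity_min)
        else:
            cyc.passed_validity = bool(valid.mean() >= cfg.validity_min)
        if not cyc.passed_validity and cyc.discard_reason is None:
            cyc.discard_reason = DISCARD_VALIDITY
            log.info("wall %d cycle [%d,%d): discarded (%s)", wall, cyc.start,
                     cyc.end, DISCARD_VALIDITY)
    return cycles


def _jump_frames(track: LandmarkTrack, ys: YSeries, wall: int,
                 cfg: FilterConfig) -> np.ndarray:
    """Frames f such that the displacement from the previous valid frame to f
    exceeds the jump threshold."""
    valid_idx = np.flatnonzero(track.valid[:, wall])
    if len(valid_idx) < 2:
        return np.empty(0, dtype=int)
    if cfg.jump_use_2d:
        pts = track.coords_mm[valid_idx, wall, :]
        step = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    else:
        step = np.abs(np.diff(ys.y_mm[valid_idx]))
    return valid_idx[1:][step > cfg.jump_max_mm]


def jump_filter(track: LandmarkTrack, ys: YSeries, wall: int,
                cycles: CycleSet, cfg: FilterConfig,
                peaks: PeakSet | None = None) -> CycleSet:
    """Discard cycles affected by frame-to-frame displacement above 5 mm.

    ECG mode discards the cycle containing the jump.  Peak mode discards the
    peak nearest to the jump, and with it every cycle that peak bounds
    (both adjacent cycles by default).
    """
    jumps = _jump_frames(track, ys, wall, cfg)
    if jumps.size == 0:
        for cyc in cycles.cycles:
            if cyc.passed_jump is None:
                cyc.passed_jump = True
        return cycles

    bad: set[int] = set()
    if cycles.mode == "ecg":
        for j, cyc in enumerate(cycles.cycles):
            if np.any((jumps >= cyc.start) & (jumps < cyc.end)):
                bad.add(j)
    else:
        maxima = (np.asarray(peaks.maxima_frames, dtype=int) if peaks is not None
                  else np.array([c.start for c in cycles.cycles]
                                + ([cycles.cycles[-1].end]
                                   if cycles.cycles else [])))
        for f in jumps:
            if maxima.size == 0:
                break
            peak = maxima[np.abs(maxima - f).argmin()]
            for j, cyc in enumerate(cycles.cycles):
                if cfg.discard_both_adjacent:
                    if cyc.start == peak or cyc.end == peak:
                        bad.add(j)
                elif cyc.start <= f < cyc.end:
                    bad.add(j)

    for j, cyc in enumerate(cycles.cycles):
        cyc.passed_jump = j not in bad
        if j in bad and cyc.discard_reason is None:
            cyc.discard_reason = DISCARD_JUMP
            log.info("wall %d cycle [%d,%d): discarded (%s)", wall, cyc.start,
                     cyc.end, DISCARD_JUMP)
    return cycles


def mapse_per_cycle(ys: YSeries, cycles: CycleSet,
                    cfg: FilterConfig) -> list[float]:
    """Per-cycle MAPSE: y(ED) - y(ES) with ES after ED, from observed frames.

    Only cycles passing the validity and jump filters yield estimates.
    Estimates outside (0, ``mapse_physiological_max_mm``] are discarded as
    unphysiological.
    """
    estimates: list[float] = []
    for cyc in cycles.cycles:
        if cyc.passed_validity is False or cyc.passed_jump is False:
            continue
        frames = cyc.frames()
        frames = frames[(frames >= 0) & (frames < ys.n_frames)]
        vmask = ys.valid[frames]
        vframes = frames[vmask]
        if len(vframes) == 0:
            cyc.discard_reason = DISCARD_NO_PEAK_PAIR
            continue
        yv = ys.y_mm[vframes]
        ed_pos = int(np.argmax(yv))
        after = yv[ed_pos:]
        if len(after) < 2:
            cyc.discard_reason = DISCARD_NO_PEAK_PAIR
            log.info("cycle [%d,%d): no ES after ED", cyc.start, cyc.end)
            continue
        es_pos = ed_pos + int(np.argmin(after))
        est = float(yv[ed_pos] - yv[es_pos])
        cyc.ed_frame = int(vframes[ed_pos])
        cyc.es_frame = int(vframes[es_pos])
        if not 0.0 < est <= cfg.mapse_physiological_max_mm:
            cyc.discard_reason = DISCARD_UNPHYSIOLOGICAL
            log.info("cycle [%d,%d): unphysiological estimate %.2f mm",
                     cyc.start, cyc.end, est)
            continue
        cyc.estimate_mm = est
        estimates.append(est)
    return estimates


def aggregate(wall: int, label: str, cycles: CycleSet,
              estimates: list[float],
              rotation_deg: float | None = None) -> WallResult:
    """Per-wall mean over surviving cycles and the feasibility verdict.

    The per-cycle outcomes reconcile exactly: every cycle is either an
    estimate or carries one discard reason.
    """
    counts = {DISCARD_VALIDITY: 0, DISCARD_JUMP: 0,
              DISCARD_UNPHYSIOLOGICAL: 0, DISCARD_NO_PEAK_PAIR: 0}
    for cyc in cycles.cycles:
        if cyc.discard_reason is not None:
            counts[cyc.discard_reason] += 1
    n_valid = len(estimates)
    assert len(cycles) == n_valid + sum(counts.values()), \
        "cycle outcomes do not reconcile"
    mean = float(np.mean(estimates)) if estimates else None
    return WallResult(wall=wall, label=label, mode=cycles.mode,
                      cycle_estimates_mm=list(estimates), mean_mm=mean,
                      n_cycles=len(cycles), n_valid_cycles=n_valid,
                      feasible=n_valid >= 1, discard_counts=counts,
                      rotation_deg_applied=rotation_deg)


def estimate_wall(track: LandmarkTrack, wall: int, mode: str,
                  rwave_times_s: np.ndarray | None = None,
                  cfg: FilterConfig | None = None) -> WallResult:
    """Run the full per-wall chain: rotate, segment, filter, estimate.

    Any failure that precludes estimation (degenerate track, too few peaks,
    missing ECG events) is reported as a non-feasible wall with the reason in
    ``error`` rather than raised, since non-feasibility is a measured outcome.
    """
    cfg = cfg or FilterConfig()
    label = track.wall_labels[wall]

    def infeasible(reason: str, n_cycles: int = 0) -> WallResult:
        return WallResult(wall=wall, label=label, mode=mode,
                          cycle_estimates_mm=[], mean_mm=None,
                          n_cycles=n_cycles, n_valid_cycles=0, feasible=False,
                          discard_counts={DISCARD_VALIDITY: 0, DISCARD_JUMP: 0,
                                          DISCARD_UNPHYSIOLOGICAL: 0,
                                          DISCARD_NO_PEAK_PAIR: 0},
                          error=reason)

    try:
        ys = rotation_correct(track, wall)
    except ValueError as exc:
        return infeasible(str(exc))

    if mode == "ecg":
        if rwave_times_s is None:
            return infeasible("ECG mode requested without R-wave times")
        try:
            cycles = segment_cycles_ecg(ys, rwave_times_s)
        except ValueError as exc:
            return infeasible(str(exc))
        peaks = None
    elif mode == "peaks":
        try:
            peaks = detect_peaks(ys)
        except ValueError as exc:
            return infeasible(str(exc))
        cycles = segment_cycles_peaks(peaks)
        if len(cycles) == 0:
            return infeasible("no maxima pair detected")
    else:
        raise ValueError("mode must be 'ecg' or 'peaks'")

    validity_filter(track, wall, cycles, cfg)
    jump_filter(track, ys, wall, cycles, cfg, peaks=peaks)
    estimates = mapse_per_cycle(ys, cycles, cfg)
    result = aggregate(wall, label, cycles, estimates,
                       rotation_deg=ys.rotation_deg_applied)
    return result


def estimate_recording(seq: HeatmapSequence,
                       rwave_times_s: np.ndarray | None = None,
                       mode: str = "auto",
                       cfg: FilterConfig | None = None,
                       threshold: float = 0.5,
                       com_weighting: str = "probability") -> MapseResult:
    """Heatmap sequence in, per-wall MAPSE and feasibility out.

    ``mode`` is ``"ecg"``, ``"peaks"`` or ``"auto"`` (ECG when R-wave times
    are provided, peak-based otherwise).
    """
    if mode == "auto":
        mode = "ecg" if rwave_times_s is not None else "peaks"
    track = extract_track(seq, threshold=threshold, weighting=com_weighting)
    walls = [estimate_wall(track, w, mode, rwave_times_s=rwave_times_s,
                           cfg=cfg)
             for w in range(2)]
    return MapseResult(mode=mode, walls=walls)
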