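"""Synthetic transoesophageal-echo recordings with known annular kinematics.

The generator produces, for each recording, a ground-truth mitral-annulus
trajectory for two walls ("left"/"right" as seen in a mid-oesophageal view),
an ECG R-wave train anchored at end-diastole, and CNN-like landmark
probability-map sequences degraded by configurable noise (per-frame dropout,
spatial jitter, and clutter blobs that mimic near-field artefacts being
misread as the annulus).  Everything downstream of the landmark network can
therefore be exercised against exact ground truth.

Coordinate convention: image coordinates are (row, col), 0-based, with the
row index increasing downward; physical coordinates are the same axes scaled
by ``pixel_spacing_mm``.  The simulated annulus descends along a displacement
axis that is rotated ``rotation_deg`` away from the image y-axis, so the
downstream rotation correction is always exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KinematicsConfig",
    "NoiseConfig",
    "GroundTruth",
    "ImageSequence",
    "simulate_kinematics",
    "render_heatmaps",
    "render_bmode",
    "excursion_waveform",
]

# Fraction of one cycle prepended/appended so that every end-diastolic maximum
# is interior to the recording with enough surrounding signal to be a
# prominent peak (real recordings do not start exactly on an R-wave; peak
# detectors ignore boundary samples and need a flank on both sides).
LEAD_FRACTION = 0.4

# Phase layout of one cardiac cycle (phase 0 = R-wave = end-diastole):
# systolic descent on [0, systole_fraction), early-diastolic return on
# [systole_fraction, _DIASTASIS_START), diastasis, then the atrial kick on
# [_KICK_START, 1) closing the residual excursion back to zero.
_DIASTASIS_START = 0.78
_KICK_START = 0.85


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid {name}: {msg}")


@dataclass(frozen=True)
class KinematicsConfig:
    """Physiology and geometry of one simulated recording.

    ``mapse_truth_mm`` holds one amplitude per wall (left, right).  The
    atrial kick is the residual excursion recovered by atrial contraction in
    late diastole; it is capped at a third of the smallest MAPSE so the
    end-diastolic maximum stays the dominant feature of each cycle.
    """

    heart_rate_bpm: float = 74.0
    frame_rate_hz: float = 38.0
    n_cycles: int = 3
    mapse_truth_mm: tuple[float, float] = (10.7, 10.7)
    systole_fraction: float = 0.35
    atrial_kick_mm: float = 1.0
    respiration_amp_mm: float = 0.0
    respiration_period_s: float = 4.0
    lateral_translation_mm: float = 0.0
    lateral_period_s: float = 5.3
    rotation_deg: float = 0.0
    pixel_spacing_mm: float = 0.4
    image_size_px: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(30.0 <= self.heart_rate_bpm <= 200.0, "heart_rate_bpm",
                 "must lie in [30, 200]")
        _require(self.frame_rate_hz > 0, "frame_rate_hz", "must be positive")
        _require(int(self.n_cycles) == self.n_cycles and self.n_cycles >= 1,
                 "n_cycles", "must be a positive integer")
        _require(len(self.mapse_truth_mm) == 2, "mapse_truth_mm",
                 "needs one value per wall (2)")
        for a in self.mapse_truth_mm:
            _require(0.0 < a < 30.0, "mapse_truth_mm", "must lie in (0, 30) mm")
        _require(0.05 < self.systole_fraction < 0.7, "systole_fraction",
                 "must lie in (0.05, 0.7)")
        _require(self.atrial_kick_mm >= 0.0, "atrial_kick_mm",
                 "must be non-negative")
        _require(self.atrial_kick_mm <= min(self.mapse_truth_mm) / 3.0,
                 "atrial_kick_mm", "must not exceed min(mapse_truth_mm)/3")
        _require(self.respiration_amp_mm >= 0.0, "respiration_amp_mm",
                 "must be non-negative")
        _require(self.respiration_period_s > 0, "respiration_period_s",
                 "must be positive")
        _require(self.lateral_translation_mm >= 0.0, "lateral_translation_mm",
                 "must be non-negative")
        _require(self.lateral_period_s > 0, "lateral_period_s",
                 "must be positive")
        _require(self.pixel_spacing_mm > 0, "pixel_spacing_mm",
                 "must be positive")
        h, w = self.image_size_px
        _require(h > 16 and w > 16, "image_size_px", "must exceed 16x16")

    @property
    def cycle_period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


@dataclass(frozen=True)
class NoiseConfig:
    """Degradations applied when rendering heatmaps from ground truth.

    ``dropout_prob`` is the per-frame, per-wall probability that the landmark
    map stays entirely below the validity threshold (a landmark invisible in
    noise).  ``clutter_prob`` adds a second supra-threshold blob displaced by
    ``clutter_offset_px``, emulating bright near-field clutter being picked up
    instead of the annulus.  ``atrial_noise_boost`` multiplies both
    probabilities inside the late-diastolic window (last 15% of each cycle),
    where image quality typically degrades after atrial contraction.
    """

    dropout_prob: float = 0.05
    jitter_sigma_px: float = 1.0
    clutter_prob: float = 0.02
    clutter_offset_px: float = 30.0
    blob_sigma_px: float = 2.0
    atrial_noise_boost: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout_prob", "clutter_prob"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must lie in [0, 1]")
        _require(self.jitter_sigma_px >= 0, "jitter_sigma_px", "must be >= 0")
        _require(self.blob_sigma_px > 0, "blob_sigma_px", "must be positive")
        _require(self.clutter_offset_px >= 0, "clutter_offset_px",
                 "must be >= 0")
        _require(self.atrial_noise_boost >= 0, "atrial_noise_boost",
                 "must be >= 0")

    @staticmethod
    def none() -> "NoiseConfig":
        """A noise-free configuration (clean rendering)."""
        return NoiseConfig(dropout_prob=0.0, jitter_sigma_px=0.0,
                           clutter_prob=0.0)


@dataclass
class GroundTruth:
    """Exact simulated state: what a perfect pipeline should recover."""

    positions_mm: np.ndarray          # (T, 2 walls, 2) as (y=row, x=col) mm
    times_s: np.ndarray               # (T,)
    rwave_times_s: np.ndarray         # (n_cycles + 1,)
    mapse_truth_mm: tuple[float, float]
    ed_frames: np.ndarray             # (n_cycles,) frame nearest each cycle's ED
    es_frames: np.ndarray             # (n_cycles,)
    config: KinematicsConfig

    def positions_px(self) -> np.ndarray:
        return self.positions_mm / self.config.pixel_spacing_mm


@dataclass
class ImageSequence:
    """Rendered grayscale sector frames with pixel-accurate landmark labels."""

    frames: np.ndarray        # (T, H, W) float32 in [0, 1]
    labels: np.ndarray        # (T, 2, H, W) float32 in [0, 1]
    times_s: np.ndarray
    pixel_spacing_mm: float


def excursion_waveform(phase: np.ndarray, amplitude_mm: float,
                       atrial_kick_mm: float,
                       systole_fraction: float) -> np.ndarray:
    """Annular excursion e(phase) in mm, 0 at end-diastole, peak at end-systole.

    Raised-cosine systolic descent, raised-cosine early-diastolic return down
    to the atrial-kick residual, a diastasis plateau, and a gentle late
    raised-cosine closing the residual at the next R-wave.  Smooth (zero-slope
    joins), unimodal per cycle, with max - min equal to ``amplitude_mm``.
    """
    phi = np.asarray(phase, dtype=float) % 1.0
    a, ka, sf = amplitude_mm, atrial_kick_mm, systole_fraction
    e = np.empty_like(phi)

    m = phi < sf
    e[m] = a / 2.0 * (1.0 - np.cos(np.pi * phi[m] / sf))

    m = (phi >= sf) & (phi < _DIASTASIS_START)
    u = (phi[m] - sf) / (_DIASTASIS_START - sf)
    e[m] = ka + (a - ka) / 2.0 * (1.0 + np.cos(np.pi * u))

    m = (phi >= _DIASTASIS_START) & (phi < _KICK_START)
    e[m] = ka

    m = phi >= _KICK_START
    u = (phi[m] - _KICK_START) / (1.0 - _KICK_START)
    e[m] = ka / 2.0 * (1.0 + np.cos(np.pi * u))
    return e


def simulate_kinematics(cfg: KinematicsConfig) -> GroundTruth:
    """Simulate annular landmark trajectories for one recording.

    The recording spans ``n_cycles`` full cycles plus a short lead-in and
    lead-out, with R-waves (``n_cycles + 1`` of them) at the end-diastolic
    instants bounding the cycles.  Respiration (axial, slow) and lateral probe
    translation are additive components on top of the cardiac excursion along
    the rotated displacement axis.
    """
    period = cfg.cycle_period_s
    lead = LEAD_FRACTION * period
    duration = cfg.n_cycles * period + 2 * lead
    n_frames = int(round(duration * cfg.frame_rate_hz)) + 1
    times = np.arange(n_frames) / cfg.frame_rate_hz

    rwaves = lead + period * np.arange(cfg.n_cycles + 1)
    phase = (times - lead) / period  # phase 0 at the first R-wave

    theta = np.deg2rad(cfg.rotation_deg)
    axis = np.array([np.cos(theta), np.sin(theta)])  # (d_row, d_col), unit

    h, w = cfg.image_size_px
    spacing = cfg.pixel_spacing_mm
    base_cols = np.array([0.33 * w, 0.67 * w]) * spacing
    positions = np.empty((n_frames, 2, 2))

    resp = cfg.respiration_amp_mm * np.sin(
        2 * np.pi * times / cfg.respiration_period_s)
    lat = cfg.lateral_translation_mm * np.sin(
        2 * np.pi * times / cfg.lateral_period_s)

    for wall, amp in enumerate(cfg.mapse_truth_mm):
        e = excursion_waveform(phase, amp, cfg.atrial_kick_mm,
                               cfg.systole_fraction)
        # centre the excursion vertically; ED (e=0) is the deepest row
        base_row = (0.55 * h) * spacing + (amp / 2.0) * abs(axis[0])
        positions[:, wall, 0] = base_row - e * axis[0] + resp
        positions[:, wall, 1] = base_cols[wall] - e * axis[1] + lat

    ed_frames = np.array([int(round((lead + k * period) * cfg.frame_rate_hz))
                          for k in range(cfg.n_cycles)])
    es_frames = np.array([
        int(round((lead + (k + cfg.systole_fraction) * period)
                  * cfg.frame_rate_hz))
        for k in range(cfg.n_cycles)])

    return GroundTruth(positions_mm=positions, times_s=times,
                       rwave_times_s=rwaves,
                       mapse_truth_mm=cfg.mapse_truth_mm,
                       ed_frames=ed_frames, es_frames=es_frames, config=cfg)


def _add_blob(img: np.ndarray, center: np.ndarray, peak: float,
              sigma: float) -> None:
    """Add (max-combine) a Gaussian blob, evaluated on a local window."""
    h, w = img.shape
    r0 = max(0, int(np.floor(center[0] - 4 * sigma)))
    r1 = min(h, int(np.ceil(center[0] + 4 * sigma)) + 1)
    c0 = max(0, int(np.floor(center[1] - 4 * sigma)))
    c1 = min(w, int(np.ceil(center[1] + 4 * sigma)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    g = peak * np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                      / (2.0 * sigma ** 2))
    np.maximum(img[r0:r1, c0:c1], g, out=img[r0:r1, c0:c1])


def _cycle_phase(times: np.ndarray, rwaves: np.ndarray) -> np.ndarray:
    """Phase in [0, 1) relative to the R-wave train (extended periodically)."""
    period = np.median(np.diff(rwaves)) if len(rwaves) > 1 else np.inf
    return ((times - rwaves[0]) / period) % 1.0


def render_heatmaps(gt: GroundTruth, noise: NoiseConfig,
                    cfg: KinematicsConfig | None = None) -> "HeatmapSequence":
    """Render per-frame, per-wall landmark probability maps from ground truth.

    A frame/wall carries a Gaussian blob with supra-threshold peak at the
    (jittered) true position unless dropped out, in which case every value
    stays below 0.5.  Clutter frames additionally carry a displaced
    supra-threshold blob.  All random draws are made for every frame/wall
    regardless of whether they take effect, so outputs for different noise
    levels under the same seed are monotonically coupled.
    """
    from .localization import HeatmapSequence  # local import: no cycle at load

    cfg = cfg or gt.config
    h, w = cfg.image_size_px
    t = len(gt.times_s)
    pos_px = gt.positions_px()

    if (pos_px < 0).any() or (pos_px[..., 0] >= h).any() \
            or (pos_px[..., 1] >= w).any():
        bad = np.argwhere((pos_px[..., 0] < 0) | (pos_px[..., 0] >= h)
                          | (pos_px[..., 1] < 0) | (pos_px[..., 1] >= w))
        fr, wall = bad[0]
        raise ValueError(
            f"landmark outside image bounds at frame {fr}, wall {wall}; "
            "enlarge image_size_px or reduce excursion")

    rng = np.random.default_rng(noise.seed)
    u_drop = rng.random((t, 2))
    jitter = rng.normal(0.0, 1.0, (t, 2, 2))
    u_clutter = rng.random((t, 2))
    clutter_angle = rng.uniform(0.0, 2 * np.pi, (t, 2))
    peak_val = rng.uniform(0.6, 0.95, (t, 2))
    drop_peak = rng.uniform(0.1, 0.45, (t, 2))
    clutter_peak = rng.uniform(0.6, 0.95, (t, 2))

    phase = _cycle_phase(gt.times_s, gt.rwave_times_s)
    boost = np.where(phase >= _KICK_START, noise.atrial_noise_boost, 1.0)
    p_drop = np.minimum(1.0, noise.dropout_prob * boost)[:, None]
    p_clutter = np.minimum(1.0, noise.clutter_prob * boost)[:, None]

    dropped = u_drop < p_drop
    cluttered = u_clutter < p_clutter

    maps = np.zeros((t, 2, h, w), dtype=np.float32)
    for i in range(t):
        for wall in range(2):
            center = pos_px[i, wall] + noise.jitter_sigma_px * jitter[i, wall]
            center = np.clip(center, [0.0, 0.0], [h - 1.0, w - 1.0])
            peak = drop_peak[i, wall] if dropped[i, wall] else peak_val[i, wall]
            m = np.zeros((h, w))
            _add_blob(m, center, peak, noise.blob_sigma_px)
            if cluttered[i, wall] and not dropped[i, wall]:
                off = noise.clutter_offset_px * np.array(
                    [np.cos(clutter_angle[i, wall]),
                     np.sin(clutter_angle[i, wall])])
                c2 = np.clip(center + off, [2.0, 2.0], [h - 3.0, w - 3.0])
                _add_blob(m, c2, clutter_peak[i, wall], noise.blob_sigma_px)
            maps[i, wall] = m
    np.clip(maps, 0.0, 1.0, out=maps)

    return HeatmapSequence(maps=maps, times_s=gt.times_s.copy(),
                           pixel_spacing_mm=cfg.pixel_spacing_mm)


def sector_mask(shape: tuple[int, int], half_angle_deg: float = 45.0
                ) -> np.ndarray:
    """Boolean mask of a scan sector with apex at the top-centre pixel."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dc = np.abs(cc - (w - 1) / 2.0)
    radius = np.hypot(rr, dc)
    tan = np.tan(np.deg2rad(half_angle_deg))
    return (dc <= rr * tan) & (radius <= h - 1)


def render_bmode(gt: GroundTruth, cfg: KinematicsConfig | None = None,
                 speckle: float = 0.3, visible: np.ndarray | None = None,
                 seed: int | None = None) -> ImageSequence:
    """Render grayscale 90-degree-sector frames plus landmark label maps.

    Each frame shows a bright band along the annular plane with the brightest
    blobs at the two hinge points, multiplicative speckle inside the sector,
    and exact zeros outside it.  ``visible[t, wall] = False`` omits that
    landmark's blob from the image and empties its label map (a landmark
    invisible in noise).  ``speckle=0`` yields deterministic frames.
    """
    cfg = cfg or gt.config
    h, w = cfg.image_size_px
    t = len(gt.times_s)
    pos = gt.positions_px()
    if visible is None:
        visible = np.ones((t, 2), dtype=bool)

    mask = sector_mask((h, w))
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    frames = np.zeros((t, h, w), dtype=np.float32)
    labels = np.zeros((t, 2, h, w), dtype=np.float32)
    rr, cc = np.mgrid[0:h, 0:w]
    for i in range(t):
        img = np.full((h, w), 0.25)
        p0, p1 = pos[i, 0], pos[i, 1]
        # distance from each pixel to the annular segment p0-p1
        d = p1 - p0
        denom = max(float(d @ d), 1e-9)
        s = np.clip(((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / denom, 0, 1)
        dist2 = (rr - (p0[0] + s * d[0])) ** 2 + (cc - (p0[1] + s * d[1])) ** 2
        img += 0.35 * np.exp(-dist2 / (2.0 * 2.0 ** 2))
        for wall in range(2):
            if visible[i, wall]:
                _add_blob(img, pos[i, wall], 1.0, 2.0)
                lab = np.zeros((h, w))
                _add_blob(lab, pos[i, wall], 1.0, 2.0)
                labels[i, wall] = lab
        if speckle > 0:
            img *= rng.uniform(1.0 - speckle, 1.0 + speckle, (h, w))
        img[~mask] = 0.0
        frames[i] = np.clip(img, 0.0, 1.0)
    return ImageSequence(frames=frames, labels=labels,
                         times_s=gt.times_s.copy(),
                         pixel_spacing_mm=cfg.pixel_spacing_mm)


def simulate_recording(cfg: KinematicsConfig, noise: NoiseConfig | None = None):
    """Convenience: kinematics + heatmaps in one call.

    Returns ``(seq, gt)`` where ``seq`` is the rendered
    :class:`~automapse.localization.HeatmapSequence`.
    """
    noise = noise if noise is not None else NoiseConfig(seed=cfg.seed)
    gt = simulate_kinematics(cfg)
    return render_heatmaps(gt, noise, cfg), gt
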