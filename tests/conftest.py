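import numpy as np
import pytest

from automapse.localization import HeatmapSequence
from automapse.simdata import (KinematicsConfig, NoiseConfig,
                               render_heatmaps, simulate_kinematics)


@pytest.fixture
def clean_cfg():
    """Default physiology, no translation/rotation, moderate resolution."""
    return KinematicsConfig(seed=7)


@pytest.fixture
def no_noise():
    return NoiseConfig.none()


@pytest.fixture
def clean_recording(clean_cfg, no_noise):
    gt = simulate_kinematics(clean_cfg)
    seq = render_heatmaps(gt, no_noise, clean_cfg)
    return seq, gt


def make_recording(seed=0, hr=74.0, mapse=(10.7, 10.7), noise=None,
                   fps=38.0, rotation_deg=0.0, pixel_spacing=0.4,
                   image=(128, 128), n_cycles=3, atrial_kick=None):
    cfg = KinematicsConfig(
        heart_rate_bpm=hr, frame_rate_hz=fps, n_cycles=n_cycles,
        mapse_truth_mm=mapse,
        atrial_kick_mm=min(mapse) / 3.5 if atrial_kick is None else atrial_kick,
        rotation_deg=rotation_deg, pixel_spacing_mm=pixel_spacing,
        image_size_px=image, seed=seed)
    noise = noise or NoiseConfig.none()
    gt = simulate_kinematics(cfg)
    return render_heatmaps(gt, noise, cfg), gt


def sequence_from_maps(maps, dt=1 / 38.0, spacing=0.4):
    maps = np.asarray(maps, dtype=np.float32)
    times = np.arange(maps.shape[0]) * dt
    return HeatmapSequence(maps=maps, times_s=times, pixel_spacing_mm=spacing)
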