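"""A compact trainable heatmap-regression localizer for the annulus landmarks.

This is a small fully-convolutional network implemented directly on numpy:
three same-padding convolution layers with ReLU activations, per-pixel sigmoid
outputs (one map per wall, so multimodal outputs such as clutter remain
representable), Adam optimisation of a positively re-weighted binary
cross-entropy, and coordinate channels appended to the grayscale input so the
network can tell the left from the right wall despite its local receptive
field.  Targets are Gaussian label maps centred on the true landmarks; frames
where a landmark is invisible carry empty target maps.

Training data come from the synthetic sector renderer, with random rotation
and cropping as augmentation.  The model emits the same
:class:`~automapse.localization.HeatmapSequence` contract as any upstream
landmark network, so the downstream pipeline is agnostic to its origin.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .localization import HeatmapSequence
from .simdata import KinematicsConfig, render_bmode, simulate_kinematics

__all__ = ["TrainConfig", "HeatmapLocalizer", "make_training_set",
           "train", "infer"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    image_size: tuple[int, int] = (64, 64)
    n_train_frames: int = 500
    epochs: int = 6
    learning_rate: float = 2e-3
    batch_size: int = 8
    rotation_range_deg: float = 10.0
    crop_fraction: float = 0.9
    augment_prob: float = 0.5
    channels: tuple[int, int] = (12, 12)
    kernel: int = 5
    target_sigma_px: float = 2.0
    pos_weight: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16x16")
        if not -45.0 <= self.rotation_range_deg <= 45.0:
            raise ValueError("rotation_range_deg must lie in [-45, 45]")
        if not 0.5 <= self.crop_fraction <= 1.0:
            raise ValueError("crop_fraction must lie in [0.5, 1]")
        if self.epochs < 1 or self.n_train_frames < 1:
            raise ValueError("epochs and n_train_frames must be positive")


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patches with same-padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)
                                ).reshape(b, h * w, c * k * k)


class _Conv:
    """Same-padding 2D convolution with im2col forward and backward."""

    def __init__(self, c_in: int, c_out: int, k: int,
                 rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, c_out))
        self.b = np.zeros(c_out)
        self._adam = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, _, h, w = x.shape
        self._cols = _im2col(x, self.k)
        y = self._cols @ self.w + self.b
        return y.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, h, w = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.dw = self._cols.reshape(b * h * w, -1).T @ dyf
        self.db = dyf.sum(axis=0)
        # gradient wrt input = convolution of dy with spatially flipped,
        # channel-transposed kernels
        wk = self.w.reshape(self.c_in, self.k, self.k, self.c_out)
        wk = wk[:, ::-1, ::-1, :]                       # flip spatially
        w_t = wk.transpose(3, 1, 2, 0).reshape(
            self.c_out * self.k * self.k, self.c_in)
        cols = _im2col(dy, self.k)
        dx = cols @ w_t
        return dx.reshape(b, h, w, self.c_in).transpose(0, 3, 1, 2)

    def adam_step(self, lr: float, t: int, beta1=0.9, beta2=0.999, eps=1e-8):
        for name, g in (("w", self.dw), ("b", self.db)):
            m = self._adam.setdefault(name + "_m", np.zeros_like(g))
            v = self._adam.setdefault(name + "_v", np.zeros_like(g))
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p = getattr(self, name)
            p -= lr * mhat / (np.sqrt(vhat) + eps)


def _coord_channels(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    rr = np.linspace(0.0, 1.0, h)[:, None] * np.ones((1, w))
    cc = np.ones((h, 1)) * np.linspace(0.0, 1.0, w)[None, :]
    return np.stack([rr, cc])


class HeatmapLocalizer:
    """Numpy FCN emitting two per-wall landmark probability maps per frame."""

    def __init__(self, cfg: TrainConfig | None = None):
        self.cfg = cfg or TrainConfig()
        self._built = False
        self.loss_history_: list[float] = []

    # -- model ------------------------------------------------------------
    def _build(self) -> None:
        c1, c2 = self.cfg.channels
        k = self.cfg.kernel
        rng = np.random.default_rng(self.cfg.seed)
        self.layers = [_Conv(3, c1, k, rng), _Conv(c1, c2, k, rng),
                       _Conv(c2, 2, k, rng)]
        self._coords = _coord_channels(self.cfg.image_size)
        self._built = True

    def _forward(self, images: np.ndarray) -> np.ndarray:
        """images (B, H, W) -> logits (B, 2, H, W), caching activations."""
        b = images.shape[0]
        x = np.concatenate([images[:, None],
                            np.broadcast_to(self._coords,
                                            (b, 2) + images.shape[1:])],
                           axis=1)
        a1 = self.layers[0].forward(x)
        self._m1 = a1 > 0
        a1 = a1 * self._m1
        a2 = self.layers[1].forward(a1)
        self._m2 = a2 > 0
        a2 = a2 * self._m2
        return self.layers[2].forward(a2)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.layers[2].backward(dlogits)
        d = self.layers[1].backward(d * self._m2)
        self.layers[0].backward(d * self._m1)

    # -- training ---------------------------------------------------------
    def fit(self, images: np.ndarray, targets: np.ndarray
            ) -> "HeatmapLocalizer":
        """Train on frames (N, H, W) with Gaussian label maps (N, 2, H, W)."""
        images = np.asarray(images, dtype=float)
        targets = np.asarray(targets, dtype=float)
        if images.ndim != 3 or len(images) == 0:
            raise ValueError("images must be a non-empty (N, H, W) array")
        if images.shape[1:] != tuple(self.cfg.image_size):
            raise ValueError("image size differs from the configured size")
        if targets.shape != (len(images), 2) + images.shape[1:]:
            raise ValueError("targets must have shape (N, 2, H, W)")
        self._build()
        rng = np.random.default_rng(self.cfg.seed + 1)
        n = len(images)
        bs = self.cfg.batch_size
        step = 0
        self.loss_history_ = []
        for epoch in range(self.cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, bs):
                idx = order[s:s + bs]
                xb, yb = self._augment(images[idx], targets[idx], rng)
                logits = self._forward(xb)
                p = 1.0 / (1.0 + np.exp(-logits))
                wgt = 1.0 + self.cfg.pos_weight * yb
                eps = 1e-7
                loss = float(np.mean(-wgt * (yb * np.log(p + eps)
                                             + (1 - yb) * np.log(1 - p + eps))))
                dlogits = wgt * (p - yb) / p.size
                step += 1
                self._backward(dlogits)
                for layer in self.layers:
                    layer.adam_step(self.cfg.learning_rate, step)
                losses.append(loss)
            self.loss_history_.append(float(np.mean(losses)))
            log.info("epoch %d/%d: loss %.5f", epoch + 1, self.cfg.epochs,
                     self.loss_history_[-1])
        return self

    def _augment(self, xb: np.ndarray, yb: np.ndarray,
                 rng: np.random.Generator):
        """Random rotation and cropping, applied jointly to image and labels."""
        xb = xb.copy()
        yb = yb.copy()
        h, w = self.cfg.image_size
        for i in range(len(xb)):
            if rng.random() >= self.cfg.augment_prob:
                continue
            angle = rng.uniform(-self.cfg.rotation_range_deg,
                                self.cfg.rotation_range_deg)
            frac = rng.uniform(self.cfg.crop_fraction, 1.0)
            ch, cw = int(round(h * frac)), int(round(w * frac))
            r0 = rng.integers(0, h - ch + 1)
            c0 = rng.integers(0, w - cw + 1)

            def tf(img):
                out = ndimage.rotate(img, angle, reshape=False, order=1,
                                     mode="constant", cval=0.0)
                out = out[r0:r0 + ch, c0:c0 + cw]
                return ndimage.zoom(out, (h / ch, w / cw), order=1)[:h, :w]

            xb[i] = _fit_shape(tf(xb[i]), (h, w))
            for wall in range(2):
                yb[i, wall] = _fit_shape(tf(yb[i, wall]), (h, w))
        return xb, np.clip(yb, 0.0, 1.0)

    # -- inference --------------------------------------------------------
    def predict(self, images: np.ndarray) -> np.ndarray:
        """Frames (N, H, W) -> probability maps (N, 2, H, W) in [0, 1]."""
        if not self._built:
            raise RuntimeError("model is not trained")
        images = np.asarray(images, dtype=float)
        if images.shape[1:] != tuple(self.cfg.image_size):
            raise ValueError("image size differs from the training size")
        out = np.empty((len(images), 2) + images.shape[1:], dtype=np.float32)
        t0 = time.perf_counter()
        for s in range(0, len(images), 32):
            logits = self._forward(images[s:s + 32])
            out[s:s + 32] = 1.0 / (1.0 + np.exp(-logits))
        dt = (time.perf_counter() - t0) / max(len(images), 1)
        log.info("inference: %.4f s/frame", dt)
        return out

    def infer_sequence(self, frames: np.ndarray, times_s: np.ndarray,
                       pixel_spacing_mm: float) -> HeatmapSequence:
        maps = self.predict(frames)
        return HeatmapSequence(maps=maps, times_s=np.asarray(times_s),
                               pixel_spacing_mm=pixel_spacing_mm)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> Path:
        """Save weights (npz) with a JSON sidecar of config and metrics."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"w{i}"] = layer.w
            arrays[f"b{i}"] = layer.b
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": asdict(self.cfg),
                   "loss_history": self.loss_history_}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return path.with_suffix(".npz")

    @classmethod
    def load(cls, path) -> "HeatmapLocalizer":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_d = sidecar["config"]
        cfg_d["image_size"] = tuple(cfg_d["image_size"])
        cfg_d["channels"] = tuple(cfg_d["channels"])
        model = cls(TrainConfig(**cfg_d))
        model._build()
        data = np.load(path.with_suffix(".npz"))
        for i, layer in enumerate(model.layers):
            layer.w = data[f"w{i}"]
            layer.b = data[f"b{i}"]
        model.loss_history_ = list(sidecar.get("loss_history", []))
        return model


def _fit_shape(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape)
    h = min(shape[0], img.shape[0])
    w = min(shape[1], img.shape[1])
    out[:h, :w] = img[:h, :w]
    return out


def make_training_set(n_frames: int, seed: int = 0,
                      image_size: tuple[int, int] = (64, 64),
                      pixel_spacing_mm: float = 0.8,
                      dropout_prob: float = 0.08,
                      target_sigma_px: float = 2.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Render a frame set for localizer training from random recordings.

    Frames are drawn from simulated recordings spanning a range of heart
    rates, excursions and axis rotations.  With probability ``dropout_prob`` a
    landmark is invisible in a frame: its blob is absent from the image and
    its target map is empty.
    """
    rng = np.random.default_rng(seed)
    images, targets = [], []
    while sum(len(x) for x in images) < n_frames:
        hr = rng.uniform(50, 120)
        mapse = tuple(rng.uniform(5.0, 18.0, 2))
        cfg = KinematicsConfig(
            heart_rate_bpm=hr, frame_rate_hz=25.0, n_cycles=1,
            mapse_truth_mm=mapse, atrial_kick_mm=min(mapse) / 4.0,
            rotation_deg=rng.uniform(-10, 10),
            pixel_spacing_mm=pixel_spacing_mm, image_size_px=image_size,
            seed=int(rng.integers(2 ** 31)))
        gt = simulate_kinematics(cfg)
        t = len(gt.times_s)
        visible = rng.random((t, 2)) >= dropout_prob
        seq = render_bmode(gt, cfg, speckle=0.3, visible=visible,
                           seed=int(rng.integers(2 ** 31)))
        take = min(t, n_frames - sum(len(x) for x in images))
        pick = rng.choice(t, size=take, replace=False)
        images.append(seq.frames[pick])
        targets.append(seq.labels[pick])
    return (np.concatenate(images)[:n_frames],
            np.concatenate(targets)[:n_frames])


def train(dataset: tuple[np.ndarray, np.ndarray],
          cfg: TrainConfig | None = None) -> HeatmapLocalizer:
    """Train a localizer on ``(images, targets)``; deterministic given seed."""
    images, targets = dataset
    if len(images) == 0:
        raise ValueError("empty dataset")
    model = HeatmapLocalizer(cfg)
    return model.fit(images, targets)


def infer(model: HeatmapLocalizer, images: np.ndarray, times_s: np.ndarray,
          pixel_spacing_mm: float) -> HeatmapSequence:
    """Module-level convenience wrapper over :meth:`HeatmapLocalizer.infer_sequence`."""
    return model.infer_sequence(images, times_s, pixel_spacing_mm)
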