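"""The three-stage binary U-Net cascade.

Stage 1 segments droplets from raw RGB frames.  Its binarized output is
overlaid on the input — every pixel outside the predicted droplet mask is
blacked out — which removes background contrast so the tiny (1–3 px)
crystal targets are no longer drowned out by dominant features.  Stages 2
(vaterite) and 3 (calcite) then run independently on the overlaid image.
Stacking the three binary outputs yields a single RGB label image:
background black, droplet white, vaterite red, calcite green.

The networks are classic encoder–decoder U-Nets with skip connections,
two 3x3 conv+ReLU blocks per resolution level, filters doubling per level,
nearest-neighbor upsampling and a 1x1 sigmoid head, trained with Adam on
binary cross-entropy.  Hyperparameter presets mirror the full-scale
configuration (5–6 encoders, 32–64 base filters, thousands of epochs);
desk-scale defaults (2–3 encoders, 8–16 filters) train in minutes on a CPU.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .tiling import cut_and_resize, reconstruct

logger = logging.getLogger(__name__)

#: Full-scale hyperparameter presets for the three cascade stages
#: (n_encoders, base_filters, learning_rate, batch_size, n_epochs).
FULL_SCALE_PRESETS = {
    "droplet": dict(n_encoders=5, base_filters=32, learning_rate=4.4e-4,
                    batch_size=2, n_epochs=9269),
    "vaterite": dict(n_encoders=6, base_filters=64, learning_rate=4.9e-4,
                     batch_size=16, n_epochs=3853),
    "calcite": dict(n_encoders=5, base_filters=64, learning_rate=6.9e-4,
                    batch_size=13, n_epochs=2997),
}


@dataclass(frozen=True)
class UNetSpec:
    """Architecture and optimization hyperparameters of one binary U-Net."""

    n_encoders: int = 2
    base_filters: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 8
    n_epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_encoders < 2:
            raise ValueError("n_encoders must be >= 2")
        if self.base_filters < 1:
            raise ValueError("base_filters must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be positive")

    @property
    def divisor(self) -> int:
        """Required divisibility of the input spatial size."""
        return 2 ** (self.n_encoders - 1)


@dataclass(frozen=True)
class TrainConfig:
    """Data split, augmentation and loss-reporting options."""

    split: float = 0.8  # train fraction
    flip_horizontal: bool = True
    flip_vertical: bool = True
    rot90: bool = True
    brightness_jitter: float = 0.1  # multiplicative amplitude on images
    loss_mode: str = "mean"  # 'mean' per-pixel BCE or 'sum' totals
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.split < 1.0:
            raise ValueError("split fraction must be in (0, 1)")
        if self.loss_mode not in ("mean", "sum"):
            raise ValueError("loss_mode must be 'mean' or 'sum'")


class UNetModel:
    """A (possibly trained) binary U-Net: spec + weights + provenance."""

    def __init__(self, spec: UNetSpec, in_channels: int = 3):
        self.spec = spec
        self.in_channels = in_channels
        self.params = _nn.unet_init(spec.n_encoders, spec.base_filters,
                                    in_channels, spec.seed)
        self.trained = False
        self.history: dict[str, list[float]] = {}

    def n_parameters(self) -> int:
        return self.params.n_parameters()

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Probability maps in [0,1] for a batch (N,H,W,C) or single (H,W,C)."""
        single = images.ndim == 3
        x = _as_float_batch(images)
        logits, _ = _nn.unet_forward(self.params, x, self.spec.n_encoders)
        prob = _nn.sigmoid(logits)[..., 0]
        return prob[0] if single else prob

    # -- persistence: NumPy-native .npz weights + JSON sidecar ------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 **{f"w{i}": w for i, w in enumerate(self.params.weights)})
        sidecar = dict(spec=asdict(self.spec), in_channels=self.in_channels,
                       trained=self.trained)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "UNetModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model = cls(UNetSpec(**sidecar["spec"]), sidecar["in_channels"])
        with np.load(path.with_suffix(".npz")) as z:
            model.params.weights = [z[f"w{i}"] for i in range(len(z.files))]
        model.trained = sidecar["trained"]
        return model


def build_unet(spec: UNetSpec, in_channels: int = 3) -> UNetModel:
    """Construct an untrained binary U-Net from its spec (deterministic init)."""
    return UNetModel(spec, in_channels)


def _as_float_batch(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if x.max() > 1.5:  # uint8-scaled input
        x = x / 255.0
    return x


def _as_binary_target(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    vals = np.unique(m)
    if not np.all(np.isin(vals, (0.0, 1.0, 255.0))):
        raise ValueError(f"mask is not binary; values {vals[:8]}")
    return (m > 0).astype(np.float64)


def _augment(img, msk, rng, cfg: TrainConfig):
    if cfg.flip_horizontal and rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if cfg.flip_vertical and rng.random() < 0.5:
        img, msk = img[::-1], msk[::-1]
    if cfg.rot90 and img.shape[0] == img.shape[1]:
        k = int(rng.integers(0, 4))
        img, msk = np.rot90(img, k), np.rot90(msk, k)
    if cfg.brightness_jitter > 0:
        img = np.clip(img * (1.0 + cfg.brightness_jitter *
                             (2 * rng.random() - 1)), 0.0, 1.0)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def train_model(
    model: UNetModel,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
) -> UNetModel:
    """Train a binary U-Net on (image, mask) pairs.

    Splits the pairs into disjoint, exhaustive train/validation sets at
    ``cfg.split``, augments training samples, optimizes mean binary
    cross-entropy with Adam, and restores the best-on-validation weights.
    The per-epoch loss trace (in ``cfg.loss_mode`` units) lands in
    ``model.history``.  Fully reproducible for fixed seeds.
    """
    if len(pairs) == 0:
        raise ValueError("empty training set")
    imgs = [_as_float_batch(im)[0] for im, _ in pairs]
    msks = [_as_binary_target(mk) for _, mk in pairs]
    for im, mk in zip(imgs, msks):
        if im.shape[:2] != mk.shape:
            raise ValueError("image and mask spatial dims differ")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(pairs))
    n_train = max(1, int(round(len(pairs) * cfg.split)))
    if n_train == len(pairs) and len(pairs) > 1:
        n_train -= 1
    tr_idx, va_idx = order[:n_train], order[n_train:]
    n_px = imgs[0].size // imgs[0].shape[2]
    scale = 1.0 if cfg.loss_mode == "mean" else n_px

    spec = model.spec
    opt = _nn.Adam(model.params.weights, spec.learning_rate)
    best_val = np.inf
    best_weights = model.params.copy()
    hist_train, hist_val = [], []

    def eval_loss(idx) -> float:
        tot, n = 0.0, 0
        for i in idx:
            prob = model.predict(imgs[i])
            tot += _nn.bce_loss(prob, msks[i], "mean")
            n += 1
        return tot / max(n, 1)

    for _epoch in range(spec.n_epochs):
        perm = rng.permutation(tr_idx)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), spec.batch_size):
            bidx = perm[start:start + spec.batch_size]
            bx, by = [], []
            for i in bidx:
                im, mk = _augment(imgs[i], msks[i], rng, cfg)
                bx.append(im)
                by.append(mk)
            x = np.stack(bx)
            y = np.stack(by)
            logits, cache = _nn.unet_forward(model.params, x, spec.n_encoders)
            prob = _nn.sigmoid(logits[..., 0])
            ep_loss += _nn.bce_loss(prob, y, "mean")
            n_batches += 1
            dlogits = ((prob - y) / y.size)[..., None]
            grads = _nn.unet_backward(model.params, cache, dlogits,
                                      spec.n_encoders)
            opt.step(model.params.weights, grads)
        hist_train.append(scale * ep_loss / max(n_batches, 1))
        val = eval_loss(va_idx) if len(va_idx) else ep_loss / max(n_batches, 1)
        hist_val.append(scale * val)
        if val < best_val:
            best_val = val
            best_weights = model.params.copy()

    model.params = best_weights
    model.trained = True
    model.history = dict(train_bce=hist_train, val_bce=hist_val,
                         n_train=len(tr_idx), n_val=len(va_idx),
                         loss_mode=cfg.loss_mode)
    return model


def overlay(rgb_image: np.ndarray, droplet_mask: np.ndarray) -> np.ndarray:
    """Black out every pixel outside the droplet mask (background removal).

    Pixels where the mask is foreground keep their original RGB values; all
    others become black.  Idempotent: overlaying twice equals overlaying once.
    """
    if rgb_image.shape[:2] != droplet_mask.shape[:2]:
        raise ValueError(
            f"image {rgb_image.shape[:2]} and mask {droplet_mask.shape[:2]} "
            "spatial dims differ"
        )
    out = rgb_image.copy()
    out[droplet_mask == 0] = 0
    return out


def _predict_full_frame(model: UNetModel, frame: np.ndarray,
                        grid: tuple[int, int],
                        target_hw: tuple[int, int]) -> np.ndarray:
    tiles = cut_and_resize(frame, grid, target_hw, is_mask=False,
                           divisor=model.spec.divisor)
    probs = [model.predict(t.image) for t in tiles.tiles]
    return reconstruct(tiles, probs, is_mask=False)


def run_cascade(
    models: tuple[UNetModel, UNetModel, UNetModel],
    rgb_frame: np.ndarray,
    grid: tuple[int, int] = (0, 0),
    target_hw: tuple[int, int] | None = None,
    binarizer=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run the full three-stage cascade on one RGB frame.

    Returns full-frame binary masks ``(droplet, vaterite, calcite)``.
    Stage 1 predicts droplets from the raw frame; its binarized output is
    overlaid on the input; stages 2 and 3 run independently on the overlaid
    image.  ``binarizer`` maps a probability map to a {0,255} mask and
    defaults to the two-cluster K-Means binarizer.
    """
    droplet_net, vaterite_net, calcite_net = models
    for name, m in zip(("droplet", "vaterite", "calcite"), models):
        if not m.trained:
            raise ValueError(f"{name} model is untrained")
    if binarizer is None:
        from .counting import binarize_kmeans
        binarizer = binarize_kmeans
    if target_hw is None:
        h, w = rgb_frame.shape[:2]
        target_hw = (h // (1 + grid[0]), w // (1 + grid[1]))

    droplet_prob = _predict_full_frame(droplet_net, rgb_frame, grid, target_hw)
    droplet_mask = binarizer(droplet_prob)
    overlaid = overlay(rgb_frame, droplet_mask)
    vat_prob = _predict_full_frame(vaterite_net, overlaid, grid, target_hw)
    cal_prob = _predict_full_frame(calcite_net, overlaid, grid, target_hw)
    return droplet_mask, binarizer(vat_prob), binarizer(cal_prob)


def stack_segmentations(
    droplet_mask: np.ndarray,
    vaterite_mask: np.ndarray,
    calcite_mask: np.ndarray,
    vaterite_prob: np.ndarray | None = None,
    calcite_prob: np.ndarray | None = None,
) -> np.ndarray:
    """Compose the three binary masks into one RGB label image.

    Background black, droplet white, vaterite red, calcite green; crystal
    classes take precedence over droplet.  A pixel claimed by both crystal
    masks goes to vaterite when its stage-2 probability >= stage-3
    probability (fallback without probabilities: vaterite).  Crystal pixels
    outside the droplet mask are still rendered, with a warning.
    """
    shapes = {droplet_mask.shape, vaterite_mask.shape, calcite_mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"mask dimensions differ: {shapes}")
    h, w = droplet_mask.shape
    out = np.zeros((h, w, 3), dtype=np.uint8)
    d = droplet_mask > 0
    v = vaterite_mask > 0
    c = calcite_mask > 0
    both = v & c
    if both.any():
        if vaterite_prob is not None and calcite_prob is not None:
            to_v = vaterite_prob >= calcite_prob
        else:
            to_v = np.ones((h, w), dtype=bool)
        v = v & (~both | to_v)
        c = c & ~v
    stray = (v | c) & ~d
    if stray.any():
        msg = f"{int(stray.sum())} crystal pixels fall outside the droplet mask"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    out[d] = (255, 255, 255)
    out[v] = (255, 0, 0)
    out[c] = (0, 255, 0)
    return out
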