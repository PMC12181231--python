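"""Minimal NumPy convolutional-network engine for the binary U-Nets.

Implements exactly the pieces the segmentation cascade needs — 3x3 same
convolutions, ReLU, 2x2 max pooling, nearest-neighbor upsampling, skip
concatenation, a 1x1 sigmoid head, binary cross-entropy and Adam — with
hand-written backpropagation.  Arrays are NHWC float32/float64.  All
convolutions are computed as nine shifted tensor contractions, which keeps
memory flat and vectorizes well for the tile sizes used here.

Everything is deterministic for a fixed seed (single-threaded NumPy ops,
no stochastic layers).
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNetParams", "unet_init", "unet_forward", "unet_backward",
           "bce_loss", "Adam"]


# ---------------------------------------------------------------- primitives

def _conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 3x3 convolution.  x: (N,H,W,Cin), W: (3,3,Cin,Cout)."""
    n, h, w, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.zeros((n, h, w, W.shape[3]), dtype=x.dtype)
    for dy in range(3):
        for dx in range(3):
            out += np.tensordot(
                xp[:, dy:dy + h, dx:dx + w, :], W[dy, dx], axes=([3], [0])
            )
    return out + b


def _conv3x3_backward(
    x: np.ndarray, W: np.ndarray, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, h, w, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dxp = np.zeros_like(xp)
    dW = np.zeros_like(W)
    for dy in range(3):
        for dx in range(3):
            xs = xp[:, dy:dy + h, dx:dx + w, :]
            dW[dy, dx] = np.tensordot(xs, dout, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, dy:dy + h, dx:dx + w, :] += np.tensordot(
                dout, W[dy, dx], axes=([3], [1])
            )
    db = dout.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dW, db


def _conv1x1_forward(x, W, b):
    return np.tensordot(x, W, axes=([3], [0])) + b


def _conv1x1_backward(x, W, dout):
    dW = np.tensordot(x, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    dx = np.tensordot(dout, W, axes=([3], [1]))
    return dx, dW, db


def _maxpool2(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
    out = xr.max(axis=(2, 4))
    return out, xr


def _maxpool2_backward(xr, out, dout):
    mask = xr == out[:, :, None, :, None, :]
    counts = mask.sum(axis=(2, 4), keepdims=True)
    dxr = mask * (dout[:, :, None, :, None, :] / counts)
    n, hh, _, ww, _, c = xr.shape
    return dxr.reshape(n, hh * 2, ww * 2, c)


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dout):
    n, h, w, c = dout.shape
    return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(prob: np.ndarray, target: np.ndarray, reduction: str = "mean") -> float:
    """Binary cross-entropy; ``reduction`` is 'mean' (per pixel) or 'sum'."""
    p = np.clip(prob, 1e-7, 1 - 1e-7)
    ll = -(target * np.log(p) + (1 - target) * np.log(1 - p))
    return float(ll.mean() if reduction == "mean" else ll.sum())


# ------------------------------------------------------------------- U-Net

class UNetParams:
    """Flat parameter store: list of (W, b) arrays in a fixed layer order."""

    def __init__(self, weights: list[np.ndarray]):
        self.weights = weights

    def copy(self) -> "UNetParams":
        return UNetParams([w.copy() for w in self.weights])

    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights))


def _level_filters(base_filters: int, n_levels: int) -> list[int]:
    return [base_filters * (2**i) for i in range(n_levels)]


def unet_init(
    n_encoders: int, base_filters: int, in_channels: int, seed: int
) -> UNetParams:
    """He-initialised weights for an ``n_encoders``-level binary U-Net.

    Each level holds two 3x3 conv+ReLU blocks; filters double per level on
    the way down and mirror on the way up; a 1x1 convolution produces the
    single-channel logit map.
    """
    rng = np.random.default_rng(seed)
    filters = _level_filters(base_filters, n_encoders)
    weights: list[np.ndarray] = []

    def conv(cin, cout, k=3):
        fan_in = k * k * cin
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout))
        if k == 1:
            W = W[0, 0]
        weights.append(W.astype(np.float64))
        weights.append(np.zeros(cout))

    cin = in_channels
    for f in filters:  # down path incl. bottom level
        conv(cin, f)
        conv(f, f)
        cin = f
    for i in range(n_encoders - 2, -1, -1):  # up path
        f = filters[i]
        cin_up = cin + f  # upsampled features concatenated with the skip
        conv(cin_up, f)
        conv(f, f)
        cin = f
    conv(cin, 1, k=1)  # logit head
    return UNetParams(weights)


def _take2(weights, idx):
    return weights[idx], weights[idx + 1]


def unet_forward(
    params: UNetParams, x: np.ndarray, n_encoders: int
) -> tuple[np.ndarray, dict]:
    """Forward pass; returns (logits, cache). x: (N,H,W,C), H,W divisible
    by 2^(n_encoders-1)."""
    h, w = x.shape[1:3]
    div = 2 ** (n_encoders - 1)
    if h % div or w % div:
        raise ValueError(
            f"input spatial size {(h, w)} must be divisible by {div} "
            f"(2^(n_encoders-1) with n_encoders={n_encoders})"
        )
    weights = params.weights
    cache: dict = {"acts": [], "pools": [], "skips": [], "concats": []}
    idx = 0
    cur = x
    for lvl in range(n_encoders):
        for _ in range(2):
            W, b = _take2(weights, idx)
            idx += 2
            pre = _conv3x3_forward(cur, W, b)
            act = np.maximum(pre, 0.0)
            cache["acts"].append((cur, W, act))
            cur = act
        if lvl < n_encoders - 1:
            cache["skips"].append(cur)
            pooled, xr = _maxpool2(cur)
            cache["pools"].append((xr, pooled))
            cur = pooled
    for lvl in range(n_encoders - 2, -1, -1):
        up = _upsample2(cur)
        skip = cache["skips"][lvl]
        cur = np.concatenate([up, skip], axis=3)
        cache["concats"].append((up.shape[3], cur))
        for _ in range(2):
            W, b = _take2(weights, idx)
            idx += 2
            pre = _conv3x3_forward(cur, W, b)
            act = np.maximum(pre, 0.0)
            cache["acts"].append((cur, W, act))
            cur = act
    W, b = _take2(weights, idx)
    logits = _conv1x1_forward(cur, W, b)
    cache["head_in"] = cur
    cache["head_W"] = W
    return logits, cache


def unet_backward(
    params: UNetParams, cache: dict, dlogits: np.ndarray, n_encoders: int
) -> list[np.ndarray]:
    """Gradients w.r.t. every weight, in ``params.weights`` order."""
    grads: list[np.ndarray | None] = [None] * len(params.weights)
    dcur, dWh, dbh = _conv1x1_backward(cache["head_in"], cache["head_W"], dlogits)
    grads[-2], grads[-1] = dWh, dbh

    acts = cache["acts"]
    a_idx = len(acts) - 1
    w_idx = len(params.weights) - 4  # last 3x3 conv's W position

    def back_block(dout):
        nonlocal a_idx, w_idx, grads
        xin, W, act = acts[a_idx]
        a_idx -= 1
        dpre = dout * (act > 0)
        dx, dW, db = _conv3x3_backward(xin, W, dpre)
        grads[w_idx], grads[w_idx + 1] = dW, db
        w_idx -= 2
        return dx

    dskips: dict[int, np.ndarray] = {}
    # up path, reversed
    concat_iter = len(cache["concats"]) - 1
    for lvl in range(0, n_encoders - 1):
        dcur = back_block(back_block(dcur))
        up_ch, _ = cache["concats"][concat_iter]
        concat_iter -= 1
        dup = dcur[..., :up_ch]
        dskips[lvl] = dcur[..., up_ch:]
        dcur = _upsample2_backward(dup)

    # down path, reversed (bottom level first)
    for lvl in range(n_encoders - 1, -1, -1):
        if lvl < n_encoders - 1:
            xr, pooled = cache["pools"][lvl]
            dcur = _maxpool2_backward(xr, pooled, dcur) + dskips[lvl]
        dcur = back_block(back_block(dcur))
    return grads  # type: ignore[return-value]


class Adam:
    """Standard Adam optimizer over a flat weight list."""

    def __init__(self, weights: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w in weights]
        self.v = [np.zeros_like(w) for w in weights]
        self.t = 0

    def step(self, weights: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (w, g) in enumerate(zip(weights, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            w -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
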