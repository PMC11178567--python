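"""Bundled segmentation model and optimizer.

The model contract is minimal so any architecture can be plugged in: a model
maps an image batch ``(B, 3, H, W)`` to per-class logit grids of the same
spatial size ``(B, C, H, W)``, exposes its parameters, and can save/load
them.  The bundled reference implementation, :class:`BlobNet`, is a small
convolutional encoder–decoder with one downsampling stage and a skip
connection, written directly on numpy (float32, channel-last internally)
with hand-derived backpropagation so it trains on a CPU in seconds at 64x64.
It is deterministic given its seed and inputs.

Gradients enter through the loss module (``masked_weighted_bce_with_grad``
returns d(total)/d(logits)); :meth:`BlobNet.backward` propagates them to all
parameters, and :class:`AdamW` applies decoupled-weight-decay updates.
"""
from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["SegmentationModel", "BlobNet", "AdamW"]


@runtime_checkable
class SegmentationModel(Protocol):
    """Anything that maps image batches to per-class logit grids."""

    n_out: int
    params: dict[str, np.ndarray]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray: ...

    def backward(self, dz: np.ndarray) -> dict[str, np.ndarray]: ...

    def get_params(self) -> dict[str, np.ndarray]: ...

    def set_params(self, params: dict[str, np.ndarray]) -> None: ...


# Convolutions operate channel-last: activations are (B, H, W, C) and a 3x3
# kernel is stored as a (9*Cin, Cout) matrix whose rows are ordered by the
# (di, dj) window offset, matching the column blocks produced by _patches.


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    """(B, H, W, C) -> (B, H, W, k*k*C) same-padding patch matrix."""
    if k == 1:
        return x
    p = k // 2
    B, H, W, C = x.shape
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    return np.concatenate(
        [xp[:, di : di + H, dj : dj + W, :] for di in range(k) for dj in range(k)],
        axis=3,
    )


def _conv_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stride-1 same-padding conv; returns (output, cached patch matrix)."""
    cols = _patches(x, k)
    return cols @ w + b, cols


def _conv_backward(
    dout: np.ndarray, cols: np.ndarray, w: np.ndarray, k: int, cin: int,
    need_dx: bool = True,
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of the conv above; dx skipped for input layers."""
    dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    if not need_dx:
        return None, dw, db
    dcols = dout @ w.T
    if k == 1:
        return dcols, dw, db
    p = k // 2
    B, H, W, _ = dout.shape
    dxp = np.zeros((B, H + 2 * p, W + 2 * p, cin), dtype=dout.dtype)
    idx = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + H, dj : dj + W, :] += dcols[
                ..., idx * cin : (idx + 1) * cin
            ]
            idx += 1
    return dxp[:, p : p + H, p : p + W, :], dw, db


def _avgpool2(x: np.ndarray) -> np.ndarray:
    B, H, W, C = x.shape
    return x.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))


def _avgpool2_backward(d: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(d, 2, axis=1), 2, axis=2) * 0.25


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(d: np.ndarray) -> np.ndarray:
    B, H, W, C = d.shape
    return d.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


class BlobNet:
    """Small encoder–decoder CNN: full-res stem, one pooled stage, skip merge.

        h1 = relu(conv3x3(x; 3 -> F))          # full resolution
        h2 = relu(conv3x3(avgpool2(h1); F -> 2F))
        h3 = relu(conv1x1([h1, up2(h2)]; 3F -> F))   # cheap skip merge
        z  = conv1x1(h3; F -> n_out)

    The receptive field spans ~10 pixels at full resolution, enough local
    context to pool colour evidence over blob interiors while the pooled
    stage adds coarser context; the merge is a 1x1 mixing layer, which keeps
    the per-pixel cost low.  He-normal init from the given seed; identical
    (seed, inputs) give identical outputs.
    """

    _shapes = staticmethod(
        lambda F, n_out: {
            "w1": (9 * 3, F),
            "b1": (F,),
            "w2": (9 * F, 2 * F),
            "b2": (2 * F,),
            "w3": (3 * F, F),
            "b3": (F,),
            "w4": (F, n_out),
            "b4": (n_out,),
        }
    )

    def __init__(self, n_out: int, width: int = 8, seed: int = 0):
        if n_out < 1:
            raise ValueError("model needs at least one output channel")
        self.n_out = int(n_out)
        self.width = int(width)
        rng = np.random.default_rng([seed, 97])
        self.params: dict[str, np.ndarray] = {}
        for name, shape in self._shapes(self.width, self.n_out).items():
            if name.startswith("b"):
                self.params[name] = np.zeros(shape, dtype=np.float32)
            else:
                fan_in = shape[0]
                self.params[name] = rng.normal(
                    0.0, np.sqrt(2.0 / fan_in), size=shape
                ).astype(np.float32)
        self._cache: dict | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) input, got {x.shape}")
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError("spatial dimensions must be even")
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # channel-last
        p = self.params
        a1, cols1 = _conv_forward(x, p["w1"], p["b1"], 3)
        h1 = np.maximum(a1, 0.0)
        pooled = _avgpool2(h1)
        a2, cols2 = _conv_forward(pooled, p["w2"], p["b2"], 3)
        h2 = np.maximum(a2, 0.0)
        cat = np.concatenate([h1, _upsample2(h2)], axis=3)
        a3, cols3 = _conv_forward(cat, p["w3"], p["b3"], 1)
        h3 = np.maximum(a3, 0.0)
        z, cols4 = _conv_forward(h3, p["w4"], p["b4"], 1)
        if train:
            self._cache = {
                "m1": a1 > 0, "m2": a2 > 0, "m3": a3 > 0,
                "cols1": cols1, "cols2": cols2, "cols3": cols3, "cols4": cols4,
            }
        else:
            self._cache = None
        return z.transpose(0, 3, 1, 2)

    def backward(self, dz: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of every parameter given d(loss)/d(logits)."""
        if self._cache is None:
            raise RuntimeError("call forward(..., train=True) before backward")
        dz = np.ascontiguousarray(np.asarray(dz, dtype=np.float32).transpose(0, 2, 3, 1))
        c = self._cache
        p = self.params
        F = self.width
        grads: dict[str, np.ndarray] = {}
        dh3, grads["w4"], grads["b4"] = _conv_backward(dz, c["cols4"], p["w4"], 1, F)
        da3 = dh3 * c["m3"]
        dcat, grads["w3"], grads["b3"] = _conv_backward(
            da3, c["cols3"], p["w3"], 1, 3 * F
        )
        dh1 = dcat[..., :F]
        dh2 = _upsample2_backward(dcat[..., F:]) * c["m2"]
        dpooled, grads["w2"], grads["b2"] = _conv_backward(
            dh2, c["cols2"], p["w2"], 3, F
        )
        da1 = (dh1 + _avgpool2_backward(dpooled)) * c["m1"]
        _, grads["w1"], grads["b1"] = _conv_backward(
            da1, c["cols1"], p["w1"], 3, 3, need_dx=False
        )
        return grads

    # -- parameter plumbing -------------------------------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(params[k], dtype=np.float32).copy()

    def save(self, path) -> None:
        np.savez(path, n_out=self.n_out, width=self.width, **self.params)

    @classmethod
    def load(cls, path) -> "BlobNet":
        with np.load(path) as data:
            model = cls(int(data["n_out"]), int(data["width"]))
            model.set_params({k: data[k] for k in model.params})
        return model


class AdamW:
    """Adam with decoupled weight decay (weights shrink before the step)."""

    def __init__(
        self,
        lr: float = 3e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.1,
    ):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, g in grads.items():
            if k not in self._m:
                self._m[k] = np.zeros_like(params[k])
                self._v[k] = np.zeros_like(params[k])
            params[k] *= 1.0 - self.lr * self.weight_decay
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            m_hat = self._m[k] / (1 - b1**self.t)
            v_hat = self._v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
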