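"""Masked, positively-weighted binary cross-entropy over per-class sigmoids.

Each class channel is an independent binary problem: for logit ``z``, target
``y`` and positive weight ``w`` the per-pixel term is

    bce = -[ w * y * ln(sigmoid(z)) + (1 - y) * ln(1 - sigmoid(z)) ]

Terms where the validity mask ``lam`` is 0 are excluded; the per-class loss
is the mean of the surviving terms, and the total is the unweighted mean over
classes that contributed at least one term.  Normalising per class by its own
count of valid terms makes the loss reduce to the standard mean BCE when
``lam`` is identically 1 and keeps it invariant under batch duplication.

Everything is computed from logits in the numerically stable log-sum-exp
form; an explicit sigmoid-then-log never appears.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .catalog import ClassCatalog
from .labels import ImpliedTarget, ValidationError

__all__ = [
    "ClassWeights",
    "LossBreakdown",
    "masked_weighted_bce",
    "masked_weighted_bce_with_grad",
    "pos_weight_neg_pos_ratio",
    "pos_weight_softmax_negated",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A weight table does not cover the classes it is applied to."""


@dataclass(frozen=True)
class ClassWeights:
    """Positive multiplicative weight per class name; all weights > 0."""

    weights: dict[str, float]

    def __post_init__(self):
        for name, w in self.weights.items():
            if not np.isfinite(w) or w <= 0:
                raise ConfigurationError(f"weight for {name!r} must be > 0, got {w}")

    def __getitem__(self, name: str) -> float:
        try:
            return self.weights[name]
        except KeyError:
            raise ConfigurationError(f"no positive weight configured for {name!r}")

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self[n] for n in names], dtype=np.float64)


@dataclass(frozen=True)
class LossBreakdown:
    """Per-class losses, the count of unmasked terms each, and their mean."""

    per_class: dict[str, float]
    term_counts: dict[str, int]
    total: float


def _channel_names(catalog: ClassCatalog, has_background: bool) -> list[str]:
    names = list(catalog.foreground_names)
    if has_background:
        names.append(catalog.background_id)
    return names


def _softplus(z: np.ndarray) -> np.ndarray:
    # log(1 + exp(z)) without overflow
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def _stack_batch(
    batch_logits: Sequence[np.ndarray],
    batch_targets: Sequence[ImpliedTarget],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    if len(batch_logits) == 0 or len(batch_logits) != len(batch_targets):
        raise ValidationError(
            f"batch sizes differ or empty: {len(batch_logits)} logit stacks, "
            f"{len(batch_targets)} targets"
        )
    has_bg = batch_targets[0].has_background
    zs, ys, lams = [], [], []
    for z, t in zip(batch_logits, batch_targets):
        z = np.asarray(z, dtype=np.float64)
        if t.has_background != has_bg:
            raise ValidationError("mixed background-channel conventions in batch")
        if z.shape != t.targets.shape:
            raise ValidationError(
                f"logits {z.shape} do not match targets {t.targets.shape} "
                f"for image {t.image_id!r}"
            )
        zs.append(z)
        ys.append(t.targets)
        lams.append(t.validity)
    return (
        np.stack(zs),
        np.stack(ys).astype(np.float64),
        np.stack(lams).astype(np.float64),
        has_bg,
    )


def masked_weighted_bce(
    batch_logits: Sequence[np.ndarray],
    batch_targets: Sequence[ImpliedTarget],
    weights: ClassWeights,
    catalog: ClassCatalog,
) -> LossBreakdown:
    """Masked weighted BCE of a batch; see module docstring for the formula."""
    breakdown, _ = masked_weighted_bce_with_grad(
        batch_logits, batch_targets, weights, catalog, want_grad=False
    )
    return breakdown


def masked_weighted_bce_with_grad(
    batch_logits: Sequence[np.ndarray],
    batch_targets: Sequence[ImpliedTarget],
    weights: ClassWeights,
    catalog: ClassCatalog,
    want_grad: bool = True,
) -> tuple[LossBreakdown, np.ndarray | None]:
    """Loss plus (optionally) the gradient of the total w.r.t. every logit.

    The gradient has the stacked batch shape ``(B, C, H, W)`` and is exact
    for the normalisation used: d(total)/dz = lam * dbce/dz / (n_c * K) where
    n_c is class c's valid-term count and K the number of contributing
    classes.
    """
    z, y, lam, has_bg = _stack_batch(batch_logits, batch_targets)
    names = _channel_names(catalog, has_bg)
    if z.shape[1] != len(names):
        raise ValidationError(
            f"batch has {z.shape[1]} channels but catalog implies {len(names)}"
        )
    w = weights.as_array(names).reshape(1, -1, 1, 1)

    # bce = w*y*softplus(-z) + (1-y)*softplus(z); with softplus(z) =
    # z + softplus(-z) one evaluation suffices:
    sp_m = _softplus(-z)
    terms = sp_m * (w * y + 1.0 - y) + (1.0 - y) * z
    counts = lam.sum(axis=(0, 2, 3))  # per class over the whole batch
    sums = (terms * lam).sum(axis=(0, 2, 3))
    per_class = sums / np.maximum(1.0, counts)
    contributing = counts > 0
    n_contrib = int(contributing.sum())
    total = float(per_class[contributing].mean()) if n_contrib else 0.0

    breakdown = LossBreakdown(
        per_class={n: float(v) for n, v in zip(names, per_class)},
        term_counts={n: int(c) for n, c in zip(names, counts)},
        total=total,
    )
    if not want_grad:
        return breakdown, None

    # dbce/dz = -w*y*sigmoid(-z) + (1-y)*sigmoid(z); sigmoid via stable expit.
    # The gradient is computed in float32: it feeds float32 models, and only
    # the loss *values* need float64 precision.
    z = z.astype(np.float32)
    y = y.astype(np.float32)
    lam = lam.astype(np.float32)
    w = w.astype(np.float32)
    sig = np.empty_like(z)
    np.negative(np.abs(z), out=sig)
    np.exp(sig, out=sig)
    sig = np.where(z >= 0, 1.0 / (1.0 + sig), sig / (1.0 + sig))
    dterm = -w * y * (1.0 - sig) + (1.0 - y) * sig
    denom = np.where(contributing, counts, 1.0) * max(1, n_contrib)
    scale = np.where(contributing, 1.0 / denom, 0.0).astype(np.float32)
    grad = dterm * lam * scale.reshape(1, -1, 1, 1)
    return breakdown, grad


def pos_weight_neg_pos_ratio(
    targets: Iterable[ImpliedTarget],
    catalog: ClassCatalog,
    include_implied: bool = True,
) -> ClassWeights:
    """Negative-to-positive valid-pixel ratio per class.

    Counts only pixels with validity 1.  With ``include_implied=False`` the
    count for class c is restricted to c's own annotated frames (using the
    targets' ``annotated_channels`` metadata, falling back to "validity
    covers the whole frame" when absent), i.e. implied negatives from other
    classes' positives are ignored.  A class with zero valid positives gets
    weight 1 with a warning rather than failing, so degenerate subsets do not
    crash parameter sweeps.
    """
    targets = list(targets)
    if not targets:
        raise ValidationError("cannot compute weights from an empty collection")
    has_bg = targets[0].has_background
    names = _channel_names(catalog, has_bg)
    pos = np.zeros(len(names))
    neg = np.zeros(len(names))
    for t in targets:
        y = t.targets.astype(np.int64)
        lam = t.validity.astype(np.int64)
        if not include_implied:
            if t.annotated_channels is not None:
                full = np.zeros(lam.shape[0], dtype=np.int64)
                full[list(t.annotated_channels)] = 1
            else:
                full = lam.reshape(lam.shape[0], -1).all(axis=1).astype(np.int64)
            lam = lam * full.reshape(-1, 1, 1)
        pos += (y * lam).sum(axis=(1, 2))
        neg += ((1 - y) * lam).sum(axis=(1, 2))
    weights = {}
    for name, p, n in zip(names, pos, neg):
        if p == 0:
            warnings.warn(
                f"class {name!r} has no valid positive pixels; positive weight "
                "falls back to 1.0",
                stacklevel=2,
            )
            weights[name] = 1.0
        else:
            weights[name] = float(n / p)
            if weights[name] == 0.0:  # all-positive class: keep weight valid
                weights[name] = 1.0
    return ClassWeights(weights)


def pos_weight_softmax_negated(positive_shares: dict[str, float]) -> ClassWeights:
    """Softmax of the negated per-class positive-pixel shares.

    Used for fully supervised training (background included): classes that
    cover more of the data get smaller weights; the weights sum to 1.
    """
    names = list(positive_shares)
    s = np.array([positive_shares[n] for n in names], dtype=np.float64)
    if ((s < 0) | (s > 1)).any():
        raise ValidationError(f"positive shares must lie in [0, 1], got {s}")
    e = np.exp(-s - np.max(-s))
    w = e / e.sum()
    return ClassWeights({n: float(v) for n, v in zip(names, w)})
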