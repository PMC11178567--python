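"""Merging independent per-class sigmoid outputs into one label map.

Because each class channel is squashed by its own sigmoid there is no
sum-to-one constraint; a single per-pixel decision is made by taking the
argmax over foreground channels and falling back to background when even the
winning probability is below a threshold.  Models trained with an explicit
background channel instead let background compete in the argmax directly.
"""
from __future__ import annotations

import numpy as np

from .catalog import ClassCatalog
from .labels import ValidationError

__all__ = ["argmax_threshold_merge", "binarize_per_class", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=np.float64)
    out = np.empty_like(z)
    np.negative(np.abs(z), out=out)
    np.exp(out, out=out)
    return np.where(z >= 0, 1.0 / (1.0 + out), out / (1.0 + out))


def argmax_threshold_merge(
    probs: np.ndarray,
    catalog: ClassCatalog,
    threshold: float = 0.5,
    background_channel_present: bool = False,
) -> np.ndarray:
    """Merge a ``(C, H, W)`` stack of per-class probabilities into a label map.

    Without a background channel (implicit-labelling and ensemble modes) the
    winning foreground class ``c*`` (ties broken towards the lowest channel
    index) is assigned where ``p[c*] >= threshold``; elsewhere the background
    index.  With ``background_channel_present`` (fully supervised mode) the
    trailing channel is the background, it competes in the argmax directly
    and the threshold is ignored.
    """
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 3 or p.shape[0] == 0:
        raise ValidationError(f"probability stack must be (C, H, W), got {p.shape}")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("probabilities must lie in [0, 1]")
    expected = catalog.n_foreground + (1 if background_channel_present else 0)
    if p.shape[0] != expected:
        raise ValidationError(
            f"expected {expected} channels for this catalog, got {p.shape[0]}"
        )
    winner = p.argmax(axis=0)  # np.argmax takes the first (lowest) max index
    if background_channel_present:
        # trailing channel index equals catalog.background_index already
        return winner.astype(np.int64)
    best = np.take_along_axis(p, winner[None], axis=0)[0]
    return np.where(
        best >= threshold, winner, catalog.background_index
    ).astype(np.int64)


def binarize_per_class(
    labels: np.ndarray, catalog: ClassCatalog
) -> dict[str, np.ndarray]:
    """Split a label map into one disjoint binary mask per catalogue class.

    Includes a mask for the background id; the masks tile the grid.
    """
    lm = np.asarray(labels)
    if lm.ndim != 2:
        raise ValidationError(f"label map must be 2-D, got {lm.shape}")
    if lm.min(initial=0) < 0 or lm.max(initial=0) > catalog.background_index:
        raise ValidationError("label map contains indices outside the catalog")
    masks = {
        name: (lm == i).astype(np.uint8)
        for i, name in enumerate(catalog.foreground_names)
    }
    masks[catalog.background_id] = (lm == catalog.background_index).astype(np.uint8)
    return masks
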