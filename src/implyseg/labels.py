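"""Partial annotations and mutual-exclusion label implication.

A binary-annotated frame tells us where one class is and is not.  Under the
assumption that every pixel belongs to exactly one class, a positive
annotation of one class additionally implies a *negative* annotation of every
other class at the same pixel.  The negative region of a binary mask, on the
other hand, says nothing about the remaining classes — those pixels stay
*unknown* for them and must be excluded from any loss.

This module represents both kinds of raw annotation and converts them into
:class:`ImpliedTarget` objects: per-class {0,1} target grids ``y`` paired
with per-class {0,1} validity grids ``lam`` (the loss mask), which is the
trainable representation of partial knowledge used throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import ClassCatalog

__all__ = [
    "BinarySampleAnnotation",
    "MultiClassAnnotation",
    "ImpliedTarget",
    "imply_from_binary",
    "imply_from_multiclass",
    "imply_masking_only",
    "check_mutual_exclusion",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised for malformed annotation grids (non-binary values, bad shapes)."""


def _as_binary_mask(mask) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        bad = np.unique(arr[~np.isin(arr, (0, 1))])
        raise ValidationError(f"mask values must be exactly 0 or 1, found {bad}")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class BinarySampleAnnotation:
    """One frame annotated with a binary mask for exactly one class."""

    image_id: str
    annotated_class: str
    mask: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mask", _as_binary_mask(self.mask))


@dataclass(frozen=True)
class MultiClassAnnotation:
    """One fully annotated frame: every pixel carries exactly one class index.

    Background is encoded as its own index (``catalog.background_index``), so
    mutual exclusivity holds by construction.
    """

    image_id: str
    label_map: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.label_map)
        if arr.ndim != 2:
            raise ValidationError(f"label map must be 2-D, got shape {arr.shape}")
        object.__setattr__(self, "label_map", arr.astype(np.int64))

    def validate(self, catalog: ClassCatalog) -> None:
        hi = int(self.label_map.max(initial=0))
        lo = int(self.label_map.min(initial=0))
        if lo < 0 or hi > catalog.background_index:
            raise ValidationError(
                f"label indices [{lo}, {hi}] out of range; "
                f"catalog allows 0..{catalog.background_index}"
            )


@dataclass(frozen=True)
class ImpliedTarget:
    """Per-class targets ``y`` and validity masks ``lam`` for one frame.

    ``targets`` and ``validity`` are ``(C, H, W)`` uint8 stacks ordered by the
    catalogue; if ``has_background`` an extra trailing channel holds the
    background pair.  Wherever ``validity == 0`` the target is unknowable; it
    is canonically stored as 0 there so array equality is well-defined.
    Invariant: at any pixel at most one class has ``target = 1`` and
    ``validity = 1``.
    """

    image_id: str
    targets: np.ndarray
    validity: np.ndarray
    has_background: bool = False
    annotated_channels: tuple[int, ...] | None = None
    """Channel indices directly annotated on this frame (as opposed to only
    carrying implied negatives); ``None`` when unknown."""

    def __post_init__(self):
        t = np.asarray(self.targets, dtype=np.uint8)
        v = np.asarray(self.validity, dtype=np.uint8)
        if t.shape != v.shape or t.ndim != 3:
            raise ValidationError(
                f"targets {t.shape} and validity {v.shape} must be equal (C, H, W)"
            )
        t = t * v  # canonical form: masked-out targets stored as 0
        object.__setattr__(self, "targets", t)
        object.__setattr__(self, "validity", v)

    @property
    def n_channels(self) -> int:
        return self.targets.shape[0]


def imply_from_binary(
    sample: BinarySampleAnnotation, catalog: ClassCatalog
) -> ImpliedTarget:
    """Expand a single-class binary mask into per-class targets via implication.

    The annotated class keeps its full mask (its positives *and* negatives are
    known, so its validity is 1 everywhere).  Every other foreground class
    receives an implied negative exactly where the annotated class is
    positive; everywhere else its status is unknown (validity 0).  No
    background channel is produced: the binary background region carries no
    information about the other classes.
    """
    c0 = catalog.index_of(sample.annotated_class)
    mask = sample.mask
    C = catalog.n_foreground
    targets = np.zeros((C,) + mask.shape, dtype=np.uint8)
    validity = np.broadcast_to(mask, (C,) + mask.shape).copy()
    targets[c0] = mask
    validity[c0] = 1
    return ImpliedTarget(
        sample.image_id, targets, validity,
        has_background=False, annotated_channels=(c0,),
    )


def imply_masking_only(
    sample: BinarySampleAnnotation, catalog: ClassCatalog
) -> ImpliedTarget:
    """Ablation of :func:`imply_from_binary` without implied negatives.

    The annotated class channel is identical to :func:`imply_from_binary`;
    every other class is fully unknown (validity 0 everywhere), i.e. only the
    loss masking survives and no cross-class information is used.
    """
    c0 = catalog.index_of(sample.annotated_class)
    mask = sample.mask
    C = catalog.n_foreground
    targets = np.zeros((C,) + mask.shape, dtype=np.uint8)
    validity = np.zeros_like(targets)
    targets[c0] = mask
    validity[c0] = 1
    return ImpliedTarget(
        sample.image_id, targets, validity,
        has_background=False, annotated_channels=(c0,),
    )


def imply_from_multiclass(
    ann: MultiClassAnnotation,
    catalog: ClassCatalog,
    include_background: bool = False,
) -> ImpliedTarget:
    """One-hot expansion of a fully annotated label map (validity 1 everywhere)."""
    ann.validate(catalog)
    C = catalog.n_foreground + (1 if include_background else 0)
    lm = ann.label_map
    targets = np.zeros((C,) + lm.shape, dtype=np.uint8)
    for c in range(catalog.n_foreground):
        targets[c] = lm == c
    if include_background:
        targets[catalog.n_foreground] = lm == catalog.background_index
    validity = np.ones_like(targets)
    return ImpliedTarget(
        ann.image_id, targets, validity,
        has_background=include_background, annotated_channels=tuple(range(C)),
    )


def check_mutual_exclusion(
    samples: list[BinarySampleAnnotation],
) -> dict[tuple[str, str], int]:
    """Count overlapping positive pixels between every pair of class masks.

    All samples must describe the same frame.  Returns a dict keyed by the
    (sorted) class-name pair with the number of pixels positive in both
    masks; an empty dict means the masks are mutually exclusive.
    """
    if not samples:
        return {}
    image_id = samples[0].image_id
    shape = samples[0].mask.shape
    for s in samples:
        if s.image_id != image_id:
            raise ValidationError(
                f"samples mix image ids {image_id!r} and {s.image_id!r}"
            )
        if s.mask.shape != shape:
            raise ValidationError(
                f"mask shape {s.mask.shape} differs from {shape} on {image_id!r}"
            )
    report: dict[tuple[str, str], int] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            overlap = int(np.logical_and(a.mask, b.mask).sum())
            if overlap:
                key = tuple(sorted((a.annotated_class, b.annotated_class)))
                report[key] = report.get(key, 0) + overlap
    return report
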