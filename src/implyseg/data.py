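"""In-memory dataset containers shared by the generator, loaders and trainers.

A :class:`SegmentationDataset` holds a catalogue plus named subsets.  A
*binary* subset annotates exactly one class per frame (one binary mask); a
*multiclass* subset carries a full label map per frame.  Every frame belongs
to one of the splits ``train``/``val``/``test``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from skimage.transform import resize as _sk_resize

from .catalog import ClassCatalog
from .labels import (
    BinarySampleAnnotation,
    MultiClassAnnotation,
    ValidationError,
)
from .prediction import binarize_per_class

SPLITS = ("train", "val", "test")

__all__ = ["Frame", "Subset", "SegmentationDataset", "EvalSample", "SPLITS"]


@dataclass
class Frame:
    """One image with its (partial or full) annotation and split label."""

    image_id: str
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    annotation: BinarySampleAnnotation | MultiClassAnnotation
    split: str

    def __post_init__(self):
        img = np.asarray(self.image, dtype=np.float32)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValidationError(f"image must be (H, W, 3), got {img.shape}")
        if self.split not in SPLITS:
            raise ValidationError(f"split must be one of {SPLITS}, got {self.split!r}")
        self.image = img


@dataclass
class Subset:
    name: str
    kind: str  # 'binary' | 'multiclass'
    annotated_class: str | None  # set for binary subsets
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self):
        if self.kind not in ("binary", "multiclass"):
            raise ValidationError(f"unknown subset kind {self.kind!r}")
        if self.kind == "binary" and not self.annotated_class:
            raise ValidationError(f"binary subset {self.name!r} needs its class")

    def split(self, split: str) -> list[Frame]:
        return [f for f in self.frames if f.split == split]


@dataclass(frozen=True)
class EvalSample:
    """A frame prepared for evaluation.

    ``class_masks`` lists exactly the classes annotated for this frame
    (one class for binary-subset frames; all classes plus background for
    fully annotated frames).  ``label_map`` is present only for fully
    annotated frames and enables pixel-confusion analysis.
    """

    image_id: str
    image: np.ndarray
    class_masks: dict[str, np.ndarray]
    label_map: np.ndarray | None = None


@dataclass
class SegmentationDataset:
    catalog: ClassCatalog
    subsets: dict[str, Subset]
    provenance: dict = field(default_factory=dict)

    def binary_subsets(self) -> dict[str, Subset]:
        return {n: s for n, s in self.subsets.items() if s.kind == "binary"}

    def multiclass_subsets(self) -> dict[str, Subset]:
        return {n: s for n, s in self.subsets.items() if s.kind == "multiclass"}

    def frames(self, kind: str | None = None, split: str | None = None) -> Iterator[Frame]:
        for s in self.subsets.values():
            if kind is not None and s.kind != kind:
                continue
            for f in s.frames:
                if split is None or f.split == split:
                    yield f

    def eval_samples(self, subset_name: str, split: str) -> list[EvalSample]:
        """Frames of one subset as evaluation samples under its protocol."""
        subset = self.subsets[subset_name]
        out = []
        for f in subset.split(split):
            if isinstance(f.annotation, BinarySampleAnnotation):
                out.append(
                    EvalSample(
                        f.image_id,
                        f.image,
                        {f.annotation.annotated_class: f.annotation.mask},
                    )
                )
            else:
                masks = binarize_per_class(f.annotation.label_map, self.catalog)
                out.append(
                    EvalSample(f.image_id, f.image, masks, f.annotation.label_map)
                )
        return out


def resize_frame_arrays(
    image: np.ndarray, masks: dict[str, np.ndarray], size: tuple[int, int]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Resize an image (bilinear) and its masks (nearest: binarity survives)."""
    h, w = size
    img = _sk_resize(image, (h, w, image.shape[2]), order=1, anti_aliasing=True)
    out_masks = {
        k: _sk_resize(m, (h, w), order=0, preserve_range=True).astype(np.uint8)
        for k, m in masks.items()
    }
    return img.astype(np.float32), out_masks
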