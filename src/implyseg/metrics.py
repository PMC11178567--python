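"""Evaluation protocol: per-image per-class dice, confusion, significance.

Dice convention: when a class occurs in neither the target nor the
prediction of a frame, the score is undefined; it is set to 1.0 because the
model behaved as expected.  Per-class scores are the mean over that class's
frames, and the overall score is the mean of the per-class means — a
two-level average that in general differs from pooling all entries.

Significance between two score tables uses the two-sided Wilcoxon
signed-rank test on paired (image, class) dice scores, per class and pooled.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ClassCatalog
from .labels import ValidationError
from .prediction import binarize_per_class

__all__ = [
    "dice_binary",
    "DiceTable",
    "build_dice_table",
    "ConfusionMatrix",
    "pixel_confusion",
    "WilcoxonResult",
    "wilcoxon_compare",
]


def dice_binary(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap of two binary masks; 1.0 when both are empty."""
    p = np.asarray(pred)
    g = np.asarray(gt)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if not np.isin(p, (0, 1)).all() or not np.isin(g, (0, 1)).all():
        raise ValidationError("dice_binary expects {0,1} masks")
    p_sum = int(p.sum())
    g_sum = int(g.sum())
    if p_sum + g_sum == 0:
        return 1.0
    inter = int(np.logical_and(p, g).sum())
    return 2.0 * inter / (p_sum + g_sum)


@dataclass(frozen=True)
class DiceTable:
    """Per-(image, class) dice scores with the two-level aggregation."""

    frame: pd.DataFrame  # columns: image_id, class, dice

    def __post_init__(self):
        required = {"image_id", "class", "dice"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(f"DiceTable frame needs columns {sorted(required)}")

    def per_class_mean(self) -> pd.Series:
        return self.frame.groupby("class", sort=False)["dice"].mean()

    def overall_mean(self) -> float:
        """Mean of the per-class means (not the mean of all entries)."""
        return float(self.per_class_mean().mean())

    def scores_for(self, cls: str) -> pd.Series:
        sub = self.frame[self.frame["class"] == cls]
        return sub.set_index("image_id")["dice"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DiceTable":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)


def build_dice_table(
    predictions: Mapping[str, np.ndarray],
    ground_truth: Mapping[str, Mapping[str, np.ndarray]],
    catalog: ClassCatalog,
) -> DiceTable:
    """Score predicted label maps against per-image annotated class masks.

    ``ground_truth`` maps image_id -> {class name -> binary mask} and lists
    *only* the classes annotated for that image: a binary-subset frame
    contributes a single entry (its own class), a fully annotated frame one
    entry per class including the background id.  A missing prediction for an
    annotated image is an error.
    """
    rows = []
    for image_id, class_masks in ground_truth.items():
        if image_id not in predictions:
            raise ValidationError(f"no prediction supplied for image {image_id!r}")
        if not class_masks:
            raise ValidationError(f"image {image_id!r} has no annotated classes")
        pred_masks = binarize_per_class(predictions[image_id], catalog)
        for cls, gt_mask in class_masks.items():
            if cls not in pred_masks:
                raise ValidationError(f"class {cls!r} not in catalog")
            rows.append(
                {
                    "image_id": image_id,
                    "class": cls,
                    "dice": dice_binary(pred_masks[cls], gt_mask),
                }
            )
    return DiceTable(pd.DataFrame(rows, columns=["image_id", "class", "dice"]))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Pixel counts of (true class row, predicted class column)."""

    counts: pd.DataFrame  # square, indexed by class names incl. background

    def normalized(self) -> pd.DataFrame:
        """Row-normalised view; empty rows stay all-zero."""
        sums = self.counts.sum(axis=1)
        out = self.counts.div(sums.where(sums > 0, other=1.0), axis=0)
        return out

    def count(self, true_cls: str, pred_cls: str) -> int:
        return int(self.counts.loc[true_cls, pred_cls])

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if not self.counts.index.equals(other.counts.index):
            raise ValidationError("confusion matrices cover different classes")
        return ConfusionMatrix(self.counts + other.counts)

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def pixel_confusion(
    pred: np.ndarray, gt: np.ndarray, catalog: ClassCatalog
) -> ConfusionMatrix:
    """Count pixels per (ground-truth class, predicted class) pair."""
    p = np.asarray(pred).ravel()
    g = np.asarray(gt).ravel()
    if p.shape != g.shape:
        raise ValidationError("prediction and ground truth shapes differ")
    k = catalog.background_index + 1
    if p.min(initial=0) < 0 or p.max(initial=0) >= k or g.max(initial=0) >= k:
        raise ValidationError("label indices outside the catalog")
    flat = np.bincount(g * k + p, minlength=k * k).reshape(k, k)
    names = list(catalog.foreground_names) + [catalog.background_id]
    return ConfusionMatrix(pd.DataFrame(flat, index=names, columns=names))


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided signed-rank p-value with a degeneracy flag.

    ``degenerate`` means every paired difference was zero, in which case the
    test is undefined and the p-value is reported as 1.0 by convention.
    """

    p_value: float
    degenerate: bool
    n_effective: int  # pairs remaining after dropping zero differences

    @property
    def significant_05(self) -> bool:
        return not self.degenerate and self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return not self.degenerate and self.p_value < 0.01


def _exact_two_sided_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p over all 2^n equally likely sign patterns.

    Ranks of |d| (midranks for ties) are doubled to stay integer; the null
    distribution of the positive-rank sum W is built by dynamic programming
    and the p-value is the probability of a deviation from the (symmetric)
    null mean at least as large as the observed one.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    w_obs = int(r2[d > 0].sum())
    dev = abs(2 * w_obs - total)  # doubled distance from the null mean total/2
    support = np.arange(total + 1)
    tail = np.abs(2 * support - total) >= dev
    return float(counts[tail].sum() / counts.sum())


def _signed_rank(a: np.ndarray, b: np.ndarray) -> WilcoxonResult:
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    d = d[d != 0.0]
    if d.size == 0:
        return WilcoxonResult(1.0, True, 0)
    if d.size <= 25:
        p = _exact_two_sided_p(d)
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        p = float(res.pvalue)
    return WilcoxonResult(min(1.0, p), False, int(d.size))


def wilcoxon_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    mode: str = "pooled",
    classes: Sequence[str] | None = None,
) -> WilcoxonResult | dict[str, WilcoxonResult]:
    """Two-sided Wilcoxon signed-rank test on paired dice scores.

    ``mode='pooled'`` tests all aligned pairs at once; ``mode='per_class'``
    requires a parallel ``classes`` sequence and returns one result per
    class over that class's pairs.  Zero differences are dropped; the exact
    null distribution is used for up to 25 effective pairs, the normal
    approximation with continuity correction above that.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("paired score lists must be 1-D, equal length, non-empty")
    if mode == "pooled":
        return _signed_rank(a, b)
    if mode == "per_class":
        if classes is None or len(classes) != a.size:
            raise ValidationError("per_class mode needs one class label per pair")
        cls_arr = np.asarray(classes)
        out = {}
        for cls in dict.fromkeys(classes):  # preserve first-seen order
            sel = cls_arr == cls
            out[str(cls)] = _signed_rank(a[sel], b[sel])
        return out
    raise ValidationError(f"unknown mode {mode!r}; use 'pooled' or 'per_class'")
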