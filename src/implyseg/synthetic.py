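"""Synthetic laparoscopy-like scenes with mutually exclusive organ blobs.

The generator emulates the structure of a multi-subset anatomy dataset: a
pool of scenes is painted as random ellipse "organs" over a dark textured
background, then partitioned into several *binary* subsets (each frame
annotated for one class only, sampled with a bias towards frames where that
organ is prominent) plus one *multiclass* subset centred on a designated
class, whose frames keep the full label map.

Mutual exclusivity holds by construction: blobs are painted back-to-front,
later blobs overwriting earlier ones, and the label map records the final
owner of each pixel.  A *confusable pair* of classes has deliberately
overlapping colour distributions, emulating organ pairs that look alike;
separating them requires cross-class (implied-negative) supervision.

All randomness derives from ``(spec, master seed)`` through per-scene
counter seeds, so identical inputs give bit-identical datasets.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse

from .catalog import ClassCatalog
from .data import Frame, SegmentationDataset, Subset
from .labels import BinarySampleAnnotation, MultiClassAnnotation

__all__ = [
    "DEFAULT_CATALOG",
    "SceneSpec",
    "GenerationError",
    "generate_scene",
    "generate_scene_pool",
    "make_binary_subsets",
    "make_multiclass_subset",
    "make_dataset",
    "nearest_mean_color_accuracy",
]


class GenerationError(RuntimeError):
    """Raised when a dataset cannot be assembled from the available scenes."""


DEFAULT_CATALOG = ClassCatalog(
    (
        "abdominal_wall",
        "colon",
        "liver",
        "pancreas",
        "small_intestine",
        "stomach",
    )
)

# Mean RGB per organ-like class, values in [0, 1].  The colon and small
# intestine are given nearby colours and are additionally pulled together by
# the confusable-pair mechanism below.
_DEFAULT_COLORS = {
    "abdominal_wall": (0.85, 0.62, 0.52),
    "colon": (0.78, 0.52, 0.40),
    "liver": (0.45, 0.16, 0.12),
    "pancreas": (0.90, 0.78, 0.50),
    "small_intestine": (0.68, 0.46, 0.36),
    "stomach": (0.82, 0.38, 0.42),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic mutually exclusive organ-blob world.

    ``color_jitter`` is a per-blob offset applied to the whole blob (organs
    vary between frames), ``noise_sigma`` per-pixel sensor-like noise.
    ``confusable_pairs`` lists class pairs whose mean colours are pulled
    towards their midpoint by ``confusion_strength`` so their appearance
    distributions overlap.  ``seed`` is the master seed; scene ``i`` uses the
    counter seed ``(seed, i)``, so generation is a pure function of the spec.
    """

    height: int = 64
    width: int = 64
    catalog: ClassCatalog = DEFAULT_CATALOG
    class_colors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COLORS)
    )
    background_color: tuple[float, float, float] = (0.24, 0.10, 0.12)
    color_jitter: float = 0.04
    noise_sigma: float = 0.03
    confusable_pairs: tuple[tuple[str, str], ...] = (("colon", "small_intestine"),)
    confusion_strength: float = 0.5
    blob_count_range: tuple[int, int] = (2, 5)
    # Semi-axis as a fraction of min(H, W).  The upper end allows close-up
    # frames where one organ dominates the view, so organ-focused subset
    # selection has genuinely organ-dominant frames to prefer.
    blob_size_range: tuple[float, float] = (0.10, 0.55)
    seed: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise GenerationError("grid dimensions must be positive")
        if self.blob_count_range[0] > 0 and (
            self.blob_size_range[0] * min(self.height, self.width) < 1.0
        ):
            raise GenerationError(
                "grid too small for the minimum blob size "
                f"({self.blob_size_range[0]} of {min(self.height, self.width)} px)"
            )
        for a, b in self.confusable_pairs:
            if a not in self.catalog or b not in self.catalog:
                raise GenerationError(f"confusable pair ({a!r}, {b!r}) not in catalog")
        for name in self.catalog.foreground_names:
            if name not in self.class_colors:
                raise GenerationError(f"no colour configured for class {name!r}")

    def effective_colors(self) -> dict[str, np.ndarray]:
        """Class colours after pulling confusable pairs towards each other."""
        colors = {k: np.asarray(v, dtype=np.float64) for k, v in self.class_colors.items()}
        for a, b in self.confusable_pairs:
            mid = 0.5 * (colors[a] + colors[b])
            s = self.confusion_strength
            colors[a] = (1 - s) * colors[a] + s * mid
            colors[b] = (1 - s) * colors[b] + s * mid
        return colors


def generate_scene(
    spec: SceneSpec, index: int
) -> tuple[np.ndarray, MultiClassAnnotation]:
    """Render scene ``index``: an (H, W, 3) float image plus its label map.

    Blobs are painted back-to-front (later blobs overwrite earlier ones), so
    the returned label map is mutually exclusive by construction.
    """
    rng = np.random.default_rng([spec.seed, int(index)])
    h, w = spec.height, spec.width
    colors = spec.effective_colors()
    catalog = spec.catalog

    label_map = np.full((h, w), catalog.background_index, dtype=np.int64)
    image = np.empty((h, w, 3), dtype=np.float64)
    image[:] = np.asarray(spec.background_color)

    lo, hi = spec.blob_count_range
    n_blobs = int(rng.integers(lo, hi + 1))
    min_dim = min(h, w)
    for _ in range(n_blobs):
        cls_idx = int(rng.integers(0, catalog.n_foreground))
        name = catalog.foreground_names[cls_idx]
        cy = rng.uniform(0, h)
        cx = rng.uniform(0, w)
        ry = rng.uniform(*spec.blob_size_range) * min_dim
        rx = rng.uniform(*spec.blob_size_range) * min_dim
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, ry, rx, shape=(h, w), rotation=rot)
        if rr.size == 0:
            continue
        blob_color = colors[name] + rng.normal(0.0, spec.color_jitter, size=3)
        label_map[rr, cc] = cls_idx
        image[rr, cc] = blob_color

    image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    np.clip(image, 0.0, 1.0, out=image)
    return image.astype(np.float32), MultiClassAnnotation(
        f"scene_{index:05d}", label_map
    )


def generate_scene_pool(
    spec: SceneSpec, n_scenes: int
) -> list[tuple[np.ndarray, MultiClassAnnotation]]:
    """Scenes 0..n-1 of the spec's deterministic sequence."""
    return [generate_scene(spec, i) for i in range(n_scenes)]


def _area_fractions(
    scenes: list[tuple[np.ndarray, MultiClassAnnotation]], cls_idx: int
) -> np.ndarray:
    return np.array(
        [float((ann.label_map == cls_idx).mean()) for _, ann in scenes]
    )


def _focus_exponent(focus_bias: float) -> float:
    # focus_bias in [0, 1): sampling weight ~ area^k with k growing without
    # bound as the bias approaches 1; focus_bias >= 1 means strict top-area
    # rank selection.
    return 6.0 * focus_bias / max(1e-9, 1.0 - focus_bias)


def _select_scenes(
    candidates: np.ndarray,  # indices into the pool
    areas: np.ndarray,  # matching area fractions
    count: int,
    focus_bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if candidates.size < count:
        raise GenerationError(
            f"only {candidates.size} candidate scenes for a subset of {count}"
        )
    if focus_bias >= 1.0:
        order = np.argsort(-areas, kind="stable")
        return candidates[order[:count]]
    if focus_bias <= 0.0:
        return rng.choice(candidates, size=count, replace=False)
    weights = np.power(np.maximum(areas, 1e-12), _focus_exponent(focus_bias))
    weights = weights / weights.sum()
    return rng.choice(candidates, size=count, replace=False, p=weights)


def _split_frames(n_train: int, n_val: int, n_test: int) -> list[str]:
    return ["train"] * n_train + ["val"] * n_val + ["test"] * n_test


def make_binary_subsets(
    scenes: list[tuple[np.ndarray, MultiClassAnnotation]],
    catalog: ClassCatalog,
    counts: tuple[int, int, int] = (200, 50, 50),
    focus_bias: float = 0.7,
    seed: int = 0,
    used: set[int] | None = None,
) -> dict[str, Subset]:
    """One binary subset per class, biased towards frames where it is large.

    Each subset draws (without replacement, disjoint from other subsets) from
    the pool scenes that contain its class, preferring large-area frames
    according to ``focus_bias``; each chosen scene contributes a single
    binary annotation for that class only.  ``used`` (shared across calls)
    tracks scenes already claimed.
    """
    rng = np.random.default_rng([seed, 1])
    used = used if used is not None else set()
    total = sum(counts)
    subsets: dict[str, Subset] = {}
    for cls_idx, name in enumerate(catalog.foreground_names):
        areas_all = _area_fractions(scenes, cls_idx)
        candidates = np.array(
            [i for i in range(len(scenes)) if areas_all[i] > 0 and i not in used],
            dtype=np.int64,
        )
        if candidates.size == 0:
            raise GenerationError(f"class {name!r} never present in the scene pool")
        chosen = _select_scenes(candidates, areas_all[candidates], total, focus_bias, rng)
        used.update(int(i) for i in chosen)
        chosen = chosen[rng.permutation(chosen.size)]  # decorrelate split from area
        frames = []
        for scene_i, split in zip(chosen, _split_frames(*counts)):
            image, ann = scenes[scene_i]
            mask = (ann.label_map == cls_idx).astype(np.uint8)
            frames.append(
                Frame(
                    ann.image_id,
                    image,
                    BinarySampleAnnotation(ann.image_id, name, mask),
                    split,
                )
            )
        subsets[name] = Subset(name, "binary", name, frames)
    return subsets


def make_multiclass_subset(
    scenes: list[tuple[np.ndarray, MultiClassAnnotation]],
    catalog: ClassCatalog,
    center_class: str,
    counts: tuple[int, int, int] = (200, 50, 50),
    seed: int = 0,
    used: set[int] | None = None,
    name: str = "multiclass",
) -> Subset:
    """A fully annotated subset whose frames all contain ``center_class``."""
    rng = np.random.default_rng([seed, 2])
    used = used if used is not None else set()
    cls_idx = catalog.index_of(center_class)
    total = sum(counts)
    candidates = np.array(
        [
            i
            for i in range(len(scenes))
            if i not in used and (scenes[i][1].label_map == cls_idx).any()
        ],
        dtype=np.int64,
    )
    if candidates.size < total:
        raise GenerationError(
            f"only {candidates.size} unused scenes contain {center_class!r}, "
            f"need {total}"
        )
    chosen = rng.choice(candidates, size=total, replace=False)
    used.update(int(i) for i in chosen)
    frames = [
        Frame(scenes[i][1].image_id, scenes[i][0], scenes[i][1], split)
        for i, split in zip(chosen, _split_frames(*counts))
    ]
    return Subset(name, "multiclass", None, frames)


def make_dataset(
    spec: SceneSpec,
    counts: tuple[int, int, int] = (200, 50, 50),
    focus_bias: float = 0.7,
    center_class: str = "stomach",
    pool_size: int | None = None,
) -> SegmentationDataset:
    """Full synthetic dataset: one binary subset per class + one multiclass.

    ``pool_size`` defaults to enough scenes for every subset to find
    class-containing frames comfortably (the pool is shared; subsets are
    scene-disjoint, like separate recordings of the same world).
    """
    total = sum(counts)
    n_subsets = spec.catalog.n_foreground + 1
    if pool_size is None:
        pool_size = int(3.0 * total * n_subsets)
    scenes = generate_scene_pool(spec, pool_size)
    used: set[int] = set()
    subsets = make_binary_subsets(
        scenes, spec.catalog, counts, focus_bias, seed=spec.seed, used=used
    )
    mc = make_multiclass_subset(
        scenes, spec.catalog, center_class, counts, seed=spec.seed, used=used
    )
    subsets[mc.name] = mc
    return SegmentationDataset(
        catalog=spec.catalog,
        subsets=subsets,
        provenance={
            "generator": "implyseg.synthetic",
            "seed": spec.seed,
            "counts": list(counts),
            "focus_bias": focus_bias,
            "center_class": center_class,
            "pool_size": pool_size,
        },
    )


def nearest_mean_color_accuracy(
    scenes: list[tuple[np.ndarray, MultiClassAnnotation]], catalog: ClassCatalog
) -> float:
    """Per-pixel accuracy of a nearest-mean-colour classifier on the scenes.

    A deliberately crude oracle: it fits one mean colour per class (plus
    background) from the labelled pixels and assigns each pixel to the
    nearest mean.  Used as a separability floor — trained models should do at
    least this well above chance.
    """
    k = catalog.background_index + 1
    sums = np.zeros((k, 3))
    counts = np.zeros(k)
    for image, ann in scenes:
        flat = ann.label_map.ravel()
        px = image.reshape(-1, 3).astype(np.float64)
        for c in range(k):
            sel = flat == c
            sums[c] += px[sel].sum(axis=0)
            counts[c] += sel.sum()
    means = sums / np.maximum(1.0, counts)[:, None]
    correct = 0
    total = 0
    for image, ann in scenes:
        px = image.reshape(-1, 3).astype(np.float64)
        d = ((px[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
        pred = d.argmin(axis=1)
        correct += int((pred == ann.label_map.ravel()).sum())
        total += pred.size
    return correct / total
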