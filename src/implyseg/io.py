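"""On-disk dataset layout, manifest, and configuration files.

Layout (all plain, diff-able formats)::

    root/
      manifest.json
      <subset>/<image_id>/image.png          # 8-bit RGB
      <subset>/<image_id>/mask_<class>.png   # 8-bit grey, 0 = neg, 255 = pos

Binary subsets store one mask (their annotated class).  Multiclass subsets
store one mask per foreground class plus the background, from which the
label map is reassembled at load time (mutual exclusivity and full coverage
are validated).  The manifest records the catalogue, subset structure,
splits and generator provenance; it is byte-identical for identical inputs.

A note on adapting real data: a published multi-subset anatomy dataset laid
out as ``<subset>/<sequence>/<frame>.png`` with per-frame binary masks can
be mapped onto this manifest by listing each frame under its subset with its
mask path and split; only the manifest needs to be written, images can stay
in place via relative paths.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .catalog import ClassCatalog
from .data import Frame, SegmentationDataset, Subset, resize_frame_arrays
from .labels import (
    BinarySampleAnnotation,
    MultiClassAnnotation,
    ValidationError,
)

__all__ = [
    "write_dataset",
    "load_dataset",
    "load_config",
    "manifest_from_organ_layout",
    "DatasetLoadError",
]

MANIFEST_NAME = "manifest.json"


class DatasetLoadError(ValueError):
    """A dataset on disk is missing files or violates the format contract."""


def _mask_to_png(mask: np.ndarray) -> np.ndarray:
    return (np.asarray(mask, dtype=np.uint8) * 255).astype(np.uint8)


def _png_to_mask(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim != 2:
        raise DatasetLoadError(f"mask {path} must be single-channel, got {arr.shape}")
    values = np.unique(arr)
    if not np.isin(values, (0, 255)).all():
        raise DatasetLoadError(
            f"mask {path} has values {values.tolist()}; only 0 and 255 are allowed"
        )
    return (arr == 255).astype(np.uint8)


def write_dataset(dataset: SegmentationDataset, root) -> Path:
    """Write images, masks and the manifest; returns the manifest path."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    catalog = dataset.catalog
    manifest = {
        "catalog": {
            "foreground_names": list(catalog.foreground_names),
            "background_id": catalog.background_id,
        },
        "provenance": dataset.provenance or {"source": "external"},
        "subsets": [],
    }
    for name in sorted(dataset.subsets):
        subset = dataset.subsets[name]
        entries = []
        for frame in sorted(subset.frames, key=lambda f: f.image_id):
            fdir = root / name / frame.image_id
            fdir.mkdir(parents=True, exist_ok=True)
            img8 = np.clip(np.rint(frame.image * 255), 0, 255).astype(np.uint8)
            iio.imwrite(fdir / "image.png", img8)
            masks = {}
            if isinstance(frame.annotation, BinarySampleAnnotation):
                cls = frame.annotation.annotated_class
                masks[cls] = frame.annotation.mask
            else:
                lm = frame.annotation.label_map
                for i, cls in enumerate(catalog.foreground_names):
                    masks[cls] = (lm == i).astype(np.uint8)
                masks[catalog.background_id] = (
                    lm == catalog.background_index
                ).astype(np.uint8)
            mask_paths = {}
            for cls in sorted(masks):
                rel = f"{name}/{frame.image_id}/mask_{cls}.png"
                iio.imwrite(root / rel, _mask_to_png(masks[cls]))
                mask_paths[cls] = rel
            entries.append(
                {
                    "image_id": frame.image_id,
                    "split": frame.split,
                    "image": f"{name}/{frame.image_id}/image.png",
                    "masks": mask_paths,
                }
            )
        manifest["subsets"].append(
            {
                "name": name,
                "kind": subset.kind,
                "annotated_classes": (
                    [subset.annotated_class]
                    if subset.kind == "binary"
                    else list(catalog.foreground_names) + [catalog.background_id]
                ),
                "entries": entries,
            }
        )
    manifest_path = root / MANIFEST_NAME
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path


def load_dataset(root, image_size: tuple[int, int] | None = None) -> SegmentationDataset:
    """Load a dataset written by :func:`write_dataset` (or a compatible
    manifest).  Masks are validated to be strictly 0/255 PNGs of the image
    shape; ``image_size`` optionally resizes (bilinear images,
    nearest-neighbour masks, so binarity is preserved)."""
    root = Path(root)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise DatasetLoadError(f"no {MANIFEST_NAME} under {root}")
    manifest = json.loads(manifest_path.read_text())
    catalog = ClassCatalog(
        manifest["catalog"]["foreground_names"],
        manifest["catalog"]["background_id"],
    )
    subsets: dict[str, Subset] = {}
    for sub in manifest["subsets"]:
        kind = sub["kind"]
        if kind == "binary" and len(sub["annotated_classes"]) != 1:
            raise DatasetLoadError(
                f"binary subset {sub['name']!r} must list exactly one class"
            )
        frames = []
        for entry in sub["entries"]:
            img_path = root / entry["image"]
            if not img_path.exists():
                raise DatasetLoadError(f"missing image file: {img_path}")
            image = iio.imread(img_path).astype(np.float32) / 255.0
            masks = {}
            for cls, rel in entry["masks"].items():
                mask_path = root / rel
                if not mask_path.exists():
                    raise DatasetLoadError(f"missing mask file: {mask_path}")
                mask = _png_to_mask(iio.imread(mask_path), str(mask_path))
                if mask.shape != image.shape[:2]:
                    raise DatasetLoadError(
                        f"mask {mask_path} shape {mask.shape} does not match "
                        f"image shape {image.shape[:2]}"
                    )
                masks[cls] = mask
            if image_size is not None:
                image, masks = resize_frame_arrays(image, masks, image_size)
            if kind == "binary":
                cls = sub["annotated_classes"][0]
                annotation = BinarySampleAnnotation(
                    entry["image_id"], cls, masks[cls]
                )
            else:
                annotation = _masks_to_label_map(
                    entry["image_id"], masks, catalog, str(img_path)
                )
            frames.append(Frame(entry["image_id"], image, annotation, entry["split"]))
        subsets[sub["name"]] = Subset(
            sub["name"],
            kind,
            sub["annotated_classes"][0] if kind == "binary" else None,
            frames,
        )
    return SegmentationDataset(catalog, subsets, manifest.get("provenance", {}))


def _masks_to_label_map(
    image_id: str,
    masks: dict[str, np.ndarray],
    catalog: ClassCatalog,
    where: str,
) -> MultiClassAnnotation:
    shape = next(iter(masks.values())).shape
    stack = np.zeros(shape, dtype=np.int64)
    coverage = np.zeros(shape, dtype=np.int64)
    for cls, mask in masks.items():
        idx = (
            catalog.background_index
            if cls == catalog.background_id
            else catalog.index_of(cls)
        )
        stack[mask == 1] = idx
        coverage += mask
    if (coverage != 1).any():
        raise DatasetLoadError(
            f"masks of {image_id} at {where} are not a mutually exclusive "
            "partition of the frame"
        )
    return MultiClassAnnotation(image_id, stack)


def manifest_from_organ_layout(
    root,
    catalog: ClassCatalog,
    split_of=None,
) -> dict:
    """Build a manifest for a published-style single-organ directory tree.

    Adapter for datasets laid out as ``root/<organ>/<sequence>/imageNN.png``
    with a sibling ``maskNN.png`` per frame (the layout used by public
    single-organ anatomy releases; sequence folders are typically surgery
    ids).  Each ``<organ>`` folder whose name is in the catalogue becomes a
    binary subset; images stay in place and are referenced by relative path.
    ``split_of(organ, sequence, stem) -> 'train'|'val'|'test'`` assigns
    splits (default: everything ``test``, suitable for evaluation-only use).
    Multi-class folders with per-class mask naming vary between releases and
    are not mapped automatically.

    Returns the manifest as a dict; write it yourself with ``json.dump`` or
    pass the root to :func:`load_dataset` after saving.
    """
    root = Path(root)
    split_of = split_of or (lambda organ, seq, stem: "test")
    subsets = []
    for organ_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        organ = organ_dir.name
        if organ not in catalog:
            continue
        entries = []
        for seq_dir in sorted(p for p in organ_dir.iterdir() if p.is_dir()):
            for image_path in sorted(seq_dir.glob("image*.png")):
                stem = image_path.stem.replace("image", "", 1)
                mask_path = seq_dir / f"mask{stem}.png"
                if not mask_path.exists():
                    raise DatasetLoadError(f"no mask for {image_path}")
                entries.append(
                    {
                        "image_id": f"{organ}_{seq_dir.name}_{stem}",
                        "split": split_of(organ, seq_dir.name, stem),
                        "image": str(image_path.relative_to(root)),
                        "masks": {organ: str(mask_path.relative_to(root))},
                    }
                )
        if entries:
            subsets.append(
                {
                    "name": organ,
                    "kind": "binary",
                    "annotated_classes": [organ],
                    "entries": entries,
                }
            )
    return {
        "catalog": {
            "foreground_names": list(catalog.foreground_names),
            "background_id": catalog.background_id,
        },
        "provenance": {"source": "external", "adapter": "organ_layout"},
        "subsets": subsets,
    }


def load_config(path) -> dict:
    """Read a YAML (or JSON) key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return cfg
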