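"""ISIC-layout dataset indexing, 8:2 splitting, and batch loading.

Images are ``ISIC_<id>.jpg`` (or .png) with masks ``ISIC_<id>_segmentation.png``.
The random train/test split is a pure function of the sorted id set, the ratio
and the seed, so it is stable under directory-listing order; the train size is
floor(ratio·N).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["DatasetRecord", "DatasetIndex", "index_dataset", "split", "load_batch",
           "load_image", "load_mask", "save_mask"]

_IMG_RE = re.compile(r"^ISIC_(?P<id>[A-Za-z0-9]+)\.(jpg|jpeg|png)$", re.IGNORECASE)
_MASK_RE = re.compile(r"^ISIC_(?P<id>[A-Za-z0-9]+)_segmentation\.png$", re.IGNORECASE)


@dataclass
class DatasetRecord:
    id: str
    image_path: Path
    mask_path: Path
    split: str | None = None


@dataclass
class DatasetIndex:
    records: list
    exclusions: list = field(default_factory=list)
    split_seed: int | None = None

    def subset(self, which: str) -> list:
        return [r for r in self.records if r.split == which]

    @property
    def train(self) -> list:
        return self.subset("train")

    @property
    def test(self) -> list:
        return self.subset("test")

    def manifest(self) -> dict:
        return {
            "split_seed": self.split_seed,
            "records": [
                {"id": r.id, "image": str(r.image_path), "mask": str(r.mask_path), "split": r.split}
                for r in self.records
            ],
            "exclusions": list(self.exclusions),
        }

    def save_manifest(self, path):
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def index_dataset(image_dir, mask_dir=None) -> DatasetIndex:
    """Pair images and masks by their ``ISIC_<id>`` stem.

    Orphan images/masks are reported in ``exclusions`` rather than dropped
    silently; duplicate ids are a structural error.
    """
    image_dir = Path(image_dir)
    mask_dir = Path(mask_dir) if mask_dir is not None else image_dir
    if not image_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {image_dir}")
    if not mask_dir.is_dir():
        raise FileNotFoundError(f"mask directory not found: {mask_dir}")

    images: dict = {}
    for f in sorted(image_dir.iterdir()):
        m = _IMG_RE.match(f.name)
        if m:
            sid = m.group("id")
            if sid in images:
                raise ValueError(f"duplicate image id ISIC_{sid}: {images[sid].name} and {f.name}")
            images[sid] = f
    masks: dict = {}
    for f in sorted(mask_dir.iterdir()):
        m = _MASK_RE.match(f.name)
        if m:
            sid = m.group("id")
            if sid in masks:
                raise ValueError(f"duplicate mask id ISIC_{sid}")
            masks[sid] = f

    records, exclusions = [], []
    for sid in sorted(images):
        if sid in masks:
            records.append(DatasetRecord(id=sid, image_path=images[sid], mask_path=masks[sid]))
        else:
            exclusions.append(f"image without mask: {images[sid].name}")
    for sid in sorted(set(masks) - set(images)):
        exclusions.append(f"mask without image: {masks[sid].name}")
    return DatasetIndex(records=records, exclusions=exclusions)


def split(index: DatasetIndex, ratio: float = 0.8, seed: int = 0) -> DatasetIndex:
    """Assign train/test with |train| = floor(ratio·N), deterministic in (ids, ratio, seed)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    ids = sorted(r.id for r in index.records)
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(np.floor(ratio * len(ids)))
    train_ids = {ids[i] for i in order[:n_train]}
    records = [
        DatasetRecord(r.id, r.image_path, r.mask_path, "train" if r.id in train_ids else "test")
        for r in sorted(index.records, key=lambda r: r.id)
    ]
    return DatasetIndex(records=records, exclusions=list(index.exclusions), split_seed=seed)


def load_image(path, input_size=None) -> np.ndarray:
    """RGB image as float32 (3, H, W) in [0,1]; optional bilinear resize."""
    with Image.open(path) as im:
        im = im.convert("RGB")
        if input_size is not None:
            im = im.resize((input_size[1], input_size[0]), Image.BILINEAR)
        arr = np.asarray(im, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


def load_mask(path, input_size=None) -> np.ndarray:
    """Binary mask as float32 (1, H, W); 8-bit PNG thresholded at >127."""
    with Image.open(path) as im:
        im = im.convert("L")
        if input_size is not None:
            im = im.resize((input_size[1], input_size[0]), Image.NEAREST)
        arr = np.asarray(im)
    return (arr > 127).astype(np.float32)[None]


def save_mask(mask: np.ndarray, path):
    """Write a binary mask as an 8-bit 0/255 PNG."""
    arr = (np.asarray(mask).squeeze() > 0.5).astype(np.uint8) * 255
    Image.fromarray(arr).save(path)


def load_batch(records, input_size=(224, 224)):
    """Stack records into (B,3,H,W) images in [0,1] and (B,1,H,W) binary masks."""
    imgs, msks = [], []
    for r in records:
        try:
            imgs.append(load_image(r.image_path, input_size))
            msks.append(load_mask(r.mask_path, input_size))
        except OSError as e:
            raise OSError(f"failed to read record {r.id}: {e}") from e
    return np.stack(imgs), np.stack(msks)
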