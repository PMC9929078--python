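"""Image banks: the labeled-image container, manifest I/O, and train/test splitting.

A *bank* is an ordered collection of grayscale images, each paired with a
(real-valued) cell-count label.  Banks are the unit that augmentation,
subsampling and splitting act on.  On disk a bank is a directory of 16-bit
PNG files plus a CSV manifest with one row per image.

The train/test split uses the floor rule ``n_train = floor(train_fraction * N)``
with a seeded uniform shuffle; with the default 70% fraction, banks of
1,136 / 704 / 832 images split into 795/341, 492/212 and 582/250.  The split
acts on whatever bank it is given: if that bank was augmented, variants of
one source image may land on both sides.  Pass ``group_by_source=True`` to
keep all variants of a source image on the same side instead (a documented
deviation from the plain random split).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "LabeledImage",
    "Bank",
    "SplitSpec",
    "split",
    "subsample",
    "save_bank",
    "load_bank",
]

_PNG_MAX = 65535  # 16-bit storage


@dataclass
class LabeledImage:
    """One grayscale image with its (possibly rescaled) cell-count label.

    ``pixels`` is a 2-D float array in [0, 1]; ``count`` is the ground-truth
    or label-rescaled cell count (non-negative, real-valued once crops have
    rescaled it); ``transform_log`` records the transforms applied since the
    image was rendered, in order, and is append-only.
    """

    pixels: np.ndarray
    count: float
    line_tag: str = ""
    transform_log: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValidationError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.count < 0:
            raise ValidationError(f"count must be non-negative, got {self.count}")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValidationError(f"pixel values must lie in [0,1], got range [{lo}, {hi}]")

    def with_transform(self, pixels: np.ndarray, count: float, entry: tuple,
                       **meta_updates) -> "LabeledImage":
        """Return a derived image whose transform_log is extended by ``entry``."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return LabeledImage(
            pixels=pixels,
            count=count,
            line_tag=self.line_tag,
            transform_log=self.transform_log + [entry],
            meta=meta,
        )


@dataclass
class Bank:
    """An ordered collection of :class:`LabeledImage` with optional provenance."""

    items: list
    split_tag: str = "unsplit"
    manifest_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.split_tag not in ("train", "test", "unsplit"):
            raise ValidationError(f"unknown split_tag {self.split_tag!r}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def counts(self) -> np.ndarray:
        return np.array([im.count for im in self.items], dtype=float)

    def pixel_stack(self) -> np.ndarray:
        """All images stacked as (N, H, W); requires a uniform image size."""
        shapes = {im.pixels.shape for im in self.items}
        if len(shapes) > 1:
            raise ValidationError(f"bank holds mixed image sizes {sorted(shapes)}")
        return np.stack([im.pixels for im in self.items])


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split parameters: fraction assigned to training, and seed."""

    train_fraction: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValidationError(
                f"train_fraction must be in (0,1), got {self.train_fraction}")


def split(bank: Bank, spec: SplitSpec, group_by_source: bool = False) -> tuple[Bank, Bank]:
    """Partition a bank into train and test banks.

    ``n_train = floor(train_fraction * N)``; the shuffle is deterministic in
    ``spec.seed``.  With ``group_by_source`` the shuffle acts on distinct
    ``meta['source_index']`` groups and whole groups are assigned to one side
    (the train size then only approximates the floor rule).
    """
    n = len(bank)
    if n < 2:
        raise ValidationError(f"cannot split a bank of {n} image(s)")
    rng = np.random.default_rng(spec.seed)
    if group_by_source:
        groups = [im.meta.get("source_index", i) for i, im in enumerate(bank.items)]
        uniq = sorted(set(groups))
        order = rng.permutation(len(uniq))
        n_train_groups = math.floor(spec.train_fraction * len(uniq))
        train_groups = {uniq[i] for i in order[:n_train_groups]}
        train_idx = [i for i, g in enumerate(groups) if g in train_groups]
        test_idx = [i for i, g in enumerate(groups) if g not in train_groups]
    else:
        order = rng.permutation(n)
        n_train = math.floor(spec.train_fraction * n)
        train_idx = sorted(order[:n_train].tolist())
        test_idx = sorted(order[n_train:].tolist())
    train = Bank(items=[bank.items[i] for i in train_idx], split_tag="train")
    test = Bank(items=[bank.items[i] for i in test_idx], split_tag="test")
    return train, test


def subsample(bank: Bank, n: int, seed: int) -> Bank:
    """Uniform seed-deterministic subset of ``n`` images, preserving bank order."""
    if not 1 <= n <= len(bank):
        raise ValidationError(f"subsample size {n} outside [1, {len(bank)}]")
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(bank), size=n, replace=False).tolist())
    return Bank(items=[bank.items[i] for i in idx], split_tag=bank.split_tag)


# ---------------------------------------------------------------------------
# Manifest I/O

_CORE_COLUMNS = ["filename", "count", "line_tag"]


def save_bank(bank: Bank, out_dir: str, prefix: str = "img") -> str:
    """Write a bank as 16-bit PNGs plus ``manifest.csv``; returns the manifest path.

    Metadata keys present on any image become extra manifest columns.
    """
    os.makedirs(out_dir, exist_ok=True)
    meta_cols: list[str] = []
    for im in bank.items:
        for k in im.meta:
            if k not in meta_cols:
                meta_cols.append(k)
    rows = []
    for i, im in enumerate(bank.items):
        fname = f"{prefix}_{i:05d}.png"
        arr = np.clip(np.round(im.pixels.astype(np.float64) * _PNG_MAX), 0, _PNG_MAX)
        iio.imwrite(os.path.join(out_dir, fname), arr.astype(np.uint16))
        row = {"filename": fname, "count": float(im.count), "line_tag": im.line_tag}
        for k in meta_cols:
            row[k] = im.meta.get(k, "")
        rows.append(row)
    manifest = pd.DataFrame(rows, columns=_CORE_COLUMNS + meta_cols)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    bank.manifest_path = manifest_path
    return manifest_path


def load_bank(manifest_path: str) -> Bank:
    """Load a bank from a manifest written by :func:`save_bank`."""
    if not os.path.exists(manifest_path):
        raise ValidationError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    missing = [c for c in _CORE_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing column(s) {missing}")
    if manifest["filename"].duplicated().any():
        dup = manifest["filename"][manifest["filename"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate filename in manifest: {dup!r}")
    base = os.path.dirname(manifest_path)
    meta_cols = [c for c in manifest.columns if c not in _CORE_COLUMNS]
    items = []
    for i, row in manifest.iterrows():
        count = float(row["count"])
        if count < 0:
            raise ValidationError(f"manifest row {i}: negative count {count}")
        path = os.path.join(base, str(row["filename"]))
        if not os.path.exists(path):
            raise ValidationError(f"manifest row {i}: image file missing: {path}")
        arr = iio.imread(path)
        pixels = arr.astype(np.float32) / _PNG_MAX
        meta = {c: row[c] for c in meta_cols}
        items.append(LabeledImage(pixels=pixels, count=count,
                                  line_tag=str(row["line_tag"]), meta=meta))
    return Bank(items=items, manifest_path=manifest_path)
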