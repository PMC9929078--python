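"""Two-stage bank augmentation with count-label rescaling.

Stage 1 (scaling): each image is centre-cropped to 100/75/50/25% of its
linear size, and its count label is rescaled for the reduced field of view.
Stage 2 (orientation): each crop is flipped horizontally, vertically, and
both ways, which leaves the label unchanged.  Every output is finally resized
to the network input size (default 200x200).  With the default four fractions
and four orientations a bank grows 16x: 71 -> 1,136, 44 -> 704, 52 -> 832,
with the scale-only stage giving the intermediate 4x banks (284, 208, 176).

Label rescaling modes
---------------------
``area``
    count x fraction^2 — the expected number of cells retained by a crop is
    proportional to the retained area.  Default.
``linear``
    count x fraction — rescaling by the linear size reduction instead.
``exact_recount``
    For synthetic images only: the label is the exact number of scene cell
    centres falling inside the crop window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .datasets import Bank, LabeledImage
from .errors import ConfigurationError, ValidationError
from .synthgen import SceneSpec

__all__ = [
    "ORIENTATIONS",
    "AugmentConfig",
    "crop_scale",
    "orient",
    "resize",
    "scale_stage",
    "expand_bank",
    "replay",
]

ORIENTATIONS = ("identity", "horizontal_flip", "vertical_flip", "both_flips")
LABEL_MODES = ("area", "linear", "exact_recount")


@dataclass(frozen=True)
class AugmentConfig:
    scale_fractions: tuple = (1.00, 0.75, 0.50, 0.25)
    orientations: tuple = ORIENTATIONS
    target_size: int = 200
    label_scaling_mode: str = "area"

    def __post_init__(self) -> None:
        fr = tuple(self.scale_fractions)
        object.__setattr__(self, "scale_fractions", fr)
        object.__setattr__(self, "orientations", tuple(self.orientations))
        if any(not 0.0 < f <= 1.0 for f in fr):
            raise ConfigurationError(f"scale fractions must lie in (0,1]: {fr}")
        if fr.count(1.0) != 1:
            raise ConfigurationError(
                f"scale fractions must contain 1.0 exactly once: {fr}")
        if self.target_size <= 0:
            raise ConfigurationError(f"target_size must be > 0, got {self.target_size}")
        for o in self.orientations:
            if o not in ORIENTATIONS:
                raise ConfigurationError(f"unknown orientation {o!r}")
        if self.label_scaling_mode not in LABEL_MODES:
            raise ConfigurationError(
                f"unknown label_scaling_mode {self.label_scaling_mode!r}")


def crop_scale(image: LabeledImage, fraction: float,
               scene: Optional[SceneSpec] = None,
               mode: str = "area",
               origin: Optional[tuple[int, int]] = None) -> LabeledImage:
    """Crop an image to ``fraction`` of its linear size and rescale its label.

    The window defaults to the centre crop; ``origin`` (row, col of the
    window's top-left corner) overrides it, e.g. for randomised-position
    studies.  ``mode='exact_recount'`` requires the image's ``scene``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0,1], got {fraction}")
    if mode not in LABEL_MODES:
        raise ConfigurationError(f"unknown label mode {mode!r}")
    if mode == "exact_recount" and scene is None:
        raise ConfigurationError("exact_recount label mode requires a SceneSpec")
    h, w = image.pixels.shape
    side_r, side_c = round(fraction * h), round(fraction * w)
    if origin is None:
        r0, c0 = (h - side_r) // 2, (w - side_c) // 2
    else:
        r0, c0 = origin
        if not (0 <= r0 <= h - side_r and 0 <= c0 <= w - side_c):
            raise ValidationError(f"crop origin {origin} leaves the image")
    pixels = image.pixels[r0:r0 + side_r, c0:c0 + side_c].copy()

    if fraction == 1.0:
        count = image.count
    elif mode == "area":
        count = image.count * fraction**2
    elif mode == "linear":
        count = image.count * fraction
    else:  # exact_recount
        rr, cc = scene.centers[:, 0], scene.centers[:, 1]
        inside = (rr >= r0) & (rr < r0 + side_r) & (cc >= c0) & (cc < c0 + side_c)
        count = float(inside.sum())
    return image.with_transform(pixels, count,
                                ("crop", fraction, (r0, c0), mode),
                                scale_fraction=fraction, label_mode=mode)


def orient(image: LabeledImage, orientation: str) -> LabeledImage:
    """Flip an image; the count is unchanged and each flip is an involution."""
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"unknown orientation {orientation!r}")
    px = image.pixels
    if orientation in ("horizontal_flip", "both_flips"):
        px = px[:, ::-1]
    if orientation in ("vertical_flip", "both_flips"):
        px = px[::-1, :]
    return image.with_transform(np.ascontiguousarray(px), image.count,
                                ("orient", orientation),
                                orientation=orientation)


def resize(image: LabeledImage, target_size: int) -> LabeledImage:
    """Resample to ``target_size`` square; a resolution change, so the count is kept.

    Bilinear interpolation, anti-aliased when downscaling.
    """
    if target_size <= 0:
        raise ValidationError(f"target_size must be > 0, got {target_size}")
    h, w = image.pixels.shape
    if (h, w) == (target_size, target_size):
        px = image.pixels.copy()
    else:
        anti = target_size < min(h, w)
        px = _sk_resize(image.pixels.astype(np.float64),
                        (target_size, target_size),
                        order=1, anti_aliasing=anti, preserve_range=True)
        px = np.clip(px, 0.0, 1.0).astype(np.float32)
    return image.with_transform(px, image.count, ("resize", target_size))


def scale_stage(bank: Bank, config: AugmentConfig = AugmentConfig(),
                scenes: Optional[Sequence[SceneSpec]] = None) -> Bank:
    """Apply only the cropping stage: |bank| x |scale_fractions| unresized crops."""
    if len(bank) == 0:
        raise ValidationError("cannot augment an empty bank")
    if config.label_scaling_mode == "exact_recount" and scenes is None:
        raise ConfigurationError("exact_recount label mode requires the scene list")
    items = []
    for i, im in enumerate(bank.items):
        scene = scenes[i] if scenes is not None else None
        src = im.meta.get("source_index", i)
        for f in config.scale_fractions:
            out = crop_scale(im, f, scene=scene, mode=config.label_scaling_mode)
            out.meta.setdefault("source_index", src)
            items.append(out)
    return Bank(items=items)


def expand_bank(bank: Bank, config: AugmentConfig = AugmentConfig(),
                scenes: Optional[Sequence[SceneSpec]] = None) -> Bank:
    """Full two-stage expansion: scales, then orientations, then resize.

    Output size is ``len(bank) * len(scale_fractions) * len(orientations)``
    (16x under the defaults); lineage is preserved via ``meta['source_index']``
    and each image's transform log.
    """
    scaled = scale_stage(bank, config, scenes=scenes)
    items = []
    for im in scaled.items:
        for o in config.orientations:
            items.append(resize(orient(im, o), config.target_size))
    return Bank(items=items)


def replay(source: LabeledImage, transform_log: Sequence[tuple],
           scene: Optional[SceneSpec] = None) -> LabeledImage:
    """Re-apply a transform log to a source image, reproducing a derived image."""
    im = source
    for entry in transform_log:
        kind = entry[0]
        if kind == "crop":
            _, fraction, origin, mode = entry
            im = crop_scale(im, fraction, scene=scene, mode=mode, origin=origin)
        elif kind == "orient":
            im = orient(im, entry[1])
        elif kind == "resize":
            im = resize(im, entry[1])
        else:
            raise ValidationError(f"unknown transform entry {entry!r}")
    return im
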