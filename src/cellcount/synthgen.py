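"""Synthetic brightfield-like image generation with exactly known cell counts.

Transmitted-light (digital contrast) microscopy images of adherent cell
cultures show blob-like cells with heterogeneous intensity against a bright
background, smooth illumination gradients across the field of view, and pixel
noise.  Two preset regimes are provided:

``high_contrast``
    Well-contrasted cultures (A549/Huh7-like): every cell is clearly darker
    than the background (mean separation ~0.4 grayscale), cells do not
    overlap appreciably.

``low_contrast_confluent``
    Confluent monolayers imaged in brightfield (3T3-like): cell intensity is
    roughly the background intensity (per-cell deviations of ~±0.03,
    symmetric about the background, so the *mean* cell intensity matches the
    background), cells may overlap, and the illumination gradient is larger
    than the cell signal.  Count information is close to invisible, which is
    the point of the regime.

Cells are rendered as radially symmetric Gaussian blobs; the illumination
gradient is a linear ramp of configurable amplitude in a direction drawn once
per scene; pixel noise is i.i.d. Gaussian.  Everything is deterministic given
the scene, and scene sampling is deterministic given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import Bank, LabeledImage
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SceneSpec",
    "LabeledImage",
    "Bank",
    "REGIMES",
    "sample_scene",
    "render",
    "generate_bank",
]

# Preset parameters per contrast regime.  ``separation`` is the typical
# grayscale offset of a cell from the background; ``symmetric`` means offsets
# take either sign with equal probability (cells as bright as they are dark,
# the confluent-brightfield failure mode).  Radii scale with the field so a
# cell keeps its size relative to the field of view.
REGIMES = {
    "high_contrast": dict(
        background=0.65, separation=0.40, dark_cells=True, symmetric=False,
        intensity_jitter=0.10, gradient_amplitude=0.05, noise_sigma=0.02,
        overlap_allowed=False,
    ),
    "low_contrast_confluent": dict(
        background=0.50, separation=0.03, dark_cells=True, symmetric=True,
        intensity_jitter=0.0, gradient_amplitude=0.12, noise_sigma=0.02,
        overlap_allowed=True,
    ),
}

_RADIUS_FRACTION = 0.014  # mean cell radius as a fraction of field size


@dataclass(frozen=True)
class SceneSpec:
    """Fully resolved parameters of one synthetic field.

    ``contrast`` is the separation between the mean cell intensity and the
    background (grayscale units); a contrast of exactly 0 requires the mean
    cell intensity to equal the background level.
    """

    field_size: int
    n_cells: int
    centers: np.ndarray           # (n_cells, 2) float (row, col)
    radii: np.ndarray             # (n_cells,) pixels
    cell_intensity: np.ndarray    # (n_cells,) grayscale in [0, 1]
    background_level: float
    contrast: float
    illum_gradient_amplitude: float
    illum_gradient_angle: float   # radians; direction of the linear ramp
    noise_sigma: float
    confluence_overlap_allowed: bool
    rng_seed: int
    line_tag: str = "synthetic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers",
                           np.asarray(self.centers, dtype=float).reshape(-1, 2))
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "cell_intensity",
                           np.asarray(self.cell_intensity, dtype=float))
        n = self.n_cells
        if n < 0:
            raise ValidationError(f"n_cells must be non-negative, got {n}")
        if not (len(self.centers) == len(self.radii) == len(self.cell_intensity) == n):
            raise ValidationError(
                f"n_cells={n} but got {len(self.centers)} centers, "
                f"{len(self.radii)} radii, {len(self.cell_intensity)} intensities")
        if n and (self.centers.min() < 0 or self.centers.max() > self.field_size - 1):
            raise ValidationError("cell centers must lie inside the field")
        for name in ("background_level", "contrast", "illum_gradient_amplitude",
                     "noise_sigma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if n and (self.cell_intensity.min() < 0 or self.cell_intensity.max() > 1):
            raise ValidationError("cell intensities must be in [0,1]")
        if self.contrast == 0.0 and n:
            if not math.isclose(float(self.cell_intensity.mean()),
                                self.background_level, abs_tol=1e-9):
                raise ValidationError(
                    "contrast == 0 requires mean cell intensity == background_level")

    def __eq__(self, other) -> bool:  # arrays defeat the dataclass default
        if not isinstance(other, SceneSpec):
            return NotImplemented
        for f in ("field_size", "n_cells", "background_level", "contrast",
                  "illum_gradient_amplitude", "illum_gradient_angle",
                  "noise_sigma", "confluence_overlap_allowed", "rng_seed",
                  "line_tag"):
            if getattr(self, f) != getattr(other, f):
                return False
        return (np.array_equal(self.centers, other.centers)
                and np.array_equal(self.radii, other.radii)
                and np.array_equal(self.cell_intensity, other.cell_intensity))


def sample_scene(regime: str, n_cells: int, field_size: int, seed: int) -> SceneSpec:
    """Draw a fully resolved :class:`SceneSpec` for a preset contrast regime.

    Deterministic in ``seed``: identical arguments give identical scenes.
    """
    if regime not in REGIMES:
        raise ConfigurationError(
            f"unknown regime {regime!r}; choose from {sorted(REGIMES)}")
    if n_cells < 0:
        raise ValidationError(f"n_cells must be non-negative, got {n_cells}")
    p = REGIMES[regime]
    rng = np.random.default_rng(seed)

    mean_radius = _RADIUS_FRACTION * field_size
    radii = np.clip(rng.normal(mean_radius, 0.2 * mean_radius, size=n_cells),
                    1.5, None)
    centers = _place_centers(rng, n_cells, field_size, radii,
                             p["overlap_allowed"])

    sign = -1.0 if p["dark_cells"] else 1.0
    offsets = sign * p["separation"] * np.ones(n_cells)
    if p["symmetric"]:
        # cells as often brighter as darker than background, magnitude jittered
        offsets = (rng.choice([-1.0, 1.0], size=n_cells)
                   * p["separation"] * rng.uniform(0.5, 1.5, size=n_cells))
    if p["intensity_jitter"]:
        offsets = offsets + rng.normal(0.0, p["intensity_jitter"], size=n_cells)
    intensity = np.clip(p["background"] + offsets, 0.02, 0.98)

    if n_cells:
        contrast = abs(float(intensity.mean()) - p["background"])
    else:
        contrast = p["separation"]
    angle = float(rng.uniform(0.0, 2.0 * math.pi))
    return SceneSpec(
        field_size=field_size,
        n_cells=n_cells,
        centers=centers,
        radii=radii,
        cell_intensity=intensity,
        background_level=p["background"],
        contrast=contrast,
        illum_gradient_amplitude=p["gradient_amplitude"],
        illum_gradient_angle=angle,
        noise_sigma=p["noise_sigma"],
        confluence_overlap_allowed=p["overlap_allowed"],
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        line_tag=regime,
    )


def _place_centers(rng: np.random.Generator, n: int, field: int,
                   radii: np.ndarray, overlap: bool) -> np.ndarray:
    """Uniform centers; without overlap, dart-throwing with bounded retries.

    After 40 failed throws a cell is placed anyway so the requested count is
    always honoured (mild crowding beats silently dropping cells).
    """
    if n == 0:
        return np.zeros((0, 2))
    margin = np.clip(radii, 0, field / 4)
    if overlap:
        rows = rng.uniform(margin, field - 1 - margin)
        cols = rng.uniform(margin, field - 1 - margin)
        return np.stack([rows, cols], axis=1)
    placed = np.zeros((n, 2))
    for i in range(n):
        for _ in range(40):
            cand = rng.uniform(margin[i], field - 1 - margin[i], size=2)
            if i == 0:
                break
            d = np.hypot(*(placed[:i] - cand).T)
            if (d > 0.9 * (radii[:i] + radii[i])).all():
                break
        placed[i] = cand
    return placed


def render(scene: SceneSpec) -> LabeledImage:
    """Render a scene to a grayscale image; the label is the exact cell count.

    The image is background + linear illumination ramp + one Gaussian blob per
    cell (peak offset = cell intensity − background, sigma = radius / 2) +
    i.i.d. Gaussian pixel noise, clipped to [0, 1].  Deterministic given the
    scene; two scenes differing only in ``rng_seed`` differ only in noise.
    """
    s = scene.field_size
    img = np.full((s, s), scene.background_level, dtype=np.float64)

    if scene.illum_gradient_amplitude > 0:
        u = np.linspace(-0.5, 0.5, s)
        rows, cols = np.meshgrid(u, u, indexing="ij")
        proj = rows * math.sin(scene.illum_gradient_angle) \
            + cols * math.cos(scene.illum_gradient_angle)
        img += scene.illum_gradient_amplitude * proj

    for (r, c), radius, intensity in zip(scene.centers, scene.radii,
                                         scene.cell_intensity):
        sigma = radius / 2.0
        half = int(math.ceil(3.0 * sigma))
        r0, r1 = max(0, int(r) - half), min(s, int(r) + half + 1)
        c0, c1 = max(0, int(c) - half), min(s, int(c) + half + 1)
        yy = np.arange(r0, r1, dtype=float)[:, None] - r
        xx = np.arange(c0, c1, dtype=float)[None, :] - c
        blob = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
        img[r0:r1, c0:c1] += (intensity - scene.background_level) * blob

    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.rng_seed)
        img += rng.normal(0.0, scene.noise_sigma, size=img.shape)

    return LabeledImage(
        pixels=np.clip(img, 0.0, 1.0).astype(np.float32),
        count=float(scene.n_cells),
        line_tag=scene.line_tag,
        meta={"regime": scene.line_tag, "scene_seed": scene.rng_seed},
    )


def generate_bank(regime: str, n_images: int, count_range: tuple[int, int],
                  field_size: int, seed: int,
                  return_scenes: bool = False):
    """Generate a bank of ``n_images`` rendered scenes with uniform random counts.

    One seed sequence is split per image by counter, so images are independent
    yet the whole bank is reproducible from ``seed``.  With ``return_scenes``
    the per-image :class:`SceneSpec` list is returned alongside the bank
    (needed for exact label recounting after crops).
    """
    if n_images < 1:
        raise ValidationError(f"n_images must be >= 1, got {n_images}")
    low, high = count_range
    if not 0 <= low <= high:
        raise ValidationError(f"invalid count range ({low}, {high})")
    root = np.random.SeedSequence(seed)
    count_rng = np.random.default_rng(root.spawn(1)[0])
    counts = count_rng.integers(low, high + 1, size=n_images)
    scene_seeds = [int(ss.generate_state(1)[0] % (2**31 - 1))
                   for ss in root.spawn(n_images + 1)[1:]]
    scenes = [sample_scene(regime, int(counts[i]), field_size, scene_seeds[i])
              for i in range(n_images)]
    items = []
    for i, scene in enumerate(scenes):
        im = render(scene)
        im.meta.update(source_index=i, seed=scene_seeds[i])
        items.append(im)
    bank = Bank(items=items)
    if return_scenes:
        return bank, scenes
    return bank
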