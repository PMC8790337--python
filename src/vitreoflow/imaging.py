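"""Particle counting and equivalent-diameter sizing for drug micrographs.

Suspension formulations (e.g. a milled small-molecule depot with 10-20 um
aggregates, or triamcinolone acetonide at 5-10 um) are spotted on
coverslips and imaged in a single fluorescence channel; particles are
counted per image and sized by the equivalent diameter of each detected
region — the diameter of the circle with the same area.

Detection is deliberately simple: global threshold (fixed or Otsu),
8-connected components, small-region rejection.  Touching particles are
not split; that limitation is acceptable for sparse spotted fields and is
documented in the methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import filters, measure

__all__ = [
    "ParticleImage",
    "ParticleStats",
    "detect_particles",
    "equivalent_diameter",
    "summarize_particles",
    "load_image",
]


@dataclass
class ParticleImage:
    """A grayscale micrograph with its physical pixel pitch (um/px)."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("particle images must be 2-D grayscale")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")


@dataclass
class ParticleStats:
    """Per-sample particle summary: mean per-image count, pooled diameters."""

    count: float
    diameters: np.ndarray
    mean_diameter: float
    median_diameter: float


def _resolve_threshold(image: ParticleImage, threshold) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        return float(filters.threshold_otsu(image.pixels))
    thr = float(threshold)
    lo, hi = float(image.pixels.min()), float(image.pixels.max())
    if not lo <= thr <= hi:
        raise ValueError(
            f"threshold {thr} outside image intensity range [{lo}, {hi}]")
    return thr


def detect_particles(image: ParticleImage, threshold=("otsu"),
                     min_area_px: int = 4) -> list:
    """Detect particles as 8-connected foreground components.

    ``threshold`` is either an absolute intensity or the string ``"otsu"``
    for automatic selection.  Components smaller than ``min_area_px`` are
    discarded as shot noise.  Returns scikit-image region properties; an
    image with no foreground yields an empty list.
    """
    if image.pixels.size == 0 or np.ptp(image.pixels) == 0:
        return []
    thr = _resolve_threshold(image, threshold)
    mask = image.pixels > thr
    labels = measure.label(mask, connectivity=2)
    return [r for r in measure.regionprops(labels) if r.area >= min_area_px]


def equivalent_diameter(area_px: float, pixel_size: float) -> float:
    """Diameter (um) of the circle whose area equals ``area_px`` pixels."""
    if area_px <= 0:
        raise ValueError("region area must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel size must be positive")
    return pixel_size * math.sqrt(4.0 * area_px / math.pi)


def summarize_particles(images: list[ParticleImage], threshold=("otsu"),
                        min_area_px: int = 4,
                        min_images: int = 3) -> ParticleStats:
    """Count and size particles across replicate images of one sample.

    Per-image counts are averaged; diameters are pooled across images.
    Fewer than ``min_images`` replicates raises; passing ``min_images``
    below 3 is allowed but warns, since single-field counts are noisy.
    """
    if min_images < 3:
        warnings.warn("averaging fewer than 3 images per sample gives "
                      "unstable counts", stacklevel=2)
    if len(images) < min_images:
        raise ValueError(
            f"need >= {min_images} images per sample, got {len(images)}")
    counts = []
    diameters: list[float] = []
    for img in images:
        regions = detect_particles(img, threshold=threshold,
                                   min_area_px=min_area_px)
        counts.append(len(regions))
        diameters.extend(equivalent_diameter(r.area, img.pixel_size)
                         for r in regions)
    dia = np.asarray(diameters, dtype=float)
    return ParticleStats(
        count=float(np.mean(counts)),
        diameters=dia,
        mean_diameter=float(np.mean(dia)) if dia.size else math.nan,
        median_diameter=float(np.median(dia)) if dia.size else math.nan,
    )


def load_image(path: str | Path, pixel_size: float) -> ParticleImage:
    """Read a grayscale TIFF/PNG micrograph from disk."""
    import imageio.v3 as iio

    pixels = np.asarray(iio.imread(path), dtype=float)
    if pixels.ndim == 3:  # collapse RGB(A) to luminance
        pixels = pixels[..., :3].mean(axis=-1)
    return ParticleImage(pixels=pixels, pixel_size=pixel_size)
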