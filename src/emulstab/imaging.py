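"""Droplet sizing from emulsion micrographs.

Measures droplet diameters from grayscale images and computes the size
statistics used to screen emulsions for stability: the arithmetic mean
diameter, the Sauter (volume–surface) mean diameter

    d32 = Σ dᵢ³ / Σ dᵢ²,

and the 5-hour size-variation rate 100·(S5 − S0)/S0.

Detection is deliberately simple and auditable: global Otsu threshold,
connected components, then size and circularity filters.  Objects touching
the image border are excluded because their diameters are censored.
Pixel diameters are converted to microns by the full-image-width
calibration (μm spanned by the image ÷ pixels across it).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from .errors import InputError

__all__ = [
    "DropletSet",
    "SizeSummary",
    "detect_droplets",
    "px_to_um",
    "sauter_mean",
    "variation_rate",
    "summarize",
    "subsample_droplets",
]


@dataclass(frozen=True)
class DropletSet:
    """Measured droplet diameters (μm) for one emulsion / time point."""

    diameters_um: np.ndarray
    source_image: str = ""
    timepoint: str = "T0"  # one of T0, T5top, T5bottom

    def __post_init__(self):
        d = np.asarray(self.diameters_um, dtype=float)
        if np.any(d <= 0):
            raise InputError("all droplet diameters must be positive")
        object.__setattr__(self, "diameters_um", d)

    @property
    def n_counted(self) -> int:
        return self.diameters_um.size


@dataclass(frozen=True)
class SizeSummary:
    """Mean diameter, Sauter mean d32 and count for a droplet population."""

    mean_diameter_um: float
    d32_um: float
    n: int


def detect_droplets(
    image: np.ndarray,
    min_diameter_px: float = 3.0,
    circularity_min: float = 0.6,
    dark_droplets: bool = True,
) -> np.ndarray:
    """Equivalent-circle diameters (px) of droplet-like objects.

    Foreground is whatever lies on the droplet side of a global Otsu
    threshold (below it when ``dark_droplets``).  Connected components are
    filtered by equivalent diameter ``2·sqrt(area/π) ≥ min_diameter_px``
    and circularity ``4πA/P² ≥ circularity_min`` (digitized disks can
    slightly exceed 1); border-touching objects are dropped.  Diameters are
    returned sorted descending.  A featureless image yields an empty
    array, not an error.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise InputError("image must be a non-empty 2-D intensity array")
    if not 0 <= circularity_min <= 1:
        raise InputError("circularity_min must lie in [0, 1]")
    if img.min() == img.max():
        return np.empty(0)
    # skimage's Otsu convention puts foreground strictly above the
    # threshold, so the dark-object mask must be inclusive (<=): on a
    # noise-free two-level image the threshold equals the droplet level.
    thr = threshold_otsu(img)
    mask = img <= thr if dark_droplets else img > thr
    labels = clear_border(label(mask, connectivity=2))
    diameters = []
    for region in regionprops(labels):
        d_eq = 2.0 * np.sqrt(region.area / np.pi)
        if d_eq < min_diameter_px:
            continue
        perimeter = region.perimeter
        if perimeter <= 0:
            continue
        circularity = 4.0 * np.pi * region.area / perimeter**2
        if circularity < circularity_min:
            continue
        diameters.append(d_eq)
    return np.sort(np.asarray(diameters))[::-1]


def px_to_um(
    diameters_px: Iterable[float], image_width_px: int, image_width_um: float
) -> np.ndarray:
    """Convert pixel diameters to microns via the full-image-width scale."""
    if image_width_px <= 0 or image_width_um <= 0:
        raise InputError("image widths must be positive")
    d = np.asarray(list(diameters_px) if not isinstance(diameters_px, np.ndarray) else diameters_px, dtype=float)
    return d * (image_width_um / float(image_width_px))


def sauter_mean(diameters: Sequence[float]) -> float:
    """Sauter (volume–surface) mean diameter d32 = Σd³/Σd²."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise InputError("need at least one diameter")
    if np.any(d <= 0):
        raise InputError("all diameters must be positive")
    return float(np.sum(d**3) / np.sum(d**2))


def variation_rate(size_t0: float, size_t5: float) -> tuple[float, float]:
    """5-hour size change: (S5 − S0, 100·(S5 − S0)/S0).

    The relative rate (in %) is the stability screen's first criterion;
    the absolute difference is reported alongside it.
    """
    if size_t0 <= 0:
        raise InputError("size at t0 must be positive")
    diff = size_t5 - size_t0
    return diff, 100.0 * diff / size_t0


def subsample_droplets(
    diameters: Sequence[float], n: int = 50, seed: int = 0
) -> np.ndarray:
    """Uniform seeded subsample of ``n`` diameters (all if fewer measured).

    Mirrors the counting protocol of 50 droplets per image; the default
    pipeline uses every detection.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size <= n:
        return d.copy()
    rng = np.random.default_rng(seed)
    return d[rng.choice(d.size, size=n, replace=False)]


def summarize(droplets: DropletSet) -> SizeSummary:
    """Arithmetic mean, Sauter mean and count for a droplet set."""
    d = droplets.diameters_um
    if d.size == 0:
        raise InputError("droplet set is empty")
    return SizeSummary(
        mean_diameter_um=float(np.mean(d)),
        d32_um=sauter_mean(d),
        n=int(d.size),
    )
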