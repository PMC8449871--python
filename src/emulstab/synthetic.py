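"""Synthetic data generators: micrographs, flow curves, design responses.

Every downstream stage of the creaming analysis (droplet sizing, yield-value
extraction, coded-factor modeling) can be exercised against data with known
ground truth produced here.  All generators are deterministic under a fixed
seed: identical spec + seed gives bit-identical output.

Micrographs emulate bright-field images of homogenized oil-in-water
emulsions: circular droplets with log-normally distributed diameters, dark
on a light background by default, at a known full-image-width calibration
(μm per pixel), with additive Gaussian intensity noise clipped to the 8-bit
range.

Flow curves emulate yield-stress ("plastic") fluids via the
Herschel–Bulkley law  σ(f) = τ0 + K·f^n , with τ0 playing the static flow
limit read off at the lowest sweep frequency.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError, PlacementError, SimulationDomainError
from .rheology import FlowCurve

__all__ = [
    "MicrographSpec",
    "FlowCurveSpec",
    "generate_micrograph",
    "generate_flow_curve",
    "generate_doe_responses",
    "DEFAULT_FREQ_GRID",
]

#: Frequency sweep grid (Hz) used by default: 30 log-spaced points over the
#: oscillatory sweep range 0.05–500 Hz.
DEFAULT_FREQ_GRID = np.geomspace(0.05, 500.0, 30)

_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class MicrographSpec:
    """Parameters of one synthetic emulsion micrograph.

    The default geometry (1000 px spanning 250 μm, i.e. 0.25 μm/px) and
    droplet load (50 droplets per image, median diameter ~12 μm, geometric
    SD ~1.28) match the droplet populations the sizing pipeline is meant
    for: micrometre-scale oil droplets counted 50 per image.
    """

    image_width_px: int = 1000
    image_width_um: float = 250.0
    n_droplets: int = 50
    diameter_log_mean: float = math.log(12.0)  # ln(μm)
    diameter_log_sd: float = 0.25  # ln-scale
    allow_overlap: bool = False
    noise_sd: float = 8.0  # 8-bit intensity units
    seed: int = 0
    dark_droplets: bool = True  # oil appears dark under bright field
    background_intensity: int = 200
    droplet_intensity: int = 60

    def validate(self) -> None:
        if self.image_width_px <= 0:
            raise InputError("image_width_px must be positive")
        if self.image_width_um <= 0:
            raise InputError("image_width_um must be positive")
        if self.n_droplets < 0:
            raise InputError("n_droplets must be non-negative")
        if self.diameter_log_sd < 0:
            raise InputError("diameter_log_sd must be non-negative")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")

    @property
    def um_per_px(self) -> float:
        return self.image_width_um / self.image_width_px


@dataclass(frozen=True)
class FlowCurveSpec:
    """Parameters of one synthetic Herschel–Bulkley flow curve.

    ``yield_stress`` (τ0, Pa) is the static flow limit, ``consistency``
    (K, Pa·s^n) and ``flow_index`` (n, dimensionless, 0 < n ≤ 1 for a
    shear-thinning plastic) shape the frequency dependence.  Noise is
    additive Gaussian on the stress, clipped at zero.
    """

    yield_stress: float = 2.0
    consistency: float = 0.5
    flow_index: float = 0.5
    freq_grid: np.ndarray = field(default_factory=lambda: DEFAULT_FREQ_GRID.copy())
    noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.yield_stress < 0:
            raise InputError("yield_stress must be non-negative")
        if self.consistency < 0:
            raise InputError("consistency must be non-negative")
        if not 0 < self.flow_index <= 1:
            raise InputError("flow_index must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        grid = np.asarray(self.freq_grid, dtype=float)
        if grid.size == 0:
            raise InputError("freq_grid must not be empty")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise InputError("freq_grid must be strictly increasing and positive")


def generate_micrograph(spec: MicrographSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a synthetic micrograph and return it with its ground truth.

    Returns
    -------
    image : ``uint8`` array of shape (W, W)
        Disk-shaped droplets on a uniform background, plus clipped Gaussian
        noise when ``spec.noise_sd > 0``.
    truth : DataFrame
        One row per droplet: droplet_id, x_px, y_px, diameter_px,
        diameter_um.  ``diameter_um = diameter_px × (image_width_um /
        image_width_px)`` — exactly the rendered diameter on the image's
        calibration.

    Raises
    ------
    PlacementError
        When ``allow_overlap`` is false and a droplet cannot be placed
        after 100 retries.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w = spec.image_width_px
    image = np.full((w, w), float(spec.background_intensity))

    diameters_um = np.exp(
        rng.normal(spec.diameter_log_mean, spec.diameter_log_sd, spec.n_droplets)
    )
    diameters_px = diameters_um / spec.um_per_px

    placed: list[tuple[float, float, float]] = []  # (cx, cy, r)
    rows = []
    for i, d_px in enumerate(diameters_px):
        r = d_px / 2.0
        lo, hi = r + 2.0, w - r - 2.0
        if lo >= hi:
            raise PlacementError(i, 0)
        for attempt in range(_PLACEMENT_RETRIES + 1):
            cx, cy = rng.uniform(lo, hi, 2)
            # 1 px clearance keeps neighbouring disks as separate components
            if spec.allow_overlap or all(
                math.hypot(cx - px, cy - py) > r + pr + 1.0 for px, py, pr in placed
            ):
                break
        else:
            raise PlacementError(i, _PLACEMENT_RETRIES)
        placed.append((cx, cy, r))
        _render_disk(image, cx, cy, r, float(spec.droplet_intensity), spec.dark_droplets)
        rows.append(
            {
                "droplet_id": i,
                "x_px": cx,
                "y_px": cy,
                "diameter_px": d_px,
                "diameter_um": d_px * spec.um_per_px,
            }
        )

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        rows, columns=["droplet_id", "x_px", "y_px", "diameter_px", "diameter_um"]
    )
    return image, truth


def _render_disk(
    image: np.ndarray, cx: float, cy: float, r: float, intensity: float, dark: bool
) -> None:
    """Paint a hard-edged disk in place (pixel centres inside radius r)."""
    w = image.shape[0]
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(w, int(cy + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    if dark:
        image[y0:y1, x0:x1][mask] = intensity
    else:
        image[y0:y1, x0:x1][mask] = 255 - intensity


def generate_flow_curve(spec: FlowCurveSpec, sample_id: str = "synthetic") -> FlowCurve:
    """Simulate an oscillatory-sweep flow curve of a plastic fluid.

    stress(f) = τ0 + K·f^n + ε,  ε ~ N(0, noise_sd²), clipped at zero so
    the curve stays a physical stress.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    f = np.asarray(spec.freq_grid, dtype=float)
    stress = spec.yield_stress + spec.consistency * f**spec.flow_index
    if spec.noise_sd > 0:
        stress = stress + rng.normal(0.0, spec.noise_sd, f.shape)
    stress = np.maximum(stress, 0.0)
    return FlowCurve(frequency_hz=f, stress_pa=stress, sample_id=sample_id)


def generate_doe_responses(
    design: pd.DataFrame,
    coefficients: Mapping[str, float],
    transform: str = "identity",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a response column from a coded-factor linear model.

    The linear predictor η = Xβ is formed on the transformed scale from
    ``coefficients`` (keys: ``const``, main effects ``A``..``E`` and
    two-letter interactions such as ``AB``), Gaussian noise of SD
    ``noise_sd`` is added on that scale, and the named transform is
    inverted (``log10`` → 10^η, ``sqrt`` → η², ``inverse-sqrt`` → η⁻²,
    ``identity`` → η) to give the response on its original scale.

    Raises :class:`SimulationDomainError` when η leaves the domain of the
    inverse transform (η ≤ 0 for the root transforms).
    """
    from .doe import coded_columns, inverse_transform  # local: avoid cycle

    coded = coded_columns(design)
    n = len(coded)
    eta = np.zeros(n)
    for term, beta in coefficients.items():
        if term in ("const", "Intercept"):
            eta += beta
            continue
        cols = list(term)
        if not all(c in coded.columns for c in cols) or len(cols) not in (1, 2):
            raise InputError(
                f"unknown model term {term!r}: expected const, a main effect "
                "A..E or a two-factor interaction"
            )
        x = coded[cols[0]].to_numpy(dtype=float)
        for c in cols[1:]:
            x = x * coded[c].to_numpy(dtype=float)
        eta += beta * x
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eta = eta + rng.normal(0.0, noise_sd, n)
    try:
        return inverse_transform(eta, transform)
    except InputError as exc:
        raise SimulationDomainError(str(exc)) from exc
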