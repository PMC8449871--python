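"""Yield-value extraction from flow curves.

The continuous phases (milk proteins + lactose, optionally starch and
sodium caseinate) behave as plastic, i.e. yield-stress, fluids.  The static
flow limit τy anchors the creaming index: a droplet aggregate must exert a
micro-stress exceeding τy before the matrix deforms and creaming starts.

Two estimators are provided:

* ``yield_value`` — the stress at the minimum sweep frequency, the direct
  reading used throughout the analysis (with an optional low-frequency
  plateau variant, the median stress over the lowest frequency decade);
* ``fit_herschel_bulkley`` — a model-based cross-check fitting
  σ(f) = τ0 + K·f^n by nonlinear least squares.

Frequencies are kept in Hz as measured; no conversion to rad/s is applied,
so τy is "the stress at the lowest sweep frequency" literally.  For a true
plastic fluid the two agree up to the K·f_min^n contribution at the lowest
frequency.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitFailureError, InputError

__all__ = ["FlowCurve", "HerschelBulkleyFit", "yield_value", "fit_herschel_bulkley"]


@dataclass(frozen=True)
class FlowCurve:
    """An oscillatory-sweep flow curve: (frequency, stress) pairs.

    Frequencies must be strictly increasing and positive; stresses
    non-negative.
    """

    frequency_hz: np.ndarray
    stress_pa: np.ndarray
    sample_id: str = ""
    temperature_c: float | None = None

    def __post_init__(self):
        f = np.asarray(self.frequency_hz, dtype=float)
        s = np.asarray(self.stress_pa, dtype=float)
        if f.shape != s.shape or f.ndim != 1:
            raise InputError("frequency and stress must be 1-D arrays of equal length")
        if f.size and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise InputError("frequencies must be strictly increasing and positive")
        if np.any(s < 0):
            raise InputError("stresses must be non-negative")
        object.__setattr__(self, "frequency_hz", f)
        object.__setattr__(self, "stress_pa", s)

    def __len__(self) -> int:
        return self.frequency_hz.size

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str = "") -> "FlowCurve":
        return cls(
            frequency_hz=df["frequency_hz"].to_numpy(),
            stress_pa=df["stress_pa"].to_numpy(),
            sample_id=sample_id,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency_hz": self.frequency_hz, "stress_pa": self.stress_pa}
        )


@dataclass(frozen=True)
class HerschelBulkleyFit:
    """Herschel–Bulkley parameters σ = τ0 + K·f^n with fit diagnostics."""

    tau0: float
    consistency: float
    flow_index: float
    residual_rms: float
    n_points: int

    def predict(self, frequency_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(frequency_hz, dtype=float)
        return self.tau0 + self.consistency * f**self.flow_index


def yield_value(curve: FlowCurve, method: str = "point") -> float:
    """Static flow limit τy (Pa) of a matrix or emulsion.

    method="point"
        The stress at the minimum sweep frequency — the curve reading that
        defines the yield value here.
    method="plateau"
        Median stress over the lowest frequency decade (requires ≥ 3 points
        there); a noise-robust variant of the same reading.
    method="hb"
        τ0 from a Herschel–Bulkley fit (see :func:`fit_herschel_bulkley`).
    """
    if len(curve) == 0:
        raise InputError("flow curve is empty")
    if method == "point":
        return float(curve.stress_pa[0])
    if method == "plateau":
        f_min = curve.frequency_hz[0]
        low = curve.stress_pa[curve.frequency_hz <= 10.0 * f_min]
        if low.size < 3:
            raise InputError(
                "plateau estimate needs at least 3 points in the lowest decade"
            )
        return float(np.median(low))
    if method == "hb":
        return fit_herschel_bulkley(curve).tau0
    raise InputError(f"unknown yield-value method {method!r}")


def _hb(f, tau0, k, n):
    return tau0 + k * f**n


def fit_herschel_bulkley(curve: FlowCurve) -> HerschelBulkleyFit:
    """Fit σ = τ0 + K·f^n by bounded nonlinear least squares.

    Bounds: τ0 ≥ 0, K ≥ 0, 0 < n ≤ 2.  Initial values come from the curve
    itself (τ0 from the lowest-frequency stress, K and n from the span).
    """
    if len(curve) < 4:
        raise InputError("Herschel-Bulkley fit needs at least 4 points")
    f = curve.frequency_hz
    s = curve.stress_pa
    span = max(s[-1] - s[0], 1e-12)
    n0 = 0.5
    k0 = span / max(f[-1] ** n0 - f[0] ** n0, 1e-12)
    tau0_0 = max(s[0] - k0 * f[0] ** n0, 0.0)
    try:
        popt, _ = curve_fit(
            _hb,
            f,
            s,
            p0=(tau0_0, k0, n0),
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(
            f"Herschel-Bulkley fit did not converge for sample "
            f"{curve.sample_id!r}",
            diagnostics={"p0": (tau0_0, k0, n0), "n_points": len(curve)},
        ) from exc
    resid = s - _hb(f, *popt)
    return HerschelBulkleyFit(
        tau0=float(popt[0]),
        consistency=float(popt[1]),
        flow_index=float(popt[2]),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=len(curve),
    )
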