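"""Pareto-chart and flow-curve figures (matplotlib, Agg-safe)."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .doe import ParetoResult
from .rheology import FlowCurve

__all__ = ["pareto_chart", "flow_curve_plot"]


def pareto_chart(pareto: ParetoResult, path: str | Path, title: str = "") -> None:
    """Bar chart of |t| per effect with the t and Bonferroni limits."""
    tab = pareto.table
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = [
        {"highly-significant": "#b2182b", "significant": "#ef8a62", "none": "#999999"}[f]
        for f in tab["flag"]
    ]
    ax.bar(tab["term"], tab["abs_t"], color=colors)
    ax.axhline(pareto.t_limit, ls="--", color="k", lw=1, label="t limit")
    ax.axhline(pareto.bonferroni_limit, ls="-", color="k", lw=1, label="Bonferroni limit")
    ax.set_ylabel("|t| value")
    ax.set_xlabel("effect")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def flow_curve_plot(curves: list[FlowCurve], path: str | Path) -> None:
    """Stress vs frequency on log–log axes for one or more samples."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for curve in curves:
        ax.loglog(curve.frequency_hz, curve.stress_pa, "o-", ms=3,
                  label=curve.sample_id or None)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("stress (Pa)")
    if any(c.sample_id for c in curves):
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
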