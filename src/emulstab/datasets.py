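"""Bundled study tables.

The analysis was developed against a 24-run mixture/process design of
argan-oil-in-water emulsions (oil, modified starch, sodium caseinate,
stirring velocity, stirring time) with droplet-size and creaming-class
responses, plus a five-sample creaming-index table for the emulsions that
passed the stability screen.  No machine-readable dataset was deposited, so
the printed tables are shipped here as versioned CSV fixtures.

Functions return fresh ``pandas.DataFrame`` copies; mutating a returned
frame never affects subsequent calls.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_design",
    "load_responses",
    "load_creaming_table",
    "load_published_coefficients",
    "design_with_responses",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files("emulstab.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, **kwargs)


def load_design() -> pd.DataFrame:
    """The 24-run design in natural units.

    Columns: run, block, space_type, oil_pct, starch_pct, caseinate_pct,
    stir_rpm, stir_min.  21 vertex runs plus 3 center points (runs 2, 9,
    16), split over 3 blocks.
    """
    return _read("table4_design.csv")


def load_responses() -> pd.DataFrame:
    """Droplet sizes and creaming classes for the 24 runs.

    Columns: run, combination (m/M/a factor labels), creaming_class (ordinal
    1 = fast separation .. 5 = no separation), size_t0_um, size_t5_um, and
    the published derived columns delta_printed_um / size_var_printed_pct
    (kept verbatim so recomputation can be cross-checked against them).
    """
    return _read("table1_responses.csv")


def load_creaming_table() -> pd.DataFrame:
    """Yield values, droplet sizes, micro-stresses and creaming indices
    for the five screened emulsions (samples 8, 10, 11, 18, 24).

    ``ads_um`` is the average (Sauter) droplet size, ``lds_um`` the largest
    droplet; the ``*_pressure_pa`` columns are the published droplet
    micro-stresses and ``ci_*_printed`` the published indices.
    """
    return _read("table3_creaming.csv")


def load_published_coefficients() -> pd.DataFrame:
    """Published coded-factor model summaries for the three size responses.

    Reference material only (the fitting code never reads it): transform
    name, R-squared triple and coefficients per term.  The source table has
    a duplicated ``DE`` row; the second occurrence is stored as ``DE2``.
    """
    return _read("table2_coefficients.csv", dtype={"term": str})


def design_with_responses() -> pd.DataFrame:
    """Design and responses merged on run number.

    Columns follow the pipeline schema: run, block, oil_pct, starch_pct,
    caseinate_pct, stir_rpm, stir_min, size_t0_um, size_t5_um,
    creaming_class.
    """
    design = load_design().drop(columns=["space_type"])
    resp = load_responses()[["run", "size_t0_um", "size_t5_um", "creaming_class"]]
    return design.merge(resp, on="run", validate="one_to_one")
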