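"""Table schemas, validated CSV I/O, and the end-to-end pipeline.

The pipeline ties the stages together in the order the analysis runs:
derived size columns → coded-factor models → yield values → creaming
index → stability selection, writing per-stage CSV/JSON outputs plus a
summary report.  Runs are deterministic: identical config + seed give
byte-identical outputs, and the report records the package version, the
seed and a hash of the config.

CSV dialect everywhere: comma-separated, UTF-8, '.' decimal, header row
mandatory.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import creaming, datasets, doe
from .errors import PipelineStageError, SchemaError
from .imaging import variation_rate

__all__ = [
    "SCHEMAS",
    "load_table",
    "write_table",
    "PipelineConfig",
    "run_pipeline",
]

#: Schema name -> ordered {column: numpy dtype kind sets} ('i' integer-like,
#: 'f' float-like, 'O' free text).  A key column listed in UNIQUE must not
#: repeat.
SCHEMAS: dict[str, dict[str, str]] = {
    "design_responses": {
        "run": "i",
        "block": "i",
        "oil_pct": "f",
        "starch_pct": "f",
        "caseinate_pct": "f",
        "stir_rpm": "f",
        "stir_min": "f",
        "size_t0_um": "f",
        "size_t5_um": "f",
        "creaming_class": "i",
    },
    "droplets": {"droplet_id": "i", "diameter_px": "f", "diameter_um": "f"},
    "droplet_truth": {
        "droplet_id": "i",
        "x_px": "f",
        "y_px": "f",
        "diameter_px": "f",
        "diameter_um": "f",
    },
    "flow_curve": {"frequency_hz": "f", "stress_pa": "f"},
    "size_summary": {
        "sample": "O",
        "timepoint": "O",
        "n": "i",
        "mean_um": "f",
        "d32_um": "f",
    },
    "creaming_inputs": {
        "sample": "O",
        "yield_pa": "f",
        "ads_um": "f",
        "lds_um": "f",
    },
}

_UNIQUE: dict[str, str] = {
    "design_responses": "run",
    "droplets": "droplet_id",
    "droplet_truth": "droplet_id",
}


def load_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a CSV and validate it against a named schema.

    Raises :class:`SchemaError` naming the offending column or row on a
    missing column, an uncoercible value, or a duplicated key.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file (schema {schema!r})") from exc
    for col, kind in spec.items():
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r} (schema {schema!r})")
        if kind in ("i", "f"):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise SchemaError(
                    f"{path}: column {col!r} has a non-numeric value at row {row}"
                )
            if coerced.isna().any():
                row = int(coerced.isna().idxmax())
                raise SchemaError(f"{path}: column {col!r} missing value at row {row}")
            df[col] = coerced.astype(int if kind == "i" else float)
    key = _UNIQUE.get(schema)
    if key is not None and df[key].duplicated().any():
        dup = df[key][df[key].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicated {key} {dup!r}")
    return df[list(spec)]


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    """Write a CSV restricted to, and ordered by, the schema's columns."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}")
    cols = list(SCHEMAS[schema])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing columns {missing}")
    df[cols].to_csv(path, index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full analysis run.

    Paths left as ``None`` fall back to the bundled study tables, so the
    default config reproduces the bundled analysis end to end.
    """

    design_csv: str | None = None  # design_responses schema
    creaming_csv: str | None = None  # creaming_inputs schema
    flow_curve_csvs: dict[str, str] = field(default_factory=dict)  # sample -> path
    outdir: str = "emulstab_report"
    seed: int = 0
    alpha: float = 0.05
    stress_per_length: float | None = None  # Pa/m; None -> calibrated default
    responses: tuple[str, ...] = ("s0", "s5", "var", "class")
    include_blocks: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "responses" in raw:
            raw["responses"] = tuple(raw["responses"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("sizes")
def _stage_sizes(table: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    out = table[["run", "size_t0_um", "size_t5_um", "creaming_class"]].copy()
    diffs, rates = zip(
        *(
            variation_rate(s0, s5)
            for s0, s5 in zip(out["size_t0_um"], out["size_t5_um"])
        )
    )
    out["delta_um"] = diffs
    out["size_var_pct"] = rates
    out.to_csv(outdir / "sizes.csv", index=False)
    return out


@_stage("models")
def _stage_models(
    table: pd.DataFrame, config: PipelineConfig, outdir: Path
) -> dict[str, dict]:
    fits = {}
    for resp in config.responses:
        fit = doe.fit_response(
            table, response=resp, include_blocks=config.include_blocks
        )
        pareto = doe.effect_pareto(fit, alpha=config.alpha)
        scan = doe.scan_response(
            table, response=resp, include_blocks=config.include_blocks
        )
        fits[resp] = {
            "fit": fit.to_dict(),
            "boxcox": {"lambda_best": scan.lambda_best, "named": scan.transform},
            "pareto": {
                "t_limit": pareto.t_limit,
                "bonferroni_limit": pareto.bonferroni_limit,
                "effects": pareto.table.to_dict(orient="records"),
            },
        }
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True))
    return fits


@_stage("creaming_index")
def _stage_creaming(config: PipelineConfig, outdir: Path) -> pd.DataFrame:
    if config.creaming_csv is not None:
        inputs = load_table(config.creaming_csv, "creaming_inputs")
        k = config.stress_per_length
        rows = []
        for rec in inputs.itertuples(index=False):
            sigma_a = creaming.micro_stress(rec.ads_um, k)
            sigma_l = creaming.micro_stress(rec.lds_um, k)
            rows.append(
                {
                    "sample": rec.sample,
                    "yield_pa": rec.yield_pa,
                    "ads_um": rec.ads_um,
                    "lds_um": rec.lds_um,
                    "sigma_ads_pa": sigma_a,
                    "sigma_lds_pa": sigma_l,
                    "ci_ads": creaming.creaming_index(rec.yield_pa, sigma_a),
                    "ci_lds": creaming.creaming_index(rec.yield_pa, sigma_l),
                }
            )
        result = pd.DataFrame(rows)
    else:
        result = creaming.assess_from_table(
            stress_per_length=config.stress_per_length
        )
    result.to_csv(outdir / "creaming_index.csv", index=False)
    return result


@_stage("selection")
def _stage_selection(sizes: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    selected = creaming.select_stable(sizes)
    selected.to_csv(outdir / "selection.csv", index=False)
    return selected


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full analysis and write a report bundle to ``config.outdir``.

    Outputs: sizes.csv (derived 5-h size change and rate), fits.json
    (models, Box-Cox scans, Pareto screens), creaming_index.csv,
    selection.csv, and report.json summarizing everything.  Returns the
    report dictionary.  Any stage failure raises
    :class:`PipelineStageError` naming the stage.
    """
    from . import __version__

    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.design_csv is not None:
        table = load_table(config.design_csv, "design_responses")
    else:
        table = datasets.design_with_responses()

    sizes = _stage_sizes(table, outdir)
    fits = _stage_models(table, config, outdir)
    index = _stage_creaming(config, outdir)
    selected = _stage_selection(sizes, outdir)

    report = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_runs": int(len(table)),
        "selected_runs": [int(r) for r in selected["run"]]
        if "run" in selected.columns
        else selected.index.tolist(),
        "creaming_index": {
            str(r["sample"]): {
                "ci_ads": float(r["ci_ads"]),
                "ci_lds": float(r["ci_lds"]),
            }
            for _, r in index.iterrows()
        },
        "models": {
            resp: {
                "transform": fits[resp]["fit"]["transform"],
                "r2_raw": fits[resp]["fit"]["r2_raw"],
                "boxcox_lambda": fits[resp]["boxcox"]["lambda_best"],
            }
            for resp in fits
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
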