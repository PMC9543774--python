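"""CSV/JSON interchange for run tables and fit reports.

The run table is the package's on-disk unit of experimental input: one row
per scouting gradient run, with unit-suffixed column names so that times are
unambiguously minutes. Dead and dwell time may be given directly (``t0_min``,
``tD_min``) or as volumes with a flow rate (``V0_ml``, ``VD_ml``,
``flow_ml_min``), never both. Compositions are fractions by default; percent
input is accepted behind an explicit flag and converted on read.

Fit reports mirror the regression/exact fit results one row per compound and
round-trip losslessly at 12 significant digits (CSV) or exactly (JSON).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import GradientProgram, LSSParameters
from .estimation import DEFAULT_KI_CUTOFF, DEFAULT_R2_THRESHOLD, RegressionFit, RunObservation

__all__ = [
    "RUN_TABLE_COLUMNS",
    "VOLUME_COLUMNS",
    "FIT_REPORT_COLUMNS",
    "RunTableError",
    "read_run_table",
    "write_run_table",
    "runs_to_frame",
    "frame_to_runs",
    "fit_report_frame",
    "write_fit_report",
    "read_fit_report",
    "write_fit_report_json",
    "read_config",
]

RUN_TABLE_COLUMNS = ("compound_id", "Ci", "Cf", "tg_min", "t0_min", "tD_min", "tr_min")
VOLUME_COLUMNS = ("V0_ml", "VD_ml", "flow_ml_min")
FIT_REPORT_COLUMNS = (
    "compound_id",
    "method",
    "n_runs",
    "alpha",
    "beta",
    "r2",
    "S",
    "log_k0",
    "log_ki",
    "applicable",
    "linearity_ok",
    "ki_cutoff",
    "r2_threshold",
)

#: 12 significant digits: lossless enough for round-tripping retention data.
FLOAT_FORMAT = "%.12g"


class RunTableError(ValueError):
    """A run-table file violates the schema."""


def read_run_table(path, composition_unit: str = "fraction") -> pd.DataFrame:
    """Read and validate a run table, normalizing to canonical columns.

    Accepts either time columns (``t0_min``, ``tD_min``) or volume columns
    (``V0_ml``, ``VD_ml``, ``flow_ml_min``); mixing both forms is rejected.
    With ``composition_unit="percent"`` the Ci/Cf columns are divided by 100.
    """
    if composition_unit not in ("fraction", "percent"):
        raise RunTableError(f"composition_unit must be 'fraction' or 'percent', got {composition_unit!r}")
    df = pd.read_csv(path)
    cols = set(df.columns)
    has_times = {"t0_min", "tD_min"} <= cols
    has_volumes = set(VOLUME_COLUMNS) <= cols
    if has_times and (cols & set(VOLUME_COLUMNS)):
        raise RunTableError(
            "run table mixes time columns (t0_min/tD_min) with volume columns "
            f"({', '.join(sorted(cols & set(VOLUME_COLUMNS)))}); provide one form only"
        )
    base_required = {"compound_id", "Ci", "Cf", "tg_min", "tr_min"}
    missing = base_required - cols
    if missing:
        raise RunTableError(f"run table missing required columns: {', '.join(sorted(missing))}")
    if not has_times:
        if not has_volumes:
            raise RunTableError(
                "run table needs either t0_min/tD_min or V0_ml/VD_ml/flow_ml_min"
            )
        df = df.copy()
        df["t0_min"] = df["V0_ml"] / df["flow_ml_min"]
        df["tD_min"] = df["VD_ml"] / df["flow_ml_min"]

    df = df.loc[:, list(RUN_TABLE_COLUMNS)].copy()
    numeric = [c for c in RUN_TABLE_COLUMNS if c != "compound_id"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="raise")
    if df[numeric].isna().any().any():
        bad = df.index[df[numeric].isna().any(axis=1)].tolist()
        raise RunTableError(f"run table has missing numeric values in rows {bad}")
    if composition_unit == "percent":
        df["Ci"] = df["Ci"] / 100.0
        df["Cf"] = df["Cf"] / 100.0
    return df


def frame_to_runs(df: pd.DataFrame) -> dict[str, list[RunObservation]]:
    """Group a validated run table into per-compound observation lists.

    Row-level invariant violations (bad window, non-positive times) surface
    as ``ValueError`` naming the compound.
    """
    out: dict[str, list[RunObservation]] = {}
    for cid, sub in df.groupby("compound_id", sort=False):
        runs = []
        for _, row in sub.iterrows():
            try:
                g = GradientProgram(
                    Ci=row["Ci"], Cf=row["Cf"], tg=row["tg_min"], t0=row["t0_min"], tD=row["tD_min"]
                )
                runs.append(RunObservation(program=g, tr_obs=row["tr_min"], compound_id=str(cid)))
            except ValueError as e:
                raise RunTableError(f"compound {cid!r}: {e}") from e
        out[str(cid)] = runs
    return out


def runs_to_frame(runs: Sequence[RunObservation]) -> pd.DataFrame:
    """Flatten run observations into the run-table schema."""
    return pd.DataFrame(
        [
            {
                "compound_id": r.compound_id,
                "Ci": r.program.Ci,
                "Cf": r.program.Cf,
                "tg_min": r.program.tg,
                "t0_min": r.program.t0,
                "tD_min": r.program.tD,
                "tr_min": r.tr_obs,
            }
            for r in runs
        ],
        columns=list(RUN_TABLE_COLUMNS),
    )


def write_run_table(df_or_runs, path) -> None:
    """Write a run table CSV (times in minutes, compositions as fractions)."""
    df = df_or_runs if isinstance(df_or_runs, pd.DataFrame) else runs_to_frame(df_or_runs)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _fit_row(compound_id: str, fit) -> dict:
    if isinstance(fit, RegressionFit):
        return {
            "compound_id": compound_id,
            "method": fit.method,
            "n_runs": fit.n_runs,
            "alpha": fit.alpha,
            "beta": fit.beta,
            "r2": fit.r2,
            "S": fit.params.S,
            "log_k0": fit.params.log_k0,
            "log_ki": fit.log_ki,
            "applicable": fit.applicable,
            "linearity_ok": fit.linearity_ok,
            "ki_cutoff": fit.ki_cutoff,
            "r2_threshold": fit.r2_threshold,
        }
    raise TypeError(f"cannot serialize fit of type {type(fit).__name__}")


def fit_report_frame(fits: Mapping[str, RegressionFit]) -> pd.DataFrame:
    """One report row per compound from a mapping of fit results."""
    return pd.DataFrame(
        [_fit_row(cid, f) for cid, f in fits.items()], columns=list(FIT_REPORT_COLUMNS)
    )


def write_fit_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_fit_report(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FIT_REPORT_COLUMNS) - set(df.columns)
    if missing:
        raise RunTableError(f"fit report missing columns: {', '.join(sorted(missing))}")
    return df


def write_fit_report_json(df: pd.DataFrame, path) -> None:
    """JSON mirror of the fit report (exact floats, one object per compound)."""
    records = df.to_dict(orient="records")
    for rec in records:
        for k, v in rec.items():
            if isinstance(v, float) and math.isnan(v):
                rec[k] = None
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def read_config(path) -> dict:
    """Read a TOML key=value configuration file for thresholds and N.

    Recognized keys: ``ki_cutoff``, ``r2_threshold``, ``n_plates``.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    known = {"ki_cutoff", "r2_threshold", "n_plates"}
    unknown = set(cfg) - known
    if unknown:
        raise RunTableError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return cfg
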