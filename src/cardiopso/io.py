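"""CSV/JSON/YAML ingestion and serialization for cohort tables and
experiment reports.

The cohort CSV dialect has a header row of the schema's 14 column names;
the tokens ``""``, ``"?"`` and ``"NA"`` mark missing cells (the UCI
files use ``"?"``).  Ingestion never silently coerces: every token
either parses as a number under the schema, maps to missing, or raises
a :class:`~cardiopso.exceptions.SchemaError` naming the offending
row/column.  Continuous values outside the schema's plausible range are
admitted but logged — they may be exactly the outliers the pipeline
exists to repair.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError
from .harness import ExperimentReport
from .schema import DEFAULT_SCHEMA, SchemaSpec

__all__ = [
    "read_cohort_csv",
    "write_cohort_csv",
    "write_report",
    "load_yaml_config",
]

logger = logging.getLogger("cardiopso")


def read_cohort_csv(path: str | Path, schema: SchemaSpec = DEFAULT_SCHEMA) -> pd.DataFrame:
    """Read a cohort CSV, validating against ``schema``.

    Missing tokens become ``NaN``; malformed numeric tokens raise with
    row/column coordinates; row order is preserved.
    """
    raw = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        na_values=list(schema.missing_tokens),
        skipinitialspace=True,
    )
    if tuple(raw.columns) != schema.column_names:
        raise SchemaError(
            f"{path}: column mismatch: expected {list(schema.column_names)}, "
            f"got {list(raw.columns)}"
        )
    out = {}
    for spec in schema.columns:
        converted = pd.to_numeric(raw[spec.name], errors="coerce")
        bad = converted.isna() & raw[spec.name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: non-numeric token {raw[spec.name].iloc[row]!r} "
                f"in column {spec.name!r} at row {row}"
            )
        out[spec.name] = converted.astype(float)
    df = pd.DataFrame(out, columns=list(schema.column_names))
    schema.validate(df, allow_missing=True)
    for spec in schema.columns:
        if spec.lo is not None:
            col = df[spec.name]
            n_oob = int(((col < spec.lo) | (col > spec.hi)).sum())
            if n_oob:
                logger.warning(
                    "%s: %d value(s) in %r outside plausible range [%s, %s]",
                    path, n_oob, spec.name, spec.lo, spec.hi,
                )
    return df


def write_cohort_csv(
    table: pd.DataFrame, path: str | Path, schema: SchemaSpec = DEFAULT_SCHEMA
) -> None:
    """Write a cohort CSV in the ingestion dialect (missing -> '?');
    a write -> read round trip is the identity, missing markers
    included."""
    table.to_csv(path, index=False, na_rep="?")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_PANEL_ORDER = (
    "balanced_accuracy", "accuracy", "sensitivity", "specificity",
    "precision", "f1", "npv", "mcc",
)


def write_report(report: ExperimentReport, path: str | Path, format: str = "json") -> None:
    """Serialize an :class:`ExperimentReport`.

    ``json`` is loss-free and round-trippable through
    ``ExperimentReport.to_dict``; ``markdown`` renders one metric table
    (percentages at 2 dp, half-up) and one likelihood-ratio/DOR table,
    one row per (family, ratio) cell.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2, default=_json_default))
        return
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    lines = [f"# Experiment report — mode: {report.mode}", ""]
    header = "| ratio | model | " + " | ".join(_PANEL_ORDER) + " |"
    lines += [header, "|" + "---|" * (len(_PANEL_ORDER) + 2)]
    for c in report.cells:
        pct = c.panel.to_percent()
        cells = " | ".join(f"{pct[k]:.2f}" for k in _PANEL_ORDER)
        lines.append(f"| {c.ratio} | {c.family} | {cells} |")
    lines += ["", "| ratio | model | LR+ | LR- | DOR |", "|---|---|---|---|---|"]
    for c in report.cells:
        r = c.ratios_panel
        lines.append(
            f"| {c.ratio} | {c.family} | {r.lr_plus:.2f} | {r.lr_minus:.4f} | {r.dor:.2f} |"
        )
    path.write_text("\n".join(lines) + "\n")


def load_yaml_config(path: str | Path) -> dict:
    """Load a YAML configuration mapping (empty file -> empty dict)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
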