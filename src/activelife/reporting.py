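"""Publication-style tables from an expectancy table.

Rows are (age, initial condition); value columns are total life expectancy,
per-state years, ALE, DFLE, years with disability and the difference
columns against the no-limitation start. Years round to 0.1; the percent of
remaining life spent active rounds half-up to an integer. DFLE and the
difference columns are computed on unrounded values and rounded last, so a
printed difference can disagree with the difference of printed values by
0.1 — the usual behaviour of published life-table reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

_META = ["age", "initial"]


def round_half_up(x, decimals: int = 0):
    """Decimal rounding with ties away from zero (5 rounds up)."""
    factor = 10.0 ** decimals
    arr = np.asarray(x, dtype=float)
    out = np.floor(np.abs(arr) * factor + 0.5) / factor * np.sign(arr)
    return float(out) if np.isscalar(x) else out


@dataclass
class ReportSpec:
    """What to render: scheme, stratification, ages, rounding, formats."""

    scheme: str = "three_level"
    stratification: str = "none"  # 'none' | 'sex'
    ages: Optional[Sequence[float]] = None  # default: all ages present
    year_decimals: int = 1
    formats: tuple = ("csv",)  # 'csv', 'json'
    label: str = "expectancy"


def percent_active(e_total, ale):
    """Integer percent of remaining life expected without limitation."""
    return round_half_up(100.0 * np.asarray(ale) / np.asarray(e_total), 0)


def render_tables(
    expectancy: pd.DataFrame,
    se: Optional[pd.DataFrame] = None,
    spec: Optional[ReportSpec] = None,
) -> dict:
    """Assemble rounded report tables (and a companion SE table if given).

    Returns ``{'expectancy': DataFrame, 'se': DataFrame?}`` — values
    rounded for print; the unrounded table remains the machine-readable
    output of the pipeline itself.
    """
    spec = spec or ReportSpec()
    df = expectancy.copy()
    if spec.ages is not None:
        df = df[df["age"].isin(list(spec.ages))]
        if df.empty:
            raise ValueError("no requested ages present in the expectancy table")
    needed = {"e_total", "ale", "dfle"}
    if not needed.issubset(df.columns):
        raise ValueError(f"expectancy table lacks columns {sorted(needed - set(df.columns))}")
    strat_cols = [c for c in ("sex",) if c in df.columns and spec.stratification == "sex"]
    pct = percent_active(df["e_total"], df["ale"])
    value_cols = [c for c in df.columns if c not in _META + strat_cols]
    out = df[strat_cols + _META].copy()
    for c in value_cols:
        out[c] = round_half_up(df[c].to_numpy(), spec.year_decimals)
    out["percent_active"] = pct.astype(int)
    tables = {"expectancy": out.reset_index(drop=True)}
    if se is not None:
        se_out = se.copy()
        if spec.ages is not None:
            se_out = se_out[se_out["age"].isin(list(spec.ages))]
        for c in se_out.columns:
            if c not in _META + strat_cols:
                se_out[c] = round_half_up(se_out[c].to_numpy(), 2)
        tables["se"] = se_out.reset_index(drop=True)
    return tables


def fig_summary(expectancy: pd.DataFrame) -> pd.DataFrame:
    """Long-format summary (age, initial state, measure, years) for charts.

    Covers the four headline measures per starting state, matching the
    five-level-scheme figure layout.
    """
    keep = expectancy[expectancy["initial"] != "total"]
    long = keep.melt(
        id_vars=_META,
        value_vars=["e_total", "ale", "dfle", "years_disabled"],
        var_name="measure", value_name="years",
    )
    long["years"] = round_half_up(long["years"].to_numpy(), 1)
    return long.sort_values(["age", "initial", "measure"]).reset_index(drop=True)


def write_report(tables: dict, out_base: Path | str, spec: Optional[ReportSpec] = None) -> list:
    """Write each table as CSV and/or JSON next to ``out_base``.

    JSON output stores the unrounded-precision values exactly as present in
    the tables (round-trips bit-exactly through ``pd.read_json``).
    """
    spec = spec or ReportSpec()
    out_base = Path(out_base)
    written = []
    for name, df in tables.items():
        stem = out_base if name == "expectancy" else out_base.with_name(
            f"{out_base.stem}_{name}{out_base.suffix or ''}")
        if "csv" in spec.formats:
            p = Path(str(stem)).with_suffix(".csv")
            df.to_csv(p, index=False)
            written.append(p)
        if "json" in spec.formats:
            p = Path(str(stem)).with_suffix(".json")
            df.to_json(p, orient="records", double_precision=15)
            written.append(p)
    return written
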