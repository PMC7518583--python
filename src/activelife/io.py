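"""Reading and writing the package's file formats.

Panel CSV: one row per participant with columns
``id, sex, age_base, <item>_b x6, <item>_f x6, interval_years, dead,
time_to_death_years, responded_followup`` — ADL items 0/1 with empty fields
for missing. Life-table CSV: ``age,qx``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .staging import ADL_ITEMS

PANEL_COLUMNS = (
    ["id", "sex", "age_base"]
    + [f"{it}_b" for it in ADL_ITEMS]
    + [f"{it}_f" for it in ADL_ITEMS]
    + ["interval_years", "dead", "time_to_death_years", "responded_followup"]
)


def read_panel(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file lacks columns {missing}")
    return df


def write_panel(panel: pd.DataFrame, path: Path | str) -> None:
    panel.to_csv(path, index=False, columns=PANEL_COLUMNS)


def read_lifetable(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"age", "qx"}.issubset(df.columns):
        raise ValueError("life table must have columns age,qx")
    if ((df["qx"] <= 0) | (df["qx"] >= 1)).any():
        raise ValueError("life-table qx must lie strictly in (0, 1)")
    return df.sort_values("age").reset_index(drop=True)


def write_lifetable(lifetable: pd.DataFrame, path: Path | str) -> None:
    lifetable.to_csv(path, index=False, columns=["age", "qx"])
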