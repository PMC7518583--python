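"""Disability staging from activities-of-daily-living (ADL) items.

Six binary difficulty items — bathing, dressing, eating, getting in/out of
chairs, walking, toileting — are classified into the Stineman ADL stages
0–IV, a hierarchical severity scale:

* Stage 0   no difficulty with any of the six activities
* Stage I   mild: difficulty only with chairs and/or walking
* Stage II  moderate: difficulty with bathing and/or dressing, but not
            eating or toileting
* Stage III severe: difficulty with eating and/or toileting, but not with
            all six activities
* Stage IV  complete: difficulty with all six activities

The rules are applied as an if/else cascade IV -> III -> II -> I -> 0, which
partitions all 64 fully observed item patterns. A battery with any missing
item is staged as missing (no imputation).

Stages are collapsed into one of three analysis schemes: binary (any
limitation vs none), three-level (none / mild / disabled), or the full
five-level staging. State 1 is always the active (stage 0) reference state;
the absorbing death state is k+1 and never appears in these maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: canonical item order used throughout the package and in panel CSV columns
ADL_ITEMS = ("bathing", "dressing", "eating", "chairs", "walking", "toileting")


class Stage(IntEnum):
    """Stineman ADL stage; integer value equals the stage number."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3
    COMPLETE = 4


def stage_from_adl(items: Mapping[str, object] | Sequence[object]) -> Optional[Stage]:
    """Stage a single six-item ADL battery.

    Parameters
    ----------
    items
        Either a mapping with keys :data:`ADL_ITEMS` or a sequence of six
        values in that order. Each value is truthy/falsy for
        difficulty/no difficulty, or ``None``/NaN for missing.

    Returns
    -------
    Stage or None
        ``None`` when any item is missing.
    """
    if isinstance(items, Mapping):
        vals = [items[k] for k in ADL_ITEMS]
    else:
        vals = list(items)
    if len(vals) != len(ADL_ITEMS):
        raise ValueError(f"expected {len(ADL_ITEMS)} ADL items, got {len(vals)}")
    norm = []
    for v in vals:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        norm.append(bool(v))
    bathing, dressing, eating, chairs, walking, toileting = norm
    if all(norm):
        return Stage.COMPLETE
    if eating or toileting:
        return Stage.SEVERE
    if bathing or dressing:
        return Stage.MODERATE
    if chairs or walking:
        return Stage.MILD
    return Stage.NONE


def stage_frame(items: pd.DataFrame) -> pd.Series:
    """Vectorised staging of an n x 6 frame with columns :data:`ADL_ITEMS`.

    Returns a float Series with values 0..4 and NaN where any item is
    missing. Mirrors the cascade in :func:`stage_from_adl`.
    """
    arr = items[list(ADL_ITEMS)].to_numpy(dtype=float)
    missing = np.isnan(arr).any(axis=1)
    b = arr > 0.5  # booleans; rows with NaN handled by the mask below
    bathing, dressing, eating, chairs, walking, toileting = (b[:, i] for i in range(6))
    out = np.zeros(len(items), dtype=float)
    out[chairs | walking] = 1.0
    out[bathing | dressing] = 2.0
    out[eating | toileting] = 3.0
    out[b.all(axis=1)] = 4.0
    out[missing] = np.nan
    return pd.Series(out, index=items.index, name="stage")


# ---------------------------------------------------------------------------
# State schemes


@dataclass(frozen=True)
class StateScheme:
    """A collapse of stages 0-IV into k ordered transient states.

    ``collapse[stage] = state`` with states numbered 1..k; state 1 is the
    active/no-limitation reference state, and higher states are never less
    severe. ``nondisabled_states`` are the states counted in disability-free
    life expectancy (stages 0 and I where the scheme separates them).
    """

    name: str
    k: int
    collapse: tuple[int, ...]
    nondisabled_states: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.collapse) != 5:
            raise ValueError("collapse map must cover stages 0..4")
        if self.collapse[0] != 1 or 1 in self.collapse[1:]:
            raise ValueError("state 1 must be exactly stage 0")
        if list(self.collapse) != sorted(self.collapse):
            raise ValueError("collapse map must be order-preserving")
        if max(self.collapse) != self.k:
            raise ValueError("collapse map must reach state k")

    @property
    def states(self) -> tuple[int, ...]:
        return tuple(range(1, self.k + 1))

    @property
    def dead_state(self) -> int:
        return self.k + 1

    def stages_for_state(self, state: int) -> tuple[int, ...]:
        return tuple(s for s in range(5) if self.collapse[s] == state)


BINARY = StateScheme("binary", 2, (1, 2, 2, 2, 2), (1,))
THREE_LEVEL = StateScheme("three_level", 3, (1, 2, 3, 3, 3), (1, 2))
FIVE_LEVEL = StateScheme("five_level", 5, (1, 2, 3, 4, 5), (1, 2))

SCHEMES = {s.name: s for s in (BINARY, THREE_LEVEL, FIVE_LEVEL)}


def get_scheme(name: str) -> StateScheme:
    try:
        return SCHEMES[name]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {sorted(SCHEMES)}") from None


def collapse_stage(stage: Optional[Stage | int], scheme: StateScheme) -> Optional[int]:
    """Map a stage to its transient state index under ``scheme``.

    A missing stage (``None``/NaN) propagates as ``None`` — it marks a
    missing state, not an error.
    """
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return None
    return scheme.collapse[int(stage)]


def add_states(panel: pd.DataFrame, scheme: StateScheme) -> pd.DataFrame:
    """Stage both waves of a panel and attach ``state_b``/``state_f`` columns.

    The panel carries the six ADL items per wave as ``<item>_b`` and
    ``<item>_f`` columns. Participants who died or did not respond have no
    follow-up battery; their ``state_f`` is NaN.
    """
    out = panel.copy()
    cmap = np.asarray(scheme.collapse, dtype=float)
    for wave, col in (("b", "state_b"), ("f", "state_f")):
        items = panel[[f"{it}_{wave}" for it in ADL_ITEMS]].copy()
        items.columns = list(ADL_ITEMS)
        stg = stage_frame(items).to_numpy()
        st = np.full(len(panel), np.nan)
        ok = ~np.isnan(stg)
        st[ok] = cmap[stg[ok].astype(int)]
        out[col] = st
        out[f"stage_{wave}"] = stg
    return out


def all_adl_patterns() -> Iterable[tuple[bool, ...]]:
    """All 64 fully observed ADL patterns, in lexicographic order."""
    for code in range(64):
        yield tuple(bool((code >> i) & 1) for i in range(6))
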