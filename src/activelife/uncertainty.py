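"""Bootstrap standard errors for the expectancy estimates.

Participants (both waves together) are resampled with replacement and the
whole pipeline — transition rates, Cox hazard ratios, prevalence smooth,
anchoring, projection — is refit on each replicate. The reference life
table is an external population quantity and is held fixed. The SE of each
expectancy cell is the standard deviation across successful replicates;
2.5/97.5 percentiles give an interval. Replicates whose fits fail are
dropped and counted; more than 20% failures aborts with an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .lifetable import AgeGrid
from .pipeline import estimate_expectancies
from .staging import StateScheme

logger = logging.getLogger(__name__)

_META = ["age", "initial"]


@dataclass
class BootstrapResult:
    """Per-cell SEs and percentile intervals for an expectancy table."""

    b: int
    n_failures: int
    seed: int
    se: pd.DataFrame
    lo: pd.DataFrame  # 2.5th percentile
    hi: pd.DataFrame  # 97.5th percentile


def bootstrap_expectancies(
    panel: pd.DataFrame,
    lifetable: pd.DataFrame,
    scheme: StateScheme,
    b: int = 200,
    seed: int = 0,
    grid: Optional[AgeGrid] = None,
    with_age_interaction: Optional[bool] = None,
) -> BootstrapResult:
    """Resample participants and refit the pipeline ``b`` times."""
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    grid = grid or AgeGrid()
    rng = np.random.default_rng(seed)
    n = len(panel)
    reps = []
    failures = 0
    for r in range(b):
        idx = rng.integers(0, n, size=n)
        boot = panel.iloc[idx].reset_index(drop=True)
        try:
            fit = estimate_expectancies(
                boot, lifetable, scheme, grid, with_age_interaction
            )
        except Exception as exc:
            failures += 1
            logger.warning("bootstrap replicate %d failed: %s", r, exc)
            if failures > 0.2 * b:
                raise RuntimeError(
                    f"{failures} of {r + 1} bootstrap replicates failed"
                ) from exc
            continue
        reps.append(fit.expectancy.set_index(_META))
    stack = np.stack([r.to_numpy() for r in reps])  # (B_ok, cells, cols)
    template = reps[0]
    se = pd.DataFrame(stack.std(axis=0, ddof=1), index=template.index,
                      columns=template.columns).reset_index()
    lo = pd.DataFrame(np.percentile(stack, 2.5, axis=0), index=template.index,
                      columns=template.columns).reset_index()
    hi = pd.DataFrame(np.percentile(stack, 97.5, axis=0), index=template.index,
                      columns=template.columns).reset_index()
    return BootstrapResult(b, failures, seed, se, lo, hi)
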