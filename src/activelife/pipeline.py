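"""End-to-end estimation: panel + reference life table -> expectancy table."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import mortality, rates, staging
from .lifetable import AgeGrid, run_all_initial_conditions
from .staging import StateScheme


@dataclass
class PipelineFit:
    """Everything fitted on one panel, for inspection and serialisation."""

    scheme: StateScheme
    grid: AgeGrid
    rate_coefficients: rates.RateCoefficients
    hazard_ratios: mortality.HazardRatioModel
    prevalence: np.ndarray  # on grid.interval_starts
    death_probs: np.ndarray  # (T, k) anchored q_t^j on grid.interval_starts
    transition_probabilities: rates.TransitionProbabilities
    expectancy: pd.DataFrame


def estimate_expectancies(
    panel: pd.DataFrame,
    lifetable: pd.DataFrame,
    scheme: StateScheme,
    grid: Optional[AgeGrid] = None,
    with_age_interaction: Optional[bool] = None,
) -> PipelineFit:
    """Run the full multi-state analysis on a two-wave panel.

    Stages the ADL items, fits the pairwise transition-rate models and the
    Cox hazard ratios, anchors state-specific mortality to ``lifetable``
    (columns age, qx, covering the reported ages), projects every initial
    condition and returns the assembled expectancy table with the fitted
    components. Probabilities beyond the last reported age are held at
    their value there (closure).
    """
    grid = grid or AgeGrid()
    staged = panel if "state_b" in panel.columns else staging.add_states(panel, scheme)

    obs = rates.build_transition_observations(staged, scheme)
    coef = rates.fit_rates(obs, scheme)
    tp = rates.probabilities_on_grid(
        coef, grid.interval_starts, hold_after=grid.last_reported
    )

    hr = mortality.fit_hazard_ratios(staged, scheme, with_age_interaction)
    prev = mortality.estimate_prevalence(staged, scheme, grid.interval_starts)

    anchored_ages = grid.reported_ages
    q_anchor = mortality.anchor_death_probs_cohort(
        lifetable, hr, prev[0], tp, anchored_ages
    )
    # hold the last anchored row out to the closure age
    n_hold = len(grid.interval_starts) - len(anchored_ages)
    q_full = np.vstack([q_anchor, np.repeat(q_anchor[-1:], n_hold, axis=0)])

    tp = rates.attach_death_probs(tp, q_full)
    table = run_all_initial_conditions(tp, prev, grid, scheme)
    return PipelineFit(scheme, grid, coef, hr, prev, q_full, tp, table)
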