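"""Deterministic multi-state cohort projection and state expectancies.

A synthetic cohort of radix 1 starts at age x distributed over the k
transient states and is pushed through the two-year grid with the fitted
transition and death probabilities:

    l_{t+2}^i = l_t^i (1 - sum_{j != i} p_t^{i,j} - q_t^i)
                + sum_{j != i} l_t^j p_t^{j,i}

Person-years in state i over [t, t+2) follow the trapezoidal rule,
L_t^i = l_t^i + l_{t+2}^i, and the expected remaining years in state i are
e_x^i = (sum_{t >= x} L_t^i) / l_x with e_x = sum_i e_x^i. State 1 is the
active state, so ALE = e_x^1; DFLE additionally counts the mild-limitation
state where the scheme separates it.

Closure: probabilities are held at their age-95 values up to the closure
age (default 115), after which the residual cohort in state i is credited
(2 - q) / q years at the held state-specific death probability q — the
constant-hazard geometric tail. At default mortality the residual mass is
negligible and the tail contributes < 1e-3 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .rates import TransitionProbabilities
from .staging import StateScheme

TOTAL = "total"


@dataclass(frozen=True)
class AgeGrid:
    """Two-year age grid: reported ages 65..95, internal closure at 115."""

    start: float = 65.0
    step: float = 2.0
    last_reported: float = 95.0
    closure: float = 115.0

    def __post_init__(self):
        if self.step != 2.0:
            raise ValueError("the method is defined on a 2-year grid")
        if not (self.start <= self.last_reported < self.closure):
            raise ValueError("need start <= last_reported < closure")

    @property
    def interval_starts(self) -> np.ndarray:
        """Start age of every internal interval [t, t+2)."""
        return np.arange(self.start, self.closure, self.step)

    @property
    def reported_ages(self) -> np.ndarray:
        return np.arange(self.start, self.last_reported + self.step / 2, self.step)


@dataclass
class CohortTrajectory:
    """Occupancy l_t^i over the grid from one starting condition."""

    start_age: float
    ages: np.ndarray  # interval start ages, plus the closure age as last entry
    l: np.ndarray  # (len(ages), k) expected persons alive per state
    q_held: np.ndarray  # (k,) death probability used for the closure tail
    radix: float
    L: Optional[np.ndarray] = field(default=None, repr=False)  # person-years

    @property
    def deaths(self) -> np.ndarray:
        """Cumulative deaths at each grid age (radix minus alive)."""
        return self.radix - self.l.sum(axis=1)


def project_cohort(
    initial: np.ndarray,
    start_age: float,
    tp: TransitionProbabilities,
    grid: AgeGrid,
) -> CohortTrajectory:
    """Iterate the occupancy recursion from ``start_age`` to closure.

    ``tp`` must carry death probabilities (see
    :func:`activelife.rates.attach_death_probs`) on grid interval ages; ages
    past the end of ``tp.ages`` reuse its last row (held probabilities).
    """
    initial = np.asarray(initial, dtype=float)
    if initial.ndim != 1 or len(initial) != tp.k:
        raise ValueError(f"initial occupancy must have length k={tp.k}")
    if np.any(initial < 0):
        raise ValueError("initial occupancy must be non-negative")
    if tp.q is None:
        raise ValueError("transition probabilities lack death probabilities")
    radix = float(initial.sum())
    if radix <= 0:
        raise ValueError("zero radix")

    ages = np.arange(start_age, grid.closure + grid.step / 2, grid.step)
    k = tp.k
    l = np.zeros((len(ages), k))
    l[0] = initial
    last = len(tp.ages) - 1
    for t in range(len(ages) - 1):
        idx = min(np.searchsorted(tp.ages, ages[t]), last)
        if tp.ages[min(idx, last)] != ages[t] and ages[t] <= tp.ages[last]:
            raise ValueError(f"age {ages[t]} not on the probability grid")
        p = tp.p[idx]
        q = tp.q[idx]
        stay = 1.0 - p.sum(axis=1) - q
        new = l[t] * stay + l[t] @ p
        bad = new < -1e-9
        if bad.any():
            i = int(np.argmin(new))
            raise ValueError(
                f"negative occupancy at age {ages[t + 1]:.0f}, state {i + 1}: "
                f"{new[i]:.3g} (inconsistent probabilities)"
            )
        l[t + 1] = np.clip(new, 0.0, None)
        if l[t + 1].sum() < 1e-9 * radix:
            l = l[: t + 2]
            ages = ages[: t + 2]
            break
    q_held = tp.q[min(np.searchsorted(tp.ages, ages[-1]), last)]
    return CohortTrajectory(start_age, ages, l, q_held, radix)


def person_years(traj: CohortTrajectory) -> np.ndarray:
    """Trapezoidal person-years per interval and state, with closure tail.

    Returns an array with one row per interval plus a final tail row
    ``l_T^i (2 - q_i) / q_i`` for the residual cohort at the closure age.
    The result is also cached on ``traj.L``.
    """
    L = traj.l[:-1] + traj.l[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = traj.l[-1] * (2.0 - traj.q_held) / traj.q_held
    tail = np.where(traj.l[-1] > 0, tail, 0.0)
    if not np.all(np.isfinite(tail)):
        raise ValueError("closure tail undefined: zero death probability with survivors")
    out = np.vstack([L, tail])
    traj.L = out
    return out


def expectancies(traj: CohortTrajectory, scheme: StateScheme) -> dict:
    """Remaining-years summary for one trajectory.

    Returns e_total, per-state e_i, ALE (= e_1), DFLE (sum over the
    scheme's non-disabled states) and years lived with disability.
    """
    L = traj.L if traj.L is not None else person_years(traj)
    e_i = L.sum(axis=0) / traj.radix
    nd = [s - 1 for s in scheme.nondisabled_states]
    e_total = float(e_i.sum())
    dfle = float(e_i[nd].sum())
    out = {"e_total": e_total}
    out.update({f"e_{s}": float(e_i[s - 1]) for s in scheme.states})
    out["ale"] = float(e_i[0])
    out["dfle"] = dfle
    out["years_disabled"] = e_total - dfle
    return out


def run_all_initial_conditions(
    tp: TransitionProbabilities,
    prevalence: np.ndarray,
    grid: AgeGrid,
    scheme: StateScheme,
) -> pd.DataFrame:
    """Expectancy table over reported ages and initial conditions.

    For each reported age x: a 'total' row started at the prevalence
    distribution pi(x) and one row per single-state start. Difference
    columns are (no-limitation row) minus (this row) for total life
    expectancy and ALE, computed on unrounded values.
    """
    prevalence = np.asarray(prevalence, dtype=float)
    if prevalence.shape != (len(tp.ages), tp.k):
        raise ValueError("prevalence must be given on the probability grid")
    rows = []
    for x in grid.reported_ages:
        idx = int(np.searchsorted(tp.ages, x))
        conds = [(TOTAL, prevalence[idx])]
        for s in scheme.states:
            v = np.zeros(scheme.k)
            v[s - 1] = 1.0
            conds.append((f"state_{s}", v))
        ref = None
        for label, init in conds:
            traj = project_cohort(init, x, tp, grid)
            row = {"age": x, "initial": label, **expectancies(traj, scheme)}
            rows.append(row)
            if label == "state_1":
                ref = row
        for row in rows[-len(conds):]:
            row["diff_total"] = ref["e_total"] - row["e_total"]
            row["diff_active"] = ref["ale"] - row["ale"]
    return pd.DataFrame(rows)
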