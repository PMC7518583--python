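"""Transition-intensity estimation from interval-censored two-wave panels.

Between the two interviews, only the pair (state at baseline, state at
follow-up) is observed, at a person-specific interval length. Assuming a
constant instantaneous rate mu_ij within an age interval, each ordered pair
of transient states (i, j) gets its own log-linear rate model

    log mu_ij(age) = alpha_ij + beta_ij * age,

fitted by Poisson regression with the observed i->j move as the outcome,
log interval length as the offset, and mid-interval age as the covariate.
Participants who died before follow-up, did not respond, or have a missing
disability state at either wave contribute no transition observations.

Rates convert to two-year transition probabilities via
``p = 1 - exp(-2 mu)``, evaluated at the midpoint of each two-year age
interval of the life-table grid. State-specific death probabilities come
from a separate, externally anchored model (see ``mortality``); when the
independently computed row sum of transition plus death probabilities
exceeds 1 for some age and origin, the transition probabilities (never the
anchored death probability) are rescaled proportionally.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .staging import StateScheme, get_scheme

logger = logging.getLogger(__name__)

PairKey = Tuple[int, int]


def build_transition_observations(
    panel: pd.DataFrame, scheme: StateScheme
) -> pd.DataFrame:
    """Expand a staged panel into per-pair transition observations.

    ``panel`` must carry ``state_b``/``state_f`` columns (see
    :func:`activelife.staging.add_states`). One row is produced per
    surviving respondent with both states observed and per candidate
    destination j != origin i: columns origin, dest, age (mid-interval),
    exposure (interval length, years), event (1 if follow-up state == j).
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    usable = (
        (panel["dead"] == 0)
        & (panel["responded_followup"] == 1)
        & panel["state_b"].notna()
        & panel["state_f"].notna()
    )
    n_excluded = int((~usable).sum())
    logger.info(
        "transition observations: %d respondents usable, %d excluded "
        "(death, non-response or missing state)", int(usable.sum()), n_excluded
    )
    sub = panel.loc[usable]
    if len(sub) == 0:
        raise ValueError("no usable transition observations in panel")
    origin = sub["state_b"].to_numpy(dtype=int)
    dest_f = sub["state_f"].to_numpy(dtype=int)
    age = sub["age_base"].to_numpy(dtype=float) + sub["interval_years"].to_numpy() / 2.0
    exposure = sub["interval_years"].to_numpy(dtype=float)
    if np.any(exposure <= 0):
        raise ValueError("non-positive exposure in panel")

    frames = []
    for j in scheme.states:
        mask = origin != j
        frames.append(pd.DataFrame({
            "origin": origin[mask],
            "dest": j,
            "age": age[mask],
            "exposure": exposure[mask],
            "event": (dest_f[mask] == j).astype(int),
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class PairRate:
    """Fitted log-linear rate for one ordered transient-state pair."""

    origin: int
    dest: int
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    n_obs: int
    n_events: int
    converged: bool
    degenerate: bool  # no events: mu fixed at 0
    cov_ab: float = 0.0  # covariance of (alpha, beta)

    def mu(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if self.degenerate:
            return np.zeros(ages.shape)
        return np.exp(self.alpha + self.beta * ages)

    def se_log_mu(self, age: float) -> float:
        """Delta-method standard error of log mu at one age."""
        return float(np.sqrt(self.se_alpha ** 2 + (age * self.se_beta) ** 2
                             + 2.0 * age * self.cov_ab))


@dataclass
class RateCoefficients:
    """All k(k-1) pairwise rate fits for one state scheme."""

    scheme_name: str
    k: int
    pairs: Dict[PairKey, PairRate] = field(default_factory=dict)

    def mu(self, i: int, j: int, ages: np.ndarray) -> np.ndarray:
        return self.pairs[(i, j)].mu(ages)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_name,
            "k": self.k,
            "pairs": [vars(p) for p in self.pairs.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateCoefficients":
        out = cls(d["scheme"], d["k"])
        for p in d["pairs"]:
            pr = PairRate(**p)
            out.pairs[(pr.origin, pr.dest)] = pr
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RateCoefficients":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_rates(observations: pd.DataFrame, scheme: StateScheme) -> RateCoefficients:
    """Fit one Poisson rate model per ordered pair of transient states.

    A pair with zero observed events is flagged degenerate and its rate is
    fixed at 0 (no information, no extrapolation); non-convergence is
    flagged on the pair rather than silently defaulted.
    """
    out = RateCoefficients(scheme.name, scheme.k)
    for i in scheme.states:
        for j in scheme.states:
            if i == j:
                continue
            sub = observations[(observations["origin"] == i) & (observations["dest"] == j)]
            n_events = int(sub["event"].sum())
            if n_events == 0:
                logger.warning("pair %d->%d has no events; rate fixed at 0", i, j)
                out.pairs[(i, j)] = PairRate(i, j, -np.inf, 0.0, np.nan, np.nan,
                                             len(sub), 0, True, True)
                continue
            X = sm.add_constant(sub["age"].to_numpy())
            model = sm.GLM(
                sub["event"].to_numpy(), X,
                family=sm.families.Poisson(),
                offset=np.log(sub["exposure"].to_numpy()),
            )
            try:
                res = model.fit(maxiter=100)
                converged = bool(res.converged)
            except Exception:  # pragma: no cover - pathological input
                logger.warning("pair %d->%d: Poisson fit failed", i, j)
                out.pairs[(i, j)] = PairRate(i, j, np.nan, np.nan, np.nan, np.nan,
                                             len(sub), n_events, False, False)
                continue
            if not converged:
                logger.warning("pair %d->%d: Poisson fit did not converge", i, j)
            out.pairs[(i, j)] = PairRate(
                i, j, float(res.params[0]), float(res.params[1]),
                float(res.bse[0]), float(res.bse[1]),
                len(sub), n_events, converged, False,
                cov_ab=float(np.asarray(res.cov_params())[0, 1]),
            )
    return out


def prob_from_rate(mu) -> np.ndarray | float:
    """Two-year transition probability ``1 - exp(-2 mu)`` for a rate/year."""
    arr = np.asarray(mu, dtype=float)
    if np.any(arr < 0):
        raise ValueError("rate must be non-negative")
    out = -np.expm1(-2.0 * arr)
    return float(out) if np.isscalar(mu) else out


@dataclass
class TransitionProbabilities:
    """Per-age transition and death probabilities on the life-table grid.

    ``ages[t]`` is the start of interval [age, age+2); ``p[t, i-1, j-1]`` the
    probability of moving from transient state i to j over the interval;
    ``q[t, i-1]`` the state-specific death probability (attached by
    :func:`attach_death_probs`).
    """

    ages: np.ndarray
    k: int
    p: np.ndarray  # (T, k, k), zero diagonal
    q: Optional[np.ndarray] = None  # (T, k)

    def stay(self) -> np.ndarray:
        if self.q is None:
            raise ValueError("death probabilities not attached")
        return 1.0 - self.p.sum(axis=2) - self.q


def probabilities_on_grid(
    coef: RateCoefficients, ages: np.ndarray, hold_after: float = 95.0
) -> TransitionProbabilities:
    """Evaluate fitted rates on a 2-year grid and convert to probabilities.

    Each interval [t, t+2) uses the rate at its midpoint t+1. Beyond
    ``hold_after`` the rates are held at their value for the interval
    starting there (the life-table closure convention).
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) > 1 and not np.allclose(np.diff(ages), 2.0):
        raise ValueError("age grid must be 2-year spaced")
    eval_ages = np.minimum(ages, hold_after) + 1.0
    k = coef.k
    p = np.zeros((len(ages), k, k))
    for (i, j), pr in coef.pairs.items():
        p[:, i - 1, j - 1] = prob_from_rate(pr.mu(eval_ages))
    return TransitionProbabilities(ages=ages, k=k, p=p)


def attach_death_probs(
    tp: TransitionProbabilities, q: np.ndarray
) -> TransitionProbabilities:
    """Attach anchored death probabilities, rescaling rows that overflow.

    Transition and death probabilities are estimated independently, so a
    row sum can exceed 1; the transition block (not the externally anchored
    death probability) is then scaled down proportionally so the row sums
    to 1 - 1e-12, with a warning.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (len(tp.ages), tp.k):
        raise ValueError("death-probability grid does not match")
    p = tp.p.copy()
    psum = p.sum(axis=2)
    over = psum + q > 1.0
    if over.any():
        t_idx, i_idx = np.where(over)
        for t, i in zip(t_idx, i_idx):
            scale = (1.0 - 1e-12 - q[t, i]) / psum[t, i]
            p[t, i, :] *= scale
        logger.warning(
            "rescaled transition probabilities in %d (age, state) cells "
            "where p + q exceeded 1", int(over.sum())
        )
    return TransitionProbabilities(ages=tp.ages, k=tp.k, p=p, q=q)
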