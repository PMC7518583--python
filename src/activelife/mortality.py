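"""State-specific mortality anchored to a reference life table.

Panel follow-up is too short to estimate absolute mortality reliably, and
survey samples can be healthier than the population. The analysis therefore
takes the *level* of mortality from an external total-population life table
(two-year death probabilities q_x) and estimates only the *relative*
mortality of the disability states: hazard ratios from a Cox proportional
hazards model on the age time scale with the disability state as a
time-varying covariate (a survivor's state switches from its baseline to
its follow-up value at the midpoint of the interval), optionally with an
age interaction so HR_j(age) = exp(gamma_j + delta_j (age - 65)).

The two are combined on the cumulative-hazard scale: at each grid age t a
baseline cumulative hazard H_t solves

    sum_j pi_j(t) * (1 - exp(-H_t * HR_j(t))) = q_t ,

where pi_j(t) is the prevalence of state j among the alive at age t, and
the state-specific death probability is q_t^j = 1 - exp(-H_t * HR_j(t)).
This keeps every q_t^j below 1 for any hazard ratio and reproduces the
life-table q_t exactly as the prevalence-weighted mean. The left side is
strictly increasing in H_t, so the root is found by bisection-safe Brent
iteration on (0, 20).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq

from .staging import StateScheme

logger = logging.getLogger(__name__)


@dataclass
class HazardRatioModel:
    """Cox hazard ratios per transient state (state 1 = reference, HR = 1)."""

    k: int
    gamma: np.ndarray  # log HR per state, gamma[0] = 0
    delta: np.ndarray  # age slope of log HR per state, delta[0] = 0
    se_gamma: np.ndarray
    se_delta: np.ndarray
    with_age_interaction: bool
    flags: Dict[str, object] = field(default_factory=dict)

    def hr(self, ages: np.ndarray) -> np.ndarray:
        """Hazard-ratio matrix, shape (len(ages), k)."""
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        return np.exp(self.gamma[None, :] + self.delta[None, :] * (ages[:, None] - 65.0))

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "se_gamma": self.se_gamma.tolist(),
            "se_delta": self.se_delta.tolist(),
            "with_age_interaction": self.with_age_interaction,
            "flags": self.flags,
        }


def _episodes(panel: pd.DataFrame, switch_at: str = "followup") -> pd.DataFrame:
    """Counting-process rows (start age, stop age, state, event) per person.

    Everyone enters at baseline age (left truncation on the age scale) in
    their baseline state; deaths end their episode at the death age. The
    disability covariate of a surviving respondent is updated with the
    follow-up value at ``switch_at``:

    * ``"followup"`` (default) — at the follow-up interview, i.e. the end
      of the risk window. All within-window risk is then classified by the
      state occupied at the start of the interval — the same semantics as
      the projection's state-specific death probability, and symmetric
      between decedents (whose state is never re-observed) and survivors.
    * ``"midpoint"`` — halfway through the interval. This updates only the
      *survivors'* labels mid-window; with strong net recovery it makes
      sicker labels spuriously predictive of death even when true hazards
      are identical across states, so it is kept only for comparison.
    """
    ok = panel["state_b"].notna()
    sub = panel.loc[ok]
    age0 = sub["age_base"].to_numpy(dtype=float)
    iv = sub["interval_years"].to_numpy(dtype=float)
    sb = sub["state_b"].to_numpy(dtype=float)
    dead = sub["dead"].to_numpy(dtype=int) == 1
    td = sub["time_to_death_years"].to_numpy(dtype=float)
    sf = sub["state_f"].to_numpy(dtype=float)
    switch = (~dead) & (sub["responded_followup"].to_numpy(dtype=int) == 1) & ~np.isnan(sf)
    if switch_at == "followup":
        switch = np.zeros(len(sub), dtype=bool)  # update coincides with exit
    elif switch_at != "midpoint":
        raise ValueError("switch_at must be 'followup' or 'midpoint'")

    rows = []
    # deaths: one episode, baseline state
    rows.append(pd.DataFrame({
        "start": age0[dead], "stop": age0[dead] + np.maximum(td[dead], 1e-6),
        "state": sb[dead], "event": 1,
    }))
    # survivors without a mid-window update: one censored episode
    plain = (~dead) & (~switch)
    rows.append(pd.DataFrame({
        "start": age0[plain], "stop": age0[plain] + iv[plain],
        "state": sb[plain], "event": 0,
    }))
    # survivors with a mid-window update: split episodes
    mid = age0[switch] + iv[switch] / 2.0
    rows.append(pd.DataFrame({
        "start": age0[switch], "stop": mid, "state": sb[switch], "event": 0,
    }))
    rows.append(pd.DataFrame({
        "start": mid, "stop": age0[switch] + iv[switch], "state": sf[switch], "event": 0,
    }))
    return pd.concat(rows, ignore_index=True)


def fit_hazard_ratios(
    panel: pd.DataFrame,
    scheme: StateScheme,
    with_age_interaction: Optional[bool] = None,
    switch_at: str = "followup",
) -> HazardRatioModel:
    """Cox PH fit of death on disability state, age as the time scale.

    ``panel`` must be staged (``state_b``/``state_f`` columns). The age
    interaction defaults to on for k <= 3 and off for the five-level scheme,
    where deaths per state are too sparse to support it; an inestimable
    interaction is dropped with a warning. A state with zero deaths is
    flagged and its log HR set to NaN (downstream anchoring will refuse it).
    """
    if with_age_interaction is None:
        with_age_interaction = scheme.k <= 3
    ep = _episodes(panel, switch_at)
    if len(ep) == 0:
        raise ValueError("no usable episodes (all baseline states missing?)")
    k = scheme.k
    flags: Dict[str, object] = {}

    if int(ep["event"].sum()) == 0:
        # no deaths anywhere: hazard ratios are unidentifiable; fall back to
        # HR = 1 for every state, loudly flagged
        logger.warning("panel contains no deaths; hazard ratios set to 1")
        z = np.zeros(k)
        return HazardRatioModel(k, z, z.copy(), z.copy(), z.copy(), False,
                                {"no_deaths": True})

    deaths_by_state = ep.loc[ep["event"] == 1].groupby("state").size()
    zero_death = [s for s in scheme.states if deaths_by_state.get(float(s), 0) == 0]
    if zero_death:
        flags["zero_death_states"] = zero_death
        logger.warning("states with zero deaths: %s", zero_death)

    cols = []
    names = []
    st = ep["state"].to_numpy()
    for s in range(2, k + 1):
        cols.append((st == s).astype(float))
        names.append(f"state_{s}")
    if with_age_interaction:
        rel_age = ep["start"].to_numpy() - 65.0
        for s in range(2, k + 1):
            cols.append((st == s).astype(float) * rel_age)
            names.append(f"state_{s}:age")
    X = np.column_stack(cols)

    def _fit(Xm, nm):
        model = sm.PHReg(
            ep["stop"].to_numpy(), Xm,
            status=ep["event"].to_numpy(),
            entry=ep["start"].to_numpy(),
        )
        return model.fit(), nm

    try:
        res, names_used = _fit(X, names)
        if not np.all(np.isfinite(res.bse)):
            raise np.linalg.LinAlgError("non-finite standard errors")
    except Exception as exc:
        if with_age_interaction:
            logger.warning("age interaction inestimable (%s); dropped", exc)
            flags["interaction_dropped"] = True
            with_age_interaction = False
            res, names_used = _fit(X[:, : k - 1], names[: k - 1])
        else:
            raise

    gamma = np.zeros(k)
    delta = np.zeros(k)
    se_g = np.zeros(k)
    se_d = np.zeros(k)
    for name, est, se in zip(names_used, res.params, res.bse):
        if name.endswith(":age"):
            s = int(name.split(":")[0].split("_")[1])
            delta[s - 1], se_d[s - 1] = est, se
        else:
            s = int(name.split("_")[1])
            gamma[s - 1], se_g[s - 1] = est, se
    for s in zero_death:
        gamma[s - 1] = np.nan
    if not np.all(np.isfinite(res.params)):
        flags["non_converged"] = True
        logger.warning("Cox fit produced non-finite coefficients")
    return HazardRatioModel(k, gamma, delta, se_g, se_d, with_age_interaction, flags)


def estimate_prevalence(
    panel: pd.DataFrame, scheme: StateScheme, ages: np.ndarray
) -> np.ndarray:
    """Smoothed state prevalence pi_j(x) at grid ages, rows summing to 1.

    Fits a multinomial-logistic model of baseline state on age and
    evaluates it at the grid; if that fit fails, falls back to raw 2-year
    age-bin proportions. Grid ages beyond the observed age range reuse the
    estimate at the nearest observed age (carry-forward).
    """
    ages = np.asarray(ages, dtype=float)
    ok = panel["state_b"].notna()
    st = panel.loc[ok, "state_b"].to_numpy(dtype=int)
    age = panel.loc[ok, "age_base"].to_numpy(dtype=float)
    if len(st) == 0:
        raise ValueError("no observed baseline states")
    k = scheme.k
    present = np.unique(st)
    eval_ages = np.clip(ages, age.min(), age.max())
    out = np.zeros((len(ages), k))
    if len(present) == 1:
        out[:, present[0] - 1] = 1.0
        return out
    # map states to consecutive codes for MNLogit
    code = {s: c for c, s in enumerate(present)}
    y = np.array([code[s] for s in st])
    X = sm.add_constant((age - 65.0) / 10.0)
    try:
        res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("MNLogit did not converge")
        Xg = sm.add_constant((eval_ages - 65.0) / 10.0)
        pred = res.predict(Xg)  # (T, len(present))
        for s, c in code.items():
            out[:, s - 1] = pred[:, c]
    except Exception as exc:
        logger.warning("multinomial smooth failed (%s); using raw age bins", exc)
        bins = np.arange(np.floor(age.min() / 2) * 2, age.max() + 2.0, 2.0)
        props = np.full((len(bins), k), np.nan)
        for b, lo in enumerate(bins):
            sel = (age >= lo) & (age < lo + 2.0)
            if sel.sum() > 0:
                for s in scheme.states:
                    props[b, s - 1] = np.mean(st[sel] == s)
        # forward-fill empty bins
        for b in range(1, len(bins)):
            if np.isnan(props[b]).any():
                props[b] = props[b - 1]
        idx = np.clip(np.searchsorted(bins, eval_ages, side="right") - 1, 0, len(bins) - 1)
        out = props[idx]
    out = out / out.sum(axis=1, keepdims=True)
    return out


def anchor_death_probs_cohort(
    lifetable: pd.DataFrame,
    hr_model: HazardRatioModel,
    pi0: np.ndarray,
    tp,
    ages: np.ndarray,
    h_max: float = 20.0,
) -> np.ndarray:
    """Anchor q_t^j at the projected cohort's own state mix, age by age.

    The population whose mortality the reference life table describes is
    the life-table cohort itself, so the anchoring weights at age t are
    the occupancy the projection reaches at t, starting from the observed
    baseline mix ``pi0`` at the first grid age and stepping forward with
    the fitted transition probabilities ``tp`` and the just-anchored death
    probabilities. By construction the projected total cohort then
    reproduces the life table's mortality at every anchored age.
    """
    ages = np.asarray(ages, dtype=float)
    lt = lifetable.set_index("age")["qx"]
    missing = [a for a in ages if a not in lt.index]
    if missing:
        raise ValueError(f"life table has no q_x for ages {missing}")
    hrs = hr_model.hr(ages)
    if not np.all(np.isfinite(hrs)):
        raise ValueError("hazard-ratio model has non-finite HRs (zero-death state?)")
    k = hr_model.k
    occ = np.asarray(pi0, dtype=float)
    occ = occ / occ.sum()
    out = np.zeros((len(ages), k))
    for t, age in enumerate(ages):
        qx = float(lt.loc[age])
        w = occ / occ.sum()
        hr_t = hrs[t]

        def f(H):
            return float(np.sum(w * -np.expm1(-H * hr_t)) - qx)

        if f(h_max) < 0:
            raise ValueError(
                f"no baseline cumulative hazard in (0, {h_max}) reproduces "
                f"q={qx:.4g} at age {age:.0f}"
            )
        H = brentq(f, 0.0, h_max, xtol=1e-12, rtol=1e-14)
        out[t] = -np.expm1(-H * hr_t)
        # step the cohort with the same overflow rule the projection uses
        p = tp.p[t].copy()
        psum = p.sum(axis=1)
        over = psum + out[t] > 1.0
        if over.any():
            scale = (1.0 - 1e-12 - out[t][over]) / psum[over]
            p[over] *= scale[:, None]
        occ = occ * (1.0 - p.sum(axis=1) - out[t]) + occ @ p
    return out


def anchor_death_probs(
    lifetable: pd.DataFrame,
    hr_model: HazardRatioModel,
    prevalence: np.ndarray,
    ages: np.ndarray,
    h_max: float = 20.0,
) -> np.ndarray:
    """Solve for state-specific death probabilities q_t^j at each grid age.

    For each age t, find the baseline cumulative hazard H with
    ``sum_j pi_j (1 - exp(-H * HR_j)) = q_t`` (Brent root on (0, h_max),
    tolerance 1e-12), then ``q_t^j = 1 - exp(-H * HR_j)``. Errors out,
    naming the age, when no root exists — a sign of inconsistent inputs.
    """
    ages = np.asarray(ages, dtype=float)
    lt = lifetable.set_index("age")["qx"]
    missing = [a for a in ages if a not in lt.index]
    if missing:
        raise ValueError(f"life table has no q_x for ages {missing}")
    qx = lt.loc[ages].to_numpy(dtype=float)
    hrs = hr_model.hr(ages)  # (T, k)
    if not np.all(np.isfinite(hrs)):
        raise ValueError("hazard-ratio model has non-finite HRs (zero-death state?)")
    prevalence = np.asarray(prevalence, dtype=float)
    if prevalence.shape != (len(ages), hr_model.k):
        raise ValueError("prevalence grid does not match ages/states")

    out = np.zeros((len(ages), hr_model.k))
    for t, (q, hr_t, pi) in enumerate(zip(qx, hrs, prevalence)):
        def f(H):
            return float(np.sum(pi * -np.expm1(-H * hr_t)) - q)
        if f(h_max) < 0:
            raise ValueError(
                f"no baseline cumulative hazard in (0, {h_max}) reproduces "
                f"q={q:.4g} at age {ages[t]:.0f}"
            )
        H = brentq(f, 0.0, h_max, xtol=1e-12, rtol=1e-14)
        out[t] = -np.expm1(-H * hr_t)
    return out
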