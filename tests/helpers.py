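"""Shared independent oracles for the test suite."""

import numpy as np


def discrete_microsim(tp, grid, start_state, n, seed):
    """Monte-Carlo years-per-state under fixed two-year probabilities.

    Simulates n discrete trajectories through the (k+1)-state chain defined
    by ``tp`` (one multinomial draw per two-year interval), crediting two
    years for a kept state and one year to each side of a transition or
    death interval. Returns (mean_years, mc_se) per transient state —
    an independent check of the deterministic trapezoidal projection.
    """
    k = tp.k
    rng = np.random.default_rng(seed)
    state = np.full(n, start_state, dtype=int)
    years = np.zeros((n, k))
    ages = np.arange(65.0, grid.closure, 2.0)
    last = len(tp.ages) - 1
    for age in ages:
        if not (state > 0).any():
            break
        start = state.copy()
        idx = min(np.searchsorted(tp.ages, age), last)
        for s in range(1, k + 1):
            rows = np.where(start == s)[0]
            if len(rows) == 0:
                continue
            move = tp.p[idx, s - 1]
            q = tp.q[idx, s - 1]
            probs = np.concatenate([[1.0 - move.sum() - q], move, [q]])
            dest = rng.choice(k + 2, size=len(rows), p=probs)
            years[rows, s - 1] += np.where(dest == 0, 2.0, 1.0)
            for d in range(1, k + 1):
                if d != s:
                    moved = rows[dest == d]
                    years[moved, d - 1] += 1.0
                    state[moved] = d
            state[rows[dest == k + 1]] = 0
    return years.mean(axis=0), years.std(axis=0) / np.sqrt(n)


def matrix_power_occupancies(p, q, init, n_steps):
    """Occupancy path from explicit powers of the (k+1)-state matrix."""
    k = len(q)
    M = np.zeros((k + 1, k + 1))
    M[:k, :k] = p
    M[np.arange(k), np.arange(k)] = 1.0 - p.sum(axis=1) - q
    M[:k, k] = q
    M[k, k] = 1.0
    v = np.append(np.asarray(init, dtype=float), 0.0)
    return np.array([(v @ np.linalg.matrix_power(M, t))[:k] for t in range(n_steps)])
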