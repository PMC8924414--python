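"""Shared fixtures and the independent brute-force engine oracle."""

import itertools

import numpy as np
import pytest

from markovce import ModelConfig, TransitionMatrix, load_subgroup_params


def brute_force_econ(matrix: TransitionMatrix, pfs_cost: float, pd_cost: float,
                     u_pfs: float, u_pd: float, config: ModelConfig):
    """Expected discounted (cost, qaly) by enumerating every state path.

    Written independently of the engine: walks all |S|^T paths of the chain
    from PFS, weights each by its product of transition probabilities, and
    accrues per-cycle rewards (trapezoid half-cycle correction when the
    config asks for it) along each path. Exponential in the horizon — use
    only for tiny T.
    """
    M = matrix.as_array()
    T = config.horizon
    rm = config.monthly_discount_rate
    state_cost = (pfs_cost, pd_cost, 0.0)
    state_util = (u_pfs / 12.0, u_pd / 12.0, 0.0)
    total_cost = total_qaly = 0.0
    for path in itertools.product(range(3), repeat=T):
        full = (0,) + path
        prob = 1.0
        for s, s2 in zip(full[:-1], full[1:]):
            prob *= M[s, s2]
        if prob == 0.0:
            continue
        for t in range(T):
            if config.half_cycle_correction:
                c = (state_cost[full[t]] + state_cost[full[t + 1]]) / 2.0
                q = (state_util[full[t]] + state_util[full[t + 1]]) / 2.0
            else:
                c, q = state_cost[full[t]], state_util[full[t]]
            d = (1.0 + rm) ** (-t)
            total_cost += prob * c * d
            total_qaly += prob * q * d
    return total_cost, total_qaly


def km_by_hand(event_times, censor_flags):
    """Product-limit estimator computed directly from its definition:
    S(t) = prod over event times t_i <= t of (1 - d_i / n_i)."""
    event_times = np.asarray(event_times)
    censored = np.asarray(censor_flags, dtype=bool)
    grid = np.arange(int(event_times.max()) + 1)
    surv = np.ones_like(grid, dtype=float)
    s = 1.0
    for t in grid[1:]:
        at_risk = np.sum(event_times >= t)
        deaths = np.sum((event_times == t) & ~censored)
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        surv[t] = s
    return grid, surv


def random_matrix(rng, low=0.0, high=1.0) -> TransitionMatrix:
    """A random valid transition matrix with stay probabilities in
    [low, high] and a uniform exit split."""
    a = rng.uniform(low, high)
    b = rng.uniform(low, high)
    w = rng.uniform(0.0, 1.0)
    return TransitionMatrix(p_pfs_pfs=a, p_pfs_pd=(1 - a) * w,
                            p_pfs_death=(1 - a) * (1 - w),
                            p_pd_pd=b, p_pd_death=1 - b)


@pytest.fixture(scope="session")
def cps10_pembro():
    return load_subgroup_params("cps10", "pembrolizumab")


@pytest.fixture(scope="session")
def total_pembro():
    return load_subgroup_params("total", "pembrolizumab")
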