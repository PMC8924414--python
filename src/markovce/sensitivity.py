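"""One-way and probabilistic sensitivity analysis.

One-way analysis (OWSA) reruns both arms with each registered parameter at
baseline x (1 - f) and x (1 + f), f = 0.20 by default, and ranks
parameters by the spread of the resulting ICERs (tornado order).

Probabilistic analysis (PSA) draws cost parameters from Gamma and
utilities from Beta distributions, both matched by method of moments to
mean = baseline and SD = ``se_fraction`` x baseline, reruns both arms per
draw, and summarises the draws as a cost-effectiveness acceptability
curve (CEAC): the fraction of draws in which each strategy has the higher
net monetary benefit, NMB = lambda x QALYs - cost, as a function of the
willingness-to-pay lambda. Transition probabilities are held fixed.

Randomness: one root seed; each parameter gets its own child stream keyed
by a stable hash of its name, so adding a parameter leaves the other
parameters' draws unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (OVERRIDE_PARAMETERS, CEResults, CostEffectivenessModel,
                    build_trace, discounted_person_months)
from .params import ValidationError

__all__ = [
    "OWSAResult", "PSAResult", "CEACCurve", "run_owsa", "run_psa", "ceac",
    "parameter_base_value", "DEFAULT_WTP_GRID",
]

#: Default willingness-to-pay grid: 0..250,000 USD/QALY in 2,500 steps,
#: always including the 1x-GDP-per-capita threshold 11,105.8.
DEFAULT_WTP_GRID = np.unique(np.append(np.arange(0.0, 250_000.0 + 1, 2_500.0), 11_105.8))

#: Parameters varied in the PSA: costs (Gamma) and utilities (Beta) only.
PSA_COST_PARAMETERS = tuple(
    n for n in OVERRIDE_PARAMETERS
    if n.startswith(("drug_cost_", "test_cost_", "ae_cost_")) or n == "subsequent_therapy_cost")
PSA_UTILITY_PARAMETERS = ("u_pfs", "u_pd")


def parameter_base_value(model: CostEffectivenessModel, name: str) -> float:
    """Baseline value of a registered sensitivity parameter."""
    if name not in OVERRIDE_PARAMETERS:
        raise ValidationError(
            f"unknown parameter {name!r}; valid names: {', '.join(sorted(OVERRIDE_PARAMETERS))}")
    for arm in (model.intervention, model.comparator):
        if name == f"drug_cost_{arm.name}":
            return arm.costs.drug_cost_per_month
        if name == f"test_cost_{arm.name}":
            return arm.costs.test_cost_per_month
        if name == f"ae_cost_{arm.name}":
            return arm.costs.ae_cost_per_month
    if name == "subsequent_therapy_cost":
        return model.intervention.costs.subsequent_therapy_cost_per_month
    if name == "u_pfs":
        return model.utilities.u_pfs
    if name == "u_pd":
        return model.utilities.u_pd
    if name == "discount_rate":
        return model.config.annual_discount_rate
    raise ValidationError(f"parameter {name!r} is not registered for this model")


@dataclass(frozen=True)
class OWSAResult:
    """Tornado-ordered one-way sensitivity table."""

    table: pd.DataFrame          # parameter, low/high values, ICERs, spread
    base_icer: float
    range_fraction: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_owsa(subgroup: str | None = None, parameters=None,
             range_fraction: float = 0.20,
             model: CostEffectivenessModel | None = None) -> OWSAResult:
    """One-way sensitivity analysis over the registered parameters.

    Each parameter is set to baseline x (1 +/- range_fraction) with all
    others at baseline; both arms are rerun and the two ICERs recorded.
    Rows are sorted by ICER spread, descending; ties (and degenerate
    zero-spread rows) keep registration order and rank last.
    """
    if model is None:
        model = CostEffectivenessModel.from_subgroup(subgroup)
    if parameters is None:
        parameters = list(OVERRIDE_PARAMETERS)
    base = model.fit()
    rows = []
    for order, name in enumerate(parameters):
        base_value = parameter_base_value(model, name)
        icers = []
        for k in (1.0 - range_fraction, 1.0 + range_fraction):
            cmp_ = model.with_overrides({name: k}).fit().comparison
            icers.append(np.nan if cmp_.icer is None else cmp_.icer)
        spread = abs(icers[1] - icers[0])
        rows.append({"parameter": name,
                     "low_value": base_value * (1.0 - range_fraction),
                     "high_value": base_value * (1.0 + range_fraction),
                     "icer_at_low": icers[0], "icer_at_high": icers[1],
                     "spread": spread, "_order": order})
    table = (pd.DataFrame(rows)
             .sort_values(["spread", "_order"], ascending=[False, True],
                          kind="mergesort", na_position="last")
             .drop(columns="_order").reset_index(drop=True))
    return OWSAResult(table=table, base_icer=base.icer, range_fraction=range_fraction)


# ---------------------------------------------------------------------------
# PSA


def _child_rng(root_seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(root_seed), key]))


def _gamma_draws(base: float, se_fraction: float, n: int, rng) -> np.ndarray:
    """Gamma with mean = base, SD = se_fraction * base (method of moments:
    shape = 1/se^2, scale = base * se^2)."""
    if se_fraction == 0 or base == 0:
        return np.full(n, base)
    shape = 1.0 / se_fraction ** 2
    scale = base * se_fraction ** 2
    return rng.gamma(shape, scale, size=n)


def _beta_draws(base: float, se_fraction: float, n: int, rng, name: str) -> np.ndarray:
    """Beta with mean = base, SD = se_fraction * base (method of moments)."""
    if se_fraction == 0:
        return np.full(n, base)
    var = (se_fraction * base) ** 2
    if var >= base * (1.0 - base):
        raise ValidationError(
            f"se_fraction {se_fraction} gives invalid Beta moments for {name!r}: "
            f"variance {var:.4g} >= mean*(1-mean) {base * (1 - base):.4g}")
    nu = base * (1.0 - base) / var - 1.0
    return rng.beta(base * nu, (1.0 - base) * nu, size=n)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo parameter draws with per-draw arm outcomes.

    ``samples`` has one row per draw: the sampled parameter values, each
    arm's discounted cost and QALYs, and the incrementals.
    """

    samples: pd.DataFrame
    seed: int
    se_fraction: float
    base: CEResults

    @property
    def n_draws(self) -> int:
        return len(self.samples)

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def run_psa(subgroup: str | None = None, n_draws: int = 10_000,
            seed: int | None = None, se_fraction: float = 0.20,
            model: CostEffectivenessModel | None = None) -> PSAResult:
    """Probabilistic sensitivity analysis by Monte Carlo.

    Cost parameters are drawn from Gamma and utilities from Beta
    distributions (moments above); transition probabilities stay fixed.
    Both arms are re-evaluated per draw. Fully reproducible given ``seed``.
    """
    if seed is None:
        raise ValidationError("PSA requires an explicit seed")
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    if model is None:
        model = CostEffectivenessModel.from_subgroup(subgroup)
    base = model.fit()

    draws: dict[str, np.ndarray] = {}
    for name in PSA_COST_PARAMETERS:
        draws[name] = _gamma_draws(parameter_base_value(model, name), se_fraction,
                                   n_draws, _child_rng(seed, name))
    for name in PSA_UTILITY_PARAMETERS:
        draws[name] = _beta_draws(parameter_base_value(model, name), se_fraction,
                                  n_draws, _child_rng(seed, name), name)

    # Matrices are fixed across draws, so each arm's discounted corrected
    # person-months are constants and outcomes are linear in the draws.
    out = {"draw": np.arange(n_draws)}
    out.update(draws)
    arm_cost = {}
    arm_qaly = {}
    for arm in (model.intervention, model.comparator):
        pm_pfs, pm_pd = discounted_person_months(
            build_trace(arm.matrix, model.config), model.config)
        pfs_cost = (draws[f"drug_cost_{arm.name}"] + draws[f"test_cost_{arm.name}"]
                    + draws[f"ae_cost_{arm.name}"])
        pd_cost = draws["subsequent_therapy_cost"]
        arm_cost[arm.name] = pm_pfs * pfs_cost + pm_pd * pd_cost
        arm_qaly[arm.name] = (pm_pfs * draws["u_pfs"] + pm_pd * draws["u_pd"]) / 12.0
        out[f"cost_{arm.name}"] = arm_cost[arm.name]
        out[f"qaly_{arm.name}"] = arm_qaly[arm.name]
    i, c = model.intervention.name, model.comparator.name
    out["delta_cost"] = arm_cost[i] - arm_cost[c]
    out["delta_qaly"] = arm_qaly[i] - arm_qaly[c]
    return PSAResult(samples=pd.DataFrame(out), seed=seed,
                     se_fraction=se_fraction, base=base)


@dataclass(frozen=True)
class CEACCurve:
    """Cost-effectiveness acceptability curve for the two strategies.

    At every willingness-to-pay value the two probabilities sum to 1; the
    intervention wins a draw iff its incremental net monetary benefit is
    strictly positive (ties count for the comparator).
    """

    frame: pd.DataFrame  # wtp, p_intervention, p_comparator

    def probability_at(self, wtp: float) -> float:
        idx = (self.frame["wtp"] - wtp).abs().idxmin()
        return float(self.frame.loc[idx, "p_intervention"])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def ceac(samples: PSAResult | pd.DataFrame, wtp_grid=None) -> CEACCurve:
    """Acceptability curve from PSA draws.

    ``P(intervention | lambda)`` is the fraction of draws with
    ``lambda * delta_qaly - delta_cost > 0``.
    """
    df = samples.samples if isinstance(samples, PSAResult) else samples
    if len(df) == 0:
        raise ValidationError("PSA sample set must be non-empty")
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) < 0):
        raise ValidationError("wtp_grid must be a non-empty ascending 1-d array")
    dq = df["delta_qaly"].to_numpy()
    dc = df["delta_cost"].to_numpy()
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    p_int = (nmb > 0).mean(axis=1)
    return CEACCurve(pd.DataFrame({"wtp": grid, "p_intervention": p_int,
                                   "p_comparator": 1.0 - p_int}))
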