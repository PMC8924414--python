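"""Cohort simulation engine and the cost-effectiveness model/results API.

A closed cohort starts in PFS and is pushed through the monthly transition
matrix for a fixed horizon (no background mortality, time-homogeneous
probabilities). Discounted costs and QALYs are accumulated over the trace
with an optional trapezoid half-cycle correction, and two arms are
compared by their incremental cost-effectiveness ratio (ICER),

    ICER = (C_intervention - C_comparator) / (Q_intervention - Q_comparator),

computed from full-precision totals. ``CostEffectivenessModel`` bundles the
two arms; ``fit()`` returns a :class:`CEResults` carrying the per-arm
decompositions, the comparison and a report-style ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import (ARMS, STATES, CostInputs, ModelConfig, TransitionMatrix,
                     UtilitySet, ValidationError, load_subgroup_params)

__all__ = [
    "CohortTrace", "EconResult", "CEResult", "CostEffectivenessModel",
    "CEResults", "build_trace", "discount_factor", "accumulate",
    "discounted_person_months",
    "compute_icer", "run_scenario", "OVERRIDE_PARAMETERS", "round2",
]

_ATOL = 1e-9


def round2(x: float) -> float:
    """Round half-up to 2 decimals; used only at the reporting boundary."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions over cycles 0..T, columns (PFS, PD, DEATH)."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != 3 or occ.shape[0] < 2:
            raise ValidationError(f"occupancy must be (T+1, 3), got {occ.shape}")
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("every occupancy row must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ValidationError("death occupancy must be non-decreasing")
        object.__setattr__(self, "occupancy", occ)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, columns=list(STATES)).rename_axis("cycle")


@dataclass(frozen=True)
class EconResult:
    """Discounted per-state and total costs (USD) and QALYs for one arm."""

    cost_pfs: float
    cost_pd: float
    qaly_pfs: float
    qaly_pd: float

    @property
    def cost_total(self) -> float:
        return self.cost_pfs + self.cost_pd

    @property
    def qaly_total(self) -> float:
        return self.qaly_pfs + self.qaly_pd


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of an intervention against a comparator.

    ``icer`` is delta_cost/delta_qaly when both deltas are positive
    (more costly, more effective) or both negative (the ratio is then a
    decrement trade-off); it is None when a dominance flag applies or the
    QALY difference is numerically zero.
    """

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str  # none | intervention_dominates | intervention_dominated | undefined


def discount_factor(cycle: int, config: ModelConfig) -> float:
    """Discount factor (1 + r_m)^(-cycle) at the start of a cycle."""
    if cycle < 0:
        raise ValidationError(f"cycle must be >= 0, got {cycle}")
    return float((1.0 + config.monthly_discount_rate) ** (-cycle))


def build_trace(matrix: TransitionMatrix, config: ModelConfig) -> CohortTrace:
    """Push a cohort that starts fully in PFS through the monthly chain.

    ``occupancy[t+1] = occupancy[t] @ M`` for t = 0..horizon-1.
    """
    M = matrix.as_array()
    T = config.horizon
    occ = np.zeros((T + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for t in range(T):
        occ[t + 1] = occ[t] @ M
    return CohortTrace(occ)


def discounted_person_months(trace: CohortTrace, config: ModelConfig) -> tuple[float, float]:
    """Discounted (and, when configured, half-cycle-corrected) person-months
    spent in (PFS, PD) over cycles 0..T-1. Totals are linear in the
    per-cycle rewards, so these two numbers fully determine an arm's
    discounted costs and QALYs."""
    if trace.horizon != config.horizon:
        raise ValidationError(
            f"trace horizon {trace.horizon} != config horizon {config.horizon}")
    occ = trace.occupancy
    T = config.horizon
    if config.half_cycle_correction:
        living = (occ[:-1, :2] + occ[1:, :2]) / 2.0
    else:
        living = occ[:-1, :2]
    disc = (1.0 + config.monthly_discount_rate) ** (-np.arange(T))
    pm = (living * disc[:, None]).sum(axis=0)
    return float(pm[0]), float(pm[1])


def accumulate(trace: CohortTrace, costs: CostInputs, utilities: UtilitySet,
               config: ModelConfig) -> EconResult:
    """Discounted costs and QALYs accumulated over a cohort trace.

    Cycle t (t = 0..T-1) accrues per-cycle state rewards — monthly cost,
    and annual utility / 12 — over the corrected occupancy
    ``(occ[t] + occ[t+1]) / 2`` (trapezoid half-cycle correction; plain
    start-of-cycle occupancy when the correction is off), discounted at the
    cycle start.
    """
    pm_pfs, pm_pd = discounted_person_months(trace, config)
    return EconResult(cost_pfs=pm_pfs * costs.pfs_cost_per_cycle,
                      cost_pd=pm_pd * costs.pd_cost_per_cycle,
                      qaly_pfs=pm_pfs * utilities.u_pfs / 12.0,
                      qaly_pd=pm_pd * utilities.u_pd / 12.0)


def compute_icer(intervention: EconResult, comparator: EconResult) -> CEResult:
    """Incremental cost, incremental QALYs and ICER (or a dominance flag).

    Deltas are taken from full-precision totals, never from rounded
    reports. Dominance: cheaper-and-more-effective interventions dominate
    (no ratio reported); costlier-and-less-effective are dominated.
    """
    dc = intervention.cost_total - comparator.cost_total
    dq = intervention.qaly_total - comparator.qaly_total
    if abs(dq) < 1e-12:
        if abs(dc) < 1e-12:
            return CEResult(dc, dq, None, "none")
        return CEResult(dc, dq, None, "undefined")
    if dc <= 0 and dq > 0:
        return CEResult(dc, dq, None, "intervention_dominates")
    if dc >= 0 and dq < 0:
        return CEResult(dc, dq, None, "intervention_dominated")
    return CEResult(dc, dq, dc / dq, "none")


# ---------------------------------------------------------------------------
# Named multiplicative overrides (scenario analysis / one-way sensitivity)

@dataclass(frozen=True)
class _OverrideSpec:
    kind: str                 # "cost" | "utility" | "discount"
    field: str | None = None  # dataclass field to scale
    arm: str | None = None    # cost overrides: which arm (None = both)


#: Registered override/sensitivity parameter names. Arm-specific cost
#: parameters carry the arm name; utilities and the discount rate are shared
#: across arms and applied once.
OVERRIDE_PARAMETERS: dict[str, _OverrideSpec] = {}
for _arm in ARMS:
    OVERRIDE_PARAMETERS[f"drug_cost_{_arm}"] = _OverrideSpec("cost", "drug_cost_per_month", _arm)
    OVERRIDE_PARAMETERS[f"test_cost_{_arm}"] = _OverrideSpec("cost", "test_cost_per_month", _arm)
    OVERRIDE_PARAMETERS[f"ae_cost_{_arm}"] = _OverrideSpec("cost", "ae_cost_per_month", _arm)
OVERRIDE_PARAMETERS["subsequent_therapy_cost"] = _OverrideSpec("cost", "subsequent_therapy_cost_per_month", None)
OVERRIDE_PARAMETERS["u_pfs"] = _OverrideSpec("utility", "u_pfs")
OVERRIDE_PARAMETERS["u_pd"] = _OverrideSpec("utility", "u_pd")
OVERRIDE_PARAMETERS["discount_rate"] = _OverrideSpec("discount")


@dataclass(frozen=True)
class _Arm:
    name: str
    matrix: TransitionMatrix
    costs: CostInputs


class CostEffectivenessModel:
    """Two-arm Markov cohort cost-effectiveness model.

    Parameters
    ----------
    intervention, comparator
        ``(name, TransitionMatrix, CostInputs)`` triples, or `_Arm`s.
    utilities, config
        Shared health-state utilities and run configuration.

    Use :meth:`from_subgroup` for the packaged trial parameter sets.
    ``fit()`` runs both cohort traces, accumulates discounted costs and
    QALYs and returns a :class:`CEResults`.
    """

    def __init__(self, intervention, comparator, utilities: UtilitySet,
                 config: ModelConfig):
        self.intervention = intervention if isinstance(intervention, _Arm) else _Arm(*intervention)
        self.comparator = comparator if isinstance(comparator, _Arm) else _Arm(*comparator)
        self.utilities = utilities
        self.config = config

    @classmethod
    def from_subgroup(cls, subgroup: str) -> "CostEffectivenessModel":
        """Model for one packaged subgroup: pembrolizumab vs chemotherapy."""
        mat_i, cost_i, util, config = load_subgroup_params(subgroup, "pembrolizumab")
        mat_c, cost_c, _, _ = load_subgroup_params(subgroup, "chemotherapy")
        model = cls(_Arm("pembrolizumab", mat_i, cost_i),
                    _Arm("chemotherapy", mat_c, cost_c), util, config)
        model.subgroup = subgroup
        return model

    def with_overrides(self, overrides: Mapping[str, float]) -> "CostEffectivenessModel":
        """New model with named parameters scaled by multiplicative factors.

        Valid names are listed in :data:`OVERRIDE_PARAMETERS`; unknown names
        raise :class:`ValidationError`.
        """
        unknown = [k for k in overrides if k not in OVERRIDE_PARAMETERS]
        if unknown:
            raise ValidationError(
                f"unknown override parameter(s) {unknown}; valid names: "
                f"{', '.join(sorted(OVERRIDE_PARAMETERS))}")
        utilities, config = self.utilities, self.config
        for name, k in overrides.items():
            spec = OVERRIDE_PARAMETERS[name]
            if spec.kind == "utility":
                utilities = replace(utilities, **{spec.field: getattr(utilities, spec.field) * k})
            elif spec.kind == "discount":
                config = replace(config, annual_discount_rate=config.annual_discount_rate * k)
        arms = []
        for arm in (self.intervention, self.comparator):
            costs = arm.costs
            for name, k in overrides.items():
                spec = OVERRIDE_PARAMETERS[name]
                if spec.kind == "cost" and spec.arm in (None, arm.name):
                    costs = replace(costs, **{spec.field: getattr(costs, spec.field) * k})
            arms.append(_Arm(arm.name, arm.matrix, costs))
        model = CostEffectivenessModel(arms[0], arms[1], utilities, config)
        model.subgroup = getattr(self, "subgroup", None)
        return model

    def fit(self) -> "CEResults":
        trace_i = build_trace(self.intervention.matrix, self.config)
        trace_c = build_trace(self.comparator.matrix, self.config)
        econ_i = accumulate(trace_i, self.intervention.costs, self.utilities, self.config)
        econ_c = accumulate(trace_c, self.comparator.costs, self.utilities, self.config)
        return CEResults(self, (trace_i, trace_c), (econ_i, econ_c),
                         compute_icer(econ_i, econ_c))


class CEResults:
    """Fitted results: per-arm traces and economics, plus the comparison."""

    def __init__(self, model: CostEffectivenessModel,
                 traces: Sequence[CohortTrace], econ: Sequence[EconResult],
                 comparison: CEResult):
        self.model = model
        self.trace_intervention, self.trace_comparator = traces
        self.econ_intervention, self.econ_comparator = econ
        self.comparison = comparison

    @property
    def icer(self) -> float | None:
        return self.comparison.icer

    def table(self) -> pd.DataFrame:
        """Report table: per-state cost/QALY decomposition and increments.

        Full precision; use :meth:`summary` for the rounded report view.
        """
        i, c = self.econ_intervention, self.econ_comparator
        cmp_ = self.comparison
        rows = {
            "cost_pfs": (i.cost_pfs, c.cost_pfs),
            "cost_pd": (i.cost_pd, c.cost_pd),
            "cost_total": (i.cost_total, c.cost_total),
            "qaly_pfs": (i.qaly_pfs, c.qaly_pfs),
            "qaly_pd": (i.qaly_pd, c.qaly_pd),
            "qaly_total": (i.qaly_total, c.qaly_total),
            "incremental_cost": (cmp_.delta_cost, np.nan),
            "incremental_qaly": (cmp_.delta_qaly, np.nan),
            "icer": (cmp_.icer if cmp_.icer is not None else np.nan, np.nan),
        }
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[self.model.intervention.name, self.model.comparator.name])

    def summary(self) -> str:
        """Plain-text summary with amounts rounded half-up to 2 decimals."""
        t = self.table().map(lambda v: "" if pd.isna(v) else f"{round2(v):,.2f}")
        head = (f"Markov cohort cost-effectiveness results"
                f"{' — ' + self.model.subgroup if getattr(self.model, 'subgroup', None) else ''}\n"
                f"horizon: {self.model.config.horizon} cycles of "
                f"{self.model.config.cycle_length_months:g} month(s); "
                f"annual discount {self.model.config.annual_discount_rate:.1%} "
                f"({self.model.config.discount_compounding}); "
                f"half-cycle correction "
                f"{'on' if self.model.config.half_cycle_correction else 'off'}\n")
        dom = self.comparison.dominance
        tail = "" if dom == "none" else f"\ndominance: {dom}\n"
        return head + t.to_string() + tail

    def trace_frame(self) -> pd.DataFrame:
        """Cycle-indexed occupancy for both arms (CSV-ready)."""
        fi = self.trace_intervention.to_dataframe().add_prefix(
            self.model.intervention.name + "_")
        fc = self.trace_comparator.to_dataframe().add_prefix(
            self.model.comparator.name + "_")
        return fi.join(fc)


def run_scenario(subgroup: str, overrides: Mapping[str, float] | None = None,
                 arm_configs=None) -> CEResult:
    """Re-run a packaged subgroup comparison under multiplicative overrides.

    ``overrides`` maps registered parameter names (see
    :data:`OVERRIDE_PARAMETERS`) to multipliers, e.g. the donation scheme
    that halves the pembrolizumab acquisition cost is
    ``{"drug_cost_pembrolizumab": 0.5}``. ``arm_configs`` may supply a
    pre-built :class:`CostEffectivenessModel` instead of the packaged one.
    """
    model = arm_configs if arm_configs is not None else CostEffectivenessModel.from_subgroup(subgroup)
    if overrides:
        model = model.with_overrides(overrides)
    return model.fit().comparison
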