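"""Pseudo-individual patient data from the three-state progression process.

No patient-level data are deposited for the trial, so the generator walks
patients through the same monthly PFS -> PD -> death chain the cohort
model assumes and records progression and death times on the integer-month
grid (the chain's native resolution; no continuous-time interpolation).
Kaplan-Meier estimates of the resulting OS/PFS endpoints feed the
calibrator, closing an end-to-end simulate -> estimate -> recover loop.

Optional administrative censoring cuts every still-at-risk patient at a
single month; no dropout, treatment switching or assessment-interval
structure is emulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .calibration import SurvivalCurve
from .params import TransitionMatrix, ValidationError

__all__ = ["PseudoPatient", "simulate_cohort", "km_estimate", "cohort_to_frame"]


@dataclass(frozen=True)
class PseudoPatient:
    """One simulated patient.

    ``pfs_time`` is the month of first exit from PFS (progression or
    death, whichever comes first) or the censoring month; ``os_time`` is
    the month of death or censoring. ``pfs_time <= os_time`` always.
    """

    pfs_time: int
    os_time: int
    progressed: bool
    censored_pfs: bool
    censored_os: bool

    def __post_init__(self) -> None:
        if self.pfs_time > self.os_time:
            raise ValidationError("pfs_time must be <= os_time")


def simulate_cohort(matrix: TransitionMatrix, n_patients: int, max_months: int = 60,
                    censor_month: int | None = None, seed: int | None = None,
                    ) -> list[PseudoPatient]:
    """Walk ``n_patients`` through the monthly chain from PFS.

    Each patient starts in PFS and transitions each month per ``matrix``
    until death or ``max_months``; survivors are administratively censored
    at ``max_months`` (or at ``censor_month`` if given and earlier).
    Reproducible given ``seed``.
    """
    if n_patients < 1:
        raise ValidationError(f"n_patients must be >= 1, got {n_patients}")
    if max_months < 1:
        raise ValidationError(f"max_months must be >= 1, got {max_months}")
    cut = max_months if censor_month is None else min(censor_month, max_months)
    if cut < 1:
        raise ValidationError("censor_month must be >= 1")
    rng = np.random.default_rng(seed)

    state = np.zeros(n_patients, dtype=np.int8)          # 0 PFS, 1 PD, 2 dead
    pfs_time = np.full(n_patients, cut, dtype=np.int64)  # default: censored in PFS
    os_time = np.full(n_patients, cut, dtype=np.int64)
    progressed = np.zeros(n_patients, dtype=bool)
    exit_pfs = (matrix.p_pfs_pd, matrix.p_pfs_pd + matrix.p_pfs_death)
    for month in range(1, cut + 1):
        u = rng.random(n_patients)
        in_pfs = state == 0
        in_pd = state == 1
        to_pd = in_pfs & (u < exit_pfs[0])
        to_death_from_pfs = in_pfs & (u >= exit_pfs[0]) & (u < exit_pfs[1])
        to_death_from_pd = in_pd & (u < matrix.p_pd_death)
        left_pfs = to_pd | to_death_from_pfs
        pfs_time[left_pfs] = month
        progressed[to_pd] = True
        died = to_death_from_pfs | to_death_from_pd
        os_time[died] = month
        state[to_pd] = 1
        state[died] = 2
    alive = state != 2
    in_pfs_at_cut = state == 0
    return [PseudoPatient(pfs_time=int(pt), os_time=int(ot), progressed=bool(pr),
                          censored_pfs=bool(cp), censored_os=bool(co))
            for pt, ot, pr, cp, co in zip(pfs_time, os_time, progressed,
                                          in_pfs_at_cut, alive)]


def cohort_to_frame(cohort: list[PseudoPatient]) -> pd.DataFrame:
    """One row per patient (CSV-ready)."""
    return pd.DataFrame([p.__dict__ for p in cohort])


def km_estimate(cohort: list[PseudoPatient], endpoint: str) -> SurvivalCurve:
    """Product-limit (Kaplan-Meier) estimate on the integer-month grid.

    ``endpoint`` is ``"OS"`` (event = death) or ``"PFS"`` (event =
    progression or death, whichever first); censored observations
    contribute risk-time only.
    """
    if not cohort:
        raise ValidationError("cohort must be non-empty")
    if endpoint not in ("OS", "PFS"):
        raise ValidationError(f"endpoint must be 'OS' or 'PFS', got {endpoint!r}")
    if endpoint == "OS":
        durations = np.array([p.os_time for p in cohort])
        observed = np.array([not p.censored_os for p in cohort])
    else:
        durations = np.array([p.pfs_time for p in cohort])
        observed = np.array([not p.censored_pfs for p in cohort])
    timeline = np.arange(int(durations.max()) + 1)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed, timeline=timeline)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    return SurvivalCurve(endpoint, timeline, surv)
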