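"""Model inputs for the three-state cost-effectiveness model.

Domain types (transition matrices, per-cycle cost components, utilities,
run configuration), the packaged KEYNOTE-181 subgroup parameter sets, and
helpers that derive per-cycle drug and adverse-event costs from unit
prices, dosing rules and toxicity profiles.

The three-state structure is progression-free survival (PFS, on study
drug), progressive disease (PD, on subsequent-line therapy) and death
(absorbing). All monetary amounts are 2021 US dollars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ValidationError",
    "HealthState",
    "STATES",
    "TransitionMatrix",
    "CostInputs",
    "UtilitySet",
    "ModelConfig",
    "DosingRule",
    "AEEvent",
    "AEProfile",
    "SUBGROUPS",
    "ARMS",
    "monthly_drug_cost",
    "expected_ae_cost_per_month",
    "load_subgroup_params",
    "load_config_file",
    "DOSING_RULES",
    "AE_PROFILES",
]

_ATOL = 1e-9


class ValidationError(ValueError):
    """An input violates a model invariant or names an unknown entity."""


class HealthState:
    """The three health states; death is absorbing."""

    PFS = "PFS"
    PD = "PD"
    DEATH = "DEATH"


#: Canonical state ordering used for every matrix and trace column.
STATES: tuple[str, str, str] = (HealthState.PFS, HealthState.PD, HealthState.DEATH)

SUBGROUPS: tuple[str, ...] = ("total", "cps10", "scc")
ARMS: tuple[str, ...] = ("pembrolizumab", "chemotherapy")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic monthly transition probabilities over (PFS, PD, DEATH).

    Only five probabilities are free: the PFS row (stay / progress / die)
    and the PD row (stay / die). The death row is fixed at (0, 0, 1).
    """

    p_pfs_pfs: float
    p_pfs_pd: float
    p_pfs_death: float
    p_pd_pd: float
    p_pd_death: float

    def __post_init__(self) -> None:
        probs = (self.p_pfs_pfs, self.p_pfs_pd, self.p_pfs_death,
                 self.p_pd_pd, self.p_pd_death)
        for p in probs:
            if not (0.0 - _ATOL <= p <= 1.0 + _ATOL):
                raise ValidationError(
                    f"transition probabilities must lie in [0, 1]; got {probs}")
        violations = []
        pfs_sum = self.p_pfs_pfs + self.p_pfs_pd + self.p_pfs_death
        pd_sum = self.p_pd_pd + self.p_pd_death
        if abs(pfs_sum - 1.0) > _ATOL:
            violations.append(f"PFS row sums to {pfs_sum!r}")
        if abs(pd_sum - 1.0) > _ATOL:
            violations.append(f"PD row sums to {pd_sum!r}")
        if violations:
            raise ValidationError(
                "transition matrix rows must sum to 1: " + "; ".join(violations))

    def as_array(self) -> np.ndarray:
        """Full 3x3 matrix in (PFS, PD, DEATH) order; DEATH row is (0,0,1)."""
        return np.array([
            [self.p_pfs_pfs, self.p_pfs_pd, self.p_pfs_death],
            [0.0, self.p_pd_pd, self.p_pd_death],
            [0.0, 0.0, 1.0],
        ])

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.p_pfs_pfs, self.p_pfs_pd, self.p_pfs_death,
                self.p_pd_pd, self.p_pd_death)


@dataclass(frozen=True)
class CostInputs:
    """Per-cycle (monthly) cost components for one treatment arm, USD.

    The PFS state carries the on-treatment costs (drug acquisition,
    tests/scans, grade >=3 adverse-event management); the PD state carries
    the subsequent-line therapy cost.
    """

    drug_cost_per_month: float
    test_cost_per_month: float
    ae_cost_per_month: float
    subsequent_therapy_cost_per_month: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")

    @property
    def pfs_cost_per_cycle(self) -> float:
        return (self.drug_cost_per_month + self.test_cost_per_month
                + self.ae_cost_per_month)

    @property
    def pd_cost_per_cycle(self) -> float:
        return self.subsequent_therapy_cost_per_month


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities per year of life; death is 0 by construction.

    Baseline sets must satisfy u_pd <= u_pfs (checked when loading a
    config); the class itself only requires each utility to lie in [0, 1]
    so that one-way sensitivity ranges may vary the two independently.
    """

    u_pfs: float = 0.75
    u_pd: float = 0.67
    u_death: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValidationError(
                f"utilities must lie in [0, 1]; got u_pfs={self.u_pfs}, u_pd={self.u_pd}")
        if self.u_death != 0.0:
            raise ValidationError("death utility must be 0")

    def check_ordering(self) -> "UtilitySet":
        """Require u_pd <= u_pfs (baseline plausibility)."""
        if self.u_pd > self.u_pfs:
            raise ValidationError(
                f"baseline utilities must satisfy u_pd <= u_pfs; "
                f"got u_pfs={self.u_pfs}, u_pd={self.u_pd}")
        return self


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration for the cohort simulation.

    ``discount_compounding`` selects the monthly rate derived from the
    annual one: ``"geometric"`` uses (1+r)^(1/12)-1, ``"simple"`` uses
    r/12. Both are accepted conventions; geometric is the default.
    """

    cycle_length_months: float = 1.0
    horizon: int = 60
    annual_discount_rate: float = 0.03
    half_cycle_correction: bool = True
    discount_compounding: str = "geometric"
    wtp_threshold: float = 11105.8
    currency_exchange_rate: float = 6.4831  # CNY per USD, metadata only

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValidationError(f"horizon must be >= 1, got {self.horizon}")
        if not (0.0 <= self.annual_discount_rate < 1.0):
            raise ValidationError(
                f"annual_discount_rate must lie in [0, 1), got {self.annual_discount_rate}")
        if self.discount_compounding not in ("geometric", "simple"):
            raise ValidationError(
                "discount_compounding must be 'geometric' or 'simple', "
                f"got {self.discount_compounding!r}")

    @property
    def monthly_discount_rate(self) -> float:
        r = self.annual_discount_rate
        if self.discount_compounding == "geometric":
            return (1.0 + r) ** (1.0 / 12.0) - 1.0
        return r / 12.0


@dataclass(frozen=True)
class DosingRule:
    """How a drug is priced and administered.

    ``dose_per_administration`` is a flat mg dose, or mg/m² when
    ``dose_is_per_bsa`` is set (scaled by ``bsa``, default 1.72 m²).
    Whole vials are billed (ceiling; no vial sharing).
    """

    unit_price: float           # USD per vial
    vial_size: float            # mg per vial
    dose_per_administration: float
    dose_is_per_bsa: bool = False
    administrations_per_cycle: int = 1
    cycle_days: float = 21.0
    bsa: float = 1.72           # m²

    def __post_init__(self) -> None:
        if self.vial_size <= 0:
            raise ValidationError(f"vial_size must be > 0, got {self.vial_size}")
        if self.unit_price < 0 or self.dose_per_administration <= 0:
            raise ValidationError("unit_price must be >= 0 and dose > 0")
        if self.cycle_days <= 0 or self.administrations_per_cycle < 1:
            raise ValidationError("cycle_days and administrations_per_cycle must be positive")


@dataclass(frozen=True)
class AEEvent:
    """One grade >=3 adverse event: incidence and per-event management cost."""

    name: str
    probability: float
    cost_per_event: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"AE probability must lie in [0,1]: {self.name}")
        if self.cost_per_event < 0:
            raise ValidationError(f"AE cost must be >= 0: {self.name}")


AEProfile = tuple[AEEvent, ...]

#: Days per model month used when converting per-administration prices to
#: per-cycle costs: one month = 28 days (4 weeks), the convention under
#: which the pembrolizumab q21d price reproduces the packaged monthly cost.
DAYS_PER_MONTH = 28.0

# Published acquisition prices (USD per vial) and trial dosing schedules.
DOSING_RULES: dict[str, DosingRule] = {
    "pembrolizumab": DosingRule(unit_price=2763.80, vial_size=100.0,
                                dose_per_administration=200.0,
                                dose_is_per_bsa=False, cycle_days=21.0),
    "docetaxel": DosingRule(unit_price=200.52, vial_size=20.0,
                            dose_per_administration=75.0,
                            dose_is_per_bsa=True, cycle_days=21.0),
    "paclitaxel": DosingRule(unit_price=104.89, vial_size=30.0,
                             dose_per_administration=90.0,
                             dose_is_per_bsa=True,
                             administrations_per_cycle=3, cycle_days=28.0),
    "irinotecan": DosingRule(unit_price=273.50, vial_size=100.0,
                             dose_per_administration=180.0,
                             dose_is_per_bsa=True, cycle_days=14.0),
}

# Grade >=3 AE incidences (trial safety population, as fractions) paired
# with per-event management unit costs. Diarrhea and alopecia have reported
# incidences but no published unit cost and are excluded from the
# reconstruction sum; see expected_ae_cost_per_month.
_AE_COSTS = {
    "fatigue": 214.43, "asthenia": 214.43, "decreased appetite": 105.57,
    "nausea": 98.83, "vomiting": 98.83, "anemia": 328.90,
    "peripheral sensory neuropathy": 17.49, "neutrophil count decreased": 356.31,
    "wbc count decreased": 356.31, "neutropenia": 356.31,
}

_AE_PROBS = {
    "pembrolizumab": {
        "fatigue": 0.0064, "decreased appetite": 0.0064, "asthenia": 0.0127,
        "nausea": 0.0, "vomiting": 0.0032, "anemia": 0.0127,
        "neutrophil count decreased": 0.0032, "peripheral sensory neuropathy": 0.0,
        "wbc count decreased": 0.0, "neutropenia": 0.0,
    },
    "chemotherapy": {
        "fatigue": 0.0034, "decreased appetite": 0.0101, "asthenia": 0.0101,
        "nausea": 0.0236, "vomiting": 0.0203, "anemia": 0.0777,
        "neutrophil count decreased": 0.0980, "peripheral sensory neuropathy": 0.0034,
        "wbc count decreased": 0.1014, "neutropenia": 0.0709,
    },
}

AE_PROFILES: dict[str, AEProfile] = {
    arm: tuple(AEEvent(name, p, _AE_COSTS[name])
               for name, p in probs.items())
    for arm, probs in _AE_PROBS.items()
}


def monthly_drug_cost(rule: DosingRule) -> float:
    """Monthly drug-acquisition cost implied by a dosing rule, USD/month.

    Cost per administration is ``ceil(required_mg / vial_size) * unit_price``
    with ``required_mg = dose * bsa`` for per-BSA dosing. The per-cycle cost
    (``administrations_per_cycle`` administrations every ``cycle_days`` days)
    is converted to a monthly cost with one month = 28 days.

    >>> round(monthly_drug_cost(DOSING_RULES["pembrolizumab"]), 2)
    7370.13
    """
    required_mg = rule.dose_per_administration * (rule.bsa if rule.dose_is_per_bsa else 1.0)
    vials = math.ceil(required_mg / rule.vial_size - _ATOL)
    per_admin = vials * rule.unit_price
    return per_admin * rule.administrations_per_cycle * (DAYS_PER_MONTH / rule.cycle_days)


def expected_ae_cost_per_month(profile: Iterable[AEEvent]) -> float:
    """Expected adverse-event management cost, Σ probability × cost, USD/month.

    Validation helper only: the packaged arm configs carry the published
    monthly AE costs (12.23 / 131.79 USD), which exceed this reconstruction
    because two AEs with reported incidence lack a published unit cost.
    """
    return float(sum(e.probability * e.cost_per_event for e in profile))


def _config_path(subgroup: str):
    if subgroup not in SUBGROUPS:
        raise ValidationError(
            f"unknown subgroup {subgroup!r}; valid choices: {', '.join(SUBGROUPS)}")
    return resources.files("markovce.configs").joinpath(f"{subgroup}.yaml")


def _parse_config(doc: Mapping, arm: str):
    try:
        trans = doc["transitions"][arm]
        costs = doc["costs"][arm]
        util = doc["utilities"]
        model = doc["model"]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"config missing required block/field: {exc}") from exc
    matrix = TransitionMatrix(
        p_pfs_pfs=float(trans["pfs_pfs"]), p_pfs_pd=float(trans["pfs_pd"]),
        p_pfs_death=float(trans["pfs_death"]), p_pd_pd=float(trans["pd_pd"]),
        p_pd_death=float(trans["pd_death"]))
    cost = CostInputs(
        drug_cost_per_month=float(costs["drug"]),
        test_cost_per_month=float(costs["tests"]),
        ae_cost_per_month=float(costs["ae"]),
        subsequent_therapy_cost_per_month=float(costs["subsequent_therapy"]))
    utilities = UtilitySet(u_pfs=float(util["pfs"]), u_pd=float(util["pd"]),
                           u_death=float(util.get("death", 0.0))).check_ordering()
    config = ModelConfig(
        cycle_length_months=float(model["cycle_length_months"]),
        horizon=int(model["horizon_cycles"]),
        annual_discount_rate=float(model["annual_discount_rate"]),
        half_cycle_correction=bool(model["half_cycle_correction"]),
        discount_compounding=str(model.get("discount_compounding", "geometric")),
        wtp_threshold=float(model["wtp_usd_per_qaly"]),
        currency_exchange_rate=float(model.get("cny_per_usd", 6.4831)))
    return matrix, cost, utilities, config


def load_config_file(path, arm: str):
    """Parse one arm out of a subgroup YAML config file.

    Returns ``(TransitionMatrix, CostInputs, UtilitySet, ModelConfig)``.
    Raises :class:`ValidationError` on a missing block or invalid value.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; valid choices: {', '.join(ARMS)}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ValidationError(f"config file {path} is not a mapping")
    return _parse_config(doc, arm)


def load_subgroup_params(subgroup: str, arm: str):
    """Packaged parameter set for one trial subgroup and treatment arm.

    ``subgroup`` is one of ``total`` (all randomized patients), ``cps10``
    (PD-L1 combined positive score >= 10) or ``scc`` (squamous cell
    carcinoma); ``arm`` is ``pembrolizumab`` or ``chemotherapy``.

    Returns ``(TransitionMatrix, CostInputs, UtilitySet, ModelConfig)``.
    Pure: repeated calls return identical values.
    """
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}; valid choices: {', '.join(ARMS)}")
    path = _config_path(subgroup)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    return _parse_config(doc, arm)
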