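"""Perspective-split costing: resource use, productivity, and program costs.

Three perspectives are tracked throughout.  The government perspective
carries facility and medical costs not borne out of pocket, plus the
triage program's own cost.  The patient perspective carries out-of-pocket
visit and admission costs (direct fees plus embedded indirect costs such
as transportation) and caregiver productivity losses (missed workdays
times the average daily wage).  The societal perspective is their sum.

Monetary amounts are expressed in 2021 US dollars; amounts incurred in
other years or in Ugandan shillings are inflated with a GDP-deflator
series and converted at the average 2021 exchange rate.  One-off program
capital is annuitized into an equivalent annual cost over the program
horizon at the discount rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .synthetic_trial import PatientRecord

__all__ = [
    "UnitCostSchedule",
    "ProgramCostItem",
    "EconomicParams",
    "CostBreakdown",
    "inflate_and_convert",
    "annuitize",
    "program_cost_per_child",
    "total_program_capital",
    "annual_program_cost",
    "hru_cost",
    "productivity_cost",
    "societal_cost",
]

Perspective = Literal["government", "patient"]
BASE_YEAR = 2021


@dataclass(frozen=True)
class UnitCostSchedule:
    """Unit costs of care, by perspective, in 2021 USD.

    ``government`` columns are facility/medical costs per outpatient visit
    and per inpatient day; ``patient`` columns are the corresponding
    out-of-pocket costs (direct fees plus indirect costs such as
    transportation, excluding productivity losses).
    """

    gov_outpatient_visit: float
    gov_inpatient_day: float
    patient_outpatient_visit: float
    patient_inpatient_day: float
    currency_year: int = BASE_YEAR
    source_label: str = ""

    def __post_init__(self) -> None:
        for name in (
            "gov_outpatient_visit",
            "gov_inpatient_day",
            "patient_outpatient_visit",
            "patient_inpatient_day",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def visit(self, perspective: Perspective) -> float:
        return (
            self.gov_outpatient_visit
            if perspective == "government"
            else self.patient_outpatient_visit
        )

    def per_diem(self, perspective: Perspective) -> float:
        return (
            self.gov_inpatient_day
            if perspective == "government"
            else self.patient_inpatient_day
        )


@dataclass(frozen=True)
class ProgramCostItem:
    label: str
    amount: float
    currency: str = "USD"  # "USD" | "UGX"
    year: int = BASE_YEAR


@dataclass(frozen=True)
class EconomicParams:
    """Economic and demographic model inputs.

    ``life_expectancy`` and ``daily_wage`` have no defensible universal
    default and must be supplied by configuration.  ``bundle_mortality_or``
    is the literature odds ratio for mortality given a timely sepsis
    bundle, used only by the bundle-linked mortality mode.
    """

    daily_wage: float
    life_expectancy: float
    bundle_mortality_or: float
    discount_rate: float = 0.03
    program_horizon_years: int = 5
    program_cost_items: Sequence[ProgramCostItem] = field(default_factory=tuple)
    annual_children: int = 28_000
    mean_age_at_death: float = 2.0
    wtp_hoc: float = 174.12
    wtp_gdp: float = 883.89
    ugx_per_usd: float = 3587.075
    deflator: Mapping[int, float] = field(default_factory=lambda: {BASE_YEAR: 100.0})

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.program_horizon_years < 1:
            raise ValueError("program_horizon_years must be >= 1")
        if not (self.life_expectancy > self.mean_age_at_death >= 0):
            raise ValueError("need life_expectancy > mean_age_at_death >= 0")
        if self.bundle_mortality_or <= 0:
            raise ValueError("bundle_mortality_or must be positive")
        if self.ugx_per_usd <= 0:
            raise ValueError("ugx_per_usd must be positive")
        if self.daily_wage < 0:
            raise ValueError("daily_wage must be >= 0")
        if self.annual_children <= 0:
            raise ValueError("annual_children must be positive")


def inflate_and_convert(
    amount: float,
    from_year: int,
    deflator_series: Mapping[int, float],
    ugx_per_usd: float,
    currency: str = "UGX",
    to_year: int = BASE_YEAR,
) -> float:
    """Inflate an amount to the base year and convert UGX to USD.

    Inflation uses the ratio of GDP-deflator indices of the country where
    the cost was incurred; conversion divides by the average UGX-per-USD
    exchange rate of the base year.  Amounts already in USD skip the
    conversion step.
    """
    for year in (from_year, to_year):
        if year not in deflator_series:
            raise KeyError(f"deflator series does not cover year {year}")
    inflated = amount * deflator_series[to_year] / deflator_series[from_year]
    if currency == "UGX":
        return inflated / ugx_per_usd
    if currency == "USD":
        return inflated
    raise ValueError(f"unsupported currency {currency!r}")


def annuitize(total_capital: float, r: float, n_y: int) -> float:
    """Equivalent annual cost of a capital outlay over ``n_y`` years.

    Uses the standard annuity factor ``r / (1 - (1+r)^-n_y)``; at a zero
    rate this reduces to an equal split across years.
    """
    if total_capital < 0:
        raise ValueError("total_capital must be >= 0")
    if n_y < 1:
        raise ValueError("n_y must be >= 1")
    if r < 0:
        raise ValueError("rate must be >= 0")
    if r == 0:
        return total_capital / n_y
    # expm1/log1p keep the factor accurate as r -> 0+
    return total_capital * r / -math.expm1(-n_y * math.log1p(r))


def program_cost_per_child(annual_cost: float, annual_children: int) -> float:
    """Annual program cost divided across the children presenting per year."""
    if annual_children <= 0:
        raise ValueError("annual_children must be positive")
    return annual_cost / annual_children


def total_program_capital(econ: EconomicParams) -> float:
    """Sum of program cost items, inflated/converted to 2021 USD."""
    return sum(
        inflate_and_convert(
            item.amount, item.year, econ.deflator, econ.ugx_per_usd, item.currency
        )
        for item in econ.program_cost_items
    )


def annual_program_cost(econ: EconomicParams, rate: float | None = None) -> float:
    """Annuitized program cost per year at the given (or default) rate."""
    r = econ.discount_rate if rate is None else rate
    return annuitize(total_program_capital(econ), r, econ.program_horizon_years)


def hru_cost(
    record: PatientRecord, schedule: UnitCostSchedule, perspective: Perspective
) -> float:
    """Cost of one child's observed health-resource use, one perspective.

    Every enrolled child incurs one outpatient visit (the index
    presentation).  Admission adds the per-diem times the length of stay;
    a post-discharge readmission adds the per-diem times the readmission
    stay; care-seeking without admission adds one further outpatient
    visit.  Deaths incur the same pathway costs as survivors.
    """
    if record.los_days < 0 or record.readmit_los_days < 0:
        raise ValueError("lengths of stay must be non-negative")
    c = schedule.visit(perspective)
    if record.admitted:
        c += schedule.per_diem(perspective) * record.los_days
    if record.postdischarge_pathway == "readmitted":
        c += schedule.per_diem(perspective) * record.readmit_los_days
    elif record.postdischarge_pathway == "care_no_admit":
        c += schedule.visit(perspective)
    return c


def productivity_cost(missed_days: float, daily_wage: float) -> float:
    """Caregiver lost wages: missed workdays times the average daily wage."""
    if missed_days < 0:
        raise ValueError("missed_days must be >= 0")
    if daily_wage < 0:
        raise ValueError("daily_wage must be >= 0")
    return missed_days * daily_wage


@dataclass(frozen=True)
class CostBreakdown:
    """Per-child cost ledger with exact perspective additivity."""

    government_hru: float
    program: float
    patient_oop: float
    productivity: float

    @property
    def government(self) -> float:
        return self.government_hru + self.program

    @property
    def patient(self) -> float:
        return self.patient_oop + self.productivity

    @property
    def societal(self) -> float:
        return self.government + self.patient


def societal_cost(
    record: PatientRecord,
    schedule: UnitCostSchedule,
    daily_wage: float,
    program_cost_child: float,
    arm: Literal["pre", "post"],
) -> CostBreakdown:
    """Full per-child cost decomposition.

    The program cost is charged to the government ledger and only in the
    post (intervention) arm; productivity losses sit on the patient side.
    """
    return CostBreakdown(
        government_hru=hru_cost(record, schedule, "government"),
        program=program_cost_child if arm == "post" else 0.0,
        patient_oop=hru_cost(record, schedule, "patient"),
        productivity=productivity_cost(record.caregiver_missed_days, daily_wage),
    )
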