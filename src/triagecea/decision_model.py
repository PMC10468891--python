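"""Single-episode decision tree for one trial arm.

The tree mirrors the clinical pathway of a child presenting at the
outpatient department: triage and possible admission; if admitted, an
inpatient stay ending in in-hospital death or discharge; every child who
leaves the hospital alive then follows a post-discharge pathway
(readmission anywhere, outpatient care without admission, or no further
care) and independently faces a 7-day post-discharge mortality risk.

Each terminal node carries its pathway probability (product of branch
probabilities), per-child costs by perspective from the costing rules,
and years of life lost (YLL) for the fraction who die.  Expected values
are probability-weighted sums over terminals; the intervention arm
additionally carries the per-child program cost on the government ledger.

Deaths are charged the discounted YLL: the gap between life expectancy
and mean age at death, discounted annually starting one year after death.

All branch arithmetic is plain ``numpy``-compatible algebra, so the same
code evaluates a scalar base case and vectorized Monte Carlo draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .costing import EconomicParams, UnitCostSchedule
from .synthetic_trial import HRU_PATTERNS, hru_pattern

__all__ = [
    "ArmInputs",
    "TerminalNode",
    "ArmResult",
    "ModelResult",
    "discounted_yll_per_death",
    "link_bundle_to_mortality",
    "evaluate_arm",
    "incremental_results",
]

Arm = Literal["pre", "post"]
MortalityMode = Literal["observed_mortality", "bundle_linked"]


@dataclass(frozen=True)
class ArmInputs:
    """Branch probabilities and resource quantities for one arm.

    ``p_readmit``/``p_care_no_admit`` are conditional on leaving the
    hospital alive; ``p_inhosp_death`` on admission; ``p_7day_death``
    applies marginally to everyone leaving alive.  Fields accept scalars
    or aligned numpy arrays (one entry per Monte Carlo draw).
    """

    p_admit: float | np.ndarray
    p_inhosp_death: float | np.ndarray
    p_7day_death: float | np.ndarray
    p_readmit: float | np.ndarray
    p_care_no_admit: float | np.ndarray
    p_timely_bundle: float | np.ndarray
    mean_los: float | np.ndarray = 4.0
    mean_readmit_los: float | np.ndarray = 4.0
    missed_days_by_pattern: Mapping[str, float | np.ndarray] = field(
        default_factory=dict
    )
    n_children: int = 1000

    def validate_scalar(self) -> None:
        for name in (
            "p_admit",
            "p_inhosp_death",
            "p_7day_death",
            "p_readmit",
            "p_care_no_admit",
            "p_timely_bundle",
        ):
            p = getattr(self, name)
            if not (0.0 <= float(p) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if float(self.p_readmit) + float(self.p_care_no_admit) > 1 + 1e-12:
            raise ValueError("p_readmit + p_care_no_admit must not exceed 1")


@dataclass(frozen=True)
class TerminalNode:
    pathway_label: str
    probability: float
    deaths_fraction: float
    cost_gov: float
    cost_patient: float
    cost_productivity: float
    yll: float


@dataclass(frozen=True)
class ArmResult:
    """Per-child expectations for one arm (scalars or per-draw arrays)."""

    arm: str
    expected_cost: dict  # keys: government, patient, societal
    expected_yll: float | np.ndarray
    death_rate: float | np.ndarray
    program_cost_child: float | np.ndarray
    terminals: list[TerminalNode] | None = None

    def terminal_table(self) -> pd.DataFrame:
        if self.terminals is None:
            raise ValueError("terminal table only available for scalar evaluation")
        return pd.DataFrame([t.__dict__ for t in self.terminals])


@dataclass(frozen=True)
class ModelResult:
    """Incremental (post minus pre) results per 1000 children."""

    delta_cost: dict  # per perspective, money per 1000 children
    delta_yll_averted: float  # YLL averted per 1000 children (pre - post)
    icer: dict  # per perspective; nan when undefined
    icer_defined: bool
    per_children: int = 1000


def discounted_yll_per_death(L, a, r: float):
    """Discounted years of life lost for one death at age ``a``.

    With remaining life ``T = L - a``, a zero rate returns ``T``; a
    positive rate returns the annuity of annual life-years discounted
    from one year after death, with the fractional final year discounted
    one further year: ``sum_{t=1..floor(T)} (1+r)^-t + frac(T) *
    (1+r)^-ceil(T)``.  For integer ``T`` this equals the closed form
    ``(1 - (1+r)^-T) / r``.  ``L`` and ``a`` may be arrays.
    """
    L = np.asarray(L, dtype=float)
    a = np.asarray(a, dtype=float)
    T = L - a
    if np.any(T <= 0):
        raise ValueError("life expectancy must exceed age at death")
    if r < 0:
        raise ValueError("discount rate must be >= 0")
    if r == 0:
        out = T
    else:
        whole = np.floor(T)
        frac = T - whole
        annuity = (1.0 - (1.0 + r) ** (-whole)) / r
        out = annuity + frac * (1.0 + r) ** (-(whole + 1.0))
    return float(out) if out.ndim == 0 else out


def link_bundle_to_mortality(p_mort_pre, delta_bundle, odds_ratio):
    """Shift a mortality probability through the timely-bundle odds ratio.

    ``delta_bundle`` is the change (post minus pre) in the proportion of
    children receiving a timely sepsis bundle; the pre-arm mortality odds
    are multiplied by ``odds_ratio ** delta_bundle``.  A zero change or a
    unit odds ratio leaves mortality untouched.
    """
    if np.any(np.asarray(odds_ratio) <= 0):
        raise ValueError("odds ratio must be positive")
    p = np.asarray(p_mort_pre, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("baseline mortality must lie strictly in (0, 1)")
    odds = p / (1.0 - p) * np.asarray(odds_ratio, dtype=float) ** np.asarray(
        delta_bundle, dtype=float
    )
    out = odds / (1.0 + odds)
    return float(out) if out.ndim == 0 else out


def _pathway_cost(
    schedule: UnitCostSchedule,
    perspective: str,
    admitted: bool,
    pathway: str,
    mean_los,
    mean_readmit_los,
):
    """Expected HRU cost of a terminal pathway (mean stays in lieu of draws)."""
    c = schedule.visit(perspective)
    if admitted:
        c = c + schedule.per_diem(perspective) * mean_los
    if pathway == "readmitted":
        c = c + schedule.per_diem(perspective) * mean_readmit_los
    elif pathway == "care_no_admit":
        c = c + schedule.visit(perspective)
    return c


def evaluate_arm(
    inputs: ArmInputs,
    schedule: UnitCostSchedule,
    econ: EconomicParams,
    arm: Arm,
    mode: MortalityMode = "observed_mortality",
    pre_inputs: ArmInputs | None = None,
    program_cost_child: float | np.ndarray = 0.0,
    daily_wage=None,
    age_at_death=None,
    build_terminals: bool | None = None,
) -> ArmResult:
    """Enumerate the decision tree and return per-child expectations.

    In ``bundle_linked`` mode the post arm's mortality probabilities are
    derived from the pre arm's via the literature odds ratio applied to
    the observed change in timely-bundle receipt; the arm's own observed
    mortality rates are ignored.  ``program_cost_child`` is added to the
    government ledger in the post arm only.

    ``daily_wage`` and ``age_at_death`` default to the economic
    parameters; Monte Carlo callers pass per-draw arrays.
    """
    wage = econ.daily_wage if daily_wage is None else daily_wage
    aad = econ.mean_age_at_death if age_at_death is None else age_at_death

    p_inhosp = inputs.p_inhosp_death
    p_7day = inputs.p_7day_death
    if mode == "bundle_linked" and arm == "post":
        if pre_inputs is None:
            raise ValueError("bundle_linked post arm needs pre_inputs")
        delta = np.asarray(inputs.p_timely_bundle) - np.asarray(
            pre_inputs.p_timely_bundle
        )
        p_inhosp = link_bundle_to_mortality(
            pre_inputs.p_inhosp_death, delta, econ.bundle_mortality_or
        )
        p_7day = link_bundle_to_mortality(
            pre_inputs.p_7day_death, delta, econ.bundle_mortality_or
        )
    elif mode not in ("observed_mortality", "bundle_linked"):
        raise ValueError(f"unknown mortality mode {mode!r}")

    for name, p in (
        ("p_admit", inputs.p_admit),
        ("p_inhosp_death", p_inhosp),
        ("p_7day_death", p_7day),
        ("p_readmit", inputs.p_readmit),
        ("p_care_no_admit", inputs.p_care_no_admit),
    ):
        arr = np.asarray(p)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} outside [0, 1] after linkage")

    dyll = discounted_yll_per_death(econ.life_expectancy, aad, econ.discount_rate)
    missed = inputs.missed_days_by_pattern or {k: 0.0 for k in HRU_PATTERNS}

    scalar = build_terminals
    if scalar is None:
        scalar = all(
            np.asarray(x).ndim == 0
            for x in (inputs.p_admit, p_inhosp, p_7day, inputs.p_readmit)
        )

    zero = 0.0 * np.asarray(inputs.p_admit)
    exp = {"government": zero, "patient_oop": zero, "productivity": zero}
    exp_yll = zero
    prob_total = zero
    terminals: list[TerminalNode] | None = [] if scalar else None

    p_none = 1.0 - inputs.p_readmit - inputs.p_care_no_admit
    pathway_probs = {
        "readmitted": inputs.p_readmit,
        "care_no_admit": inputs.p_care_no_admit,
        "none": p_none,
    }

    def add(label, prob, deaths_fraction, admitted, pathway):
        nonlocal exp_yll, prob_total
        cg = _pathway_cost(
            schedule, "government", admitted, pathway, inputs.mean_los, inputs.mean_readmit_los
        )
        cp = _pathway_cost(
            schedule, "patient", admitted, pathway, inputs.mean_los, inputs.mean_readmit_los
        )
        cw = missed.get(hru_pattern(admitted, pathway), 0.0) * wage
        yll = deaths_fraction * dyll
        exp["government"] = exp["government"] + prob * cg
        exp["patient_oop"] = exp["patient_oop"] + prob * cp
        exp["productivity"] = exp["productivity"] + prob * cw
        exp_yll = exp_yll + prob * yll
        prob_total = prob_total + prob
        if terminals is not None:
            terminals.append(
                TerminalNode(
                    pathway_label=label,
                    probability=float(prob),
                    deaths_fraction=float(deaths_fraction),
                    cost_gov=float(cg),
                    cost_patient=float(cp),
                    cost_productivity=float(cw),
                    yll=float(yll),
                )
            )

    # Admitted, died in hospital.
    add(
        "admitted / died in hospital",
        inputs.p_admit * p_inhosp,
        1.0,
        True,
        "none",
    )
    # Children leaving the hospital alive: discharged after admission or
    # never admitted, then pathway x 7-day survival.
    for admitted, p_entry, entry_label in (
        (True, inputs.p_admit * (1.0 - p_inhosp), "admitted / discharged"),
        (False, 1.0 - inputs.p_admit, "not admitted"),
    ):
        for pathway, p_path in pathway_probs.items():
            for died7, p_d7, d_label in (
                (True, p_7day, "died within 7 days"),
                (False, 1.0 - p_7day, "survived"),
            ):
                add(
                    f"{entry_label} / {pathway} / {d_label}",
                    p_entry * p_path * p_d7,
                    1.0 if died7 else 0.0,
                    admitted,
                    pathway,
                )

    err = np.max(np.abs(np.asarray(prob_total) - 1.0))
    if err > 1e-9:
        raise AssertionError(f"terminal probabilities sum to 1 +- {err}")

    program = program_cost_child if arm == "post" else 0.0 * np.asarray(program_cost_child)
    gov = exp["government"] + program
    patient = exp["patient_oop"] + exp["productivity"]
    death_rate = inputs.p_admit * p_inhosp + (1.0 - inputs.p_admit * p_inhosp) * p_7day

    def _maybe_float(x):
        arr = np.asarray(x)
        return float(arr) if arr.ndim == 0 else arr

    return ArmResult(
        arm=arm,
        expected_cost={
            "government": _maybe_float(gov),
            "patient": _maybe_float(patient),
            "societal": _maybe_float(gov + patient),
        },
        expected_yll=_maybe_float(exp_yll),
        death_rate=_maybe_float(death_rate),
        program_cost_child=_maybe_float(program),
        terminals=terminals,
    )


def incremental_results(
    pre_result: ArmResult, post_result: ArmResult, per_children: int = 1000
) -> ModelResult:
    """Incremental cost and effect (post minus pre), scaled per 1000 children.

    YLL averted is ``per_children * (yll_pre - yll_post)``; the ICER is
    the incremental cost divided by the YLL averted.  A negative ICER
    with positive YLL averted means the intervention is cost-saving and
    more effective.  When no YLL are averted the ICER is undefined and
    flagged; incremental costs are still reported.
    """
    delta_yll = per_children * (
        np.asarray(pre_result.expected_yll) - np.asarray(post_result.expected_yll)
    )
    delta_cost = {
        k: per_children
        * (np.asarray(post_result.expected_cost[k]) - np.asarray(pre_result.expected_cost[k]))
        for k in ("government", "patient", "societal")
    }
    defined = bool(np.all(delta_yll != 0.0))
    icer = {
        k: (float(delta_cost[k] / delta_yll) if defined else float("nan"))
        for k in delta_cost
    }
    return ModelResult(
        delta_cost={k: float(v) for k, v in delta_cost.items()},
        delta_yll_averted=float(delta_yll),
        icer=icer,
        icer_defined=defined,
        per_children=per_children,
    )
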