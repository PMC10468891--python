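"""Probabilistic sensitivity analysis of the decision model.

Parameter uncertainty is propagated by Monte Carlo: each draw samples the
model inputs from standard health-economic PSA families -- Beta for
probabilities (parameterized directly from event counts,
``Beta(events, n - events)``), Gamma for costs, wages, stays and missed
workdays (moments matched to the reported mean and 95% CI), and a
zero-truncated Normal for the mean age at death -- then evaluates the
full decision tree for both arms.  Parameters are sampled independently.

The joint distribution of incremental effect (YLL averted per 1000
children) and incremental cost is summarized as cost-effectiveness plane
quadrant shares, mean incrementals with percentile intervals, the average
ICER, and a cost-effectiveness acceptability curve (CEAC): the share of
draws with non-negative net monetary benefit ``lambda * dE - dC`` at each
willingness-to-pay ``lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .config import AppConfig, PhaseCounts
from .costing import EconomicParams, UnitCostSchedule, annual_program_cost, program_cost_per_child
from .decision_model import ArmInputs, evaluate_arm
from .synthetic_trial import HRU_PATTERNS

__all__ = [
    "BaseCase",
    "SampledInputs",
    "PsaResult",
    "beta_from_counts",
    "gamma_from_ci",
    "sample_inputs",
    "run_psa",
    "classify_quadrants",
    "ceac",
    "default_lambda_grid",
]

PERSPECTIVES = ("government", "patient", "societal")
_MAX_REDRAW_ROUNDS = 100


@dataclass(frozen=True)
class BaseCase:
    """Everything one PSA run needs, with scenario hooks.

    ``admission_penalty`` shrinks the post-arm admission reduction by the
    given fraction (applied per draw); ``program_cost_child`` is the
    per-child program cost already priced for the scenario at hand.
    """

    pre: PhaseCounts
    post: PhaseCounts
    schedule: UnitCostSchedule
    econ: EconomicParams
    missed_days: Mapping[str, float]
    missed_days_ci: Mapping[str, tuple[float, float]]
    unit_cost_ci: Mapping[str, tuple[float, float]]
    daily_wage_ci: tuple[float, float]
    age_at_death_ci: tuple[float, float]
    program_cost_child: float
    admission_penalty: float = 0.0
    mortality_mode: str = "observed_mortality"

    @classmethod
    def from_config(cls, cfg: AppConfig, program_cost_child: float | None = None) -> "BaseCase":
        if program_cost_child is None:
            program_cost_child = program_cost_per_child(
                annual_program_cost(cfg.econ), cfg.econ.annual_children
            )
        return cls(
            pre=cfg.pre,
            post=cfg.post,
            schedule=cfg.schedule,
            econ=cfg.econ,
            missed_days=dict(cfg.missed_days),
            missed_days_ci=dict(cfg.missed_days_ci),
            unit_cost_ci=dict(cfg.unit_cost_ci),
            daily_wage_ci=cfg.daily_wage_ci,
            age_at_death_ci=cfg.age_at_death_ci,
            program_cost_child=program_cost_child,
        )

    def deterministic_arm_inputs(self) -> tuple[ArmInputs, ArmInputs]:
        pre = self.pre.arm_inputs(self.missed_days)
        post = self.post.arm_inputs(self.missed_days)
        if self.admission_penalty:
            from .sensitivity import apply_admission_penalty

            post = replace(
                post,
                p_admit=apply_admission_penalty(
                    pre.p_admit, post.p_admit, self.admission_penalty
                ),
            )
        return pre, post


@dataclass(frozen=True)
class SampledSchedule:
    """Per-draw unit-cost arrays with the schedule's lookup interface."""

    gov_outpatient_visit: np.ndarray
    gov_inpatient_day: np.ndarray
    patient_outpatient_visit: np.ndarray
    patient_inpatient_day: np.ndarray

    def visit(self, perspective: str) -> np.ndarray:
        return (
            self.gov_outpatient_visit
            if perspective == "government"
            else self.patient_outpatient_visit
        )

    def per_diem(self, perspective: str) -> np.ndarray:
        return (
            self.gov_inpatient_day
            if perspective == "government"
            else self.patient_inpatient_day
        )


@dataclass(frozen=True)
class SampledInputs:
    pre: ArmInputs
    post: ArmInputs
    schedule: SampledSchedule
    daily_wage: np.ndarray
    age_at_death: np.ndarray
    n_draws: int
    rejections: int = 0


def beta_from_counts(events: int, n: int, rng: np.random.Generator, size: int) -> np.ndarray:
    """Beta draws with mean ``events / n``; degenerate at the boundaries."""
    if not (0 <= events <= n) or n <= 0:
        raise ValueError(f"need 0 <= events <= n with n > 0, got {events}/{n}")
    if events == 0 or events == n:
        return np.full(size, events / n)
    return rng.beta(events, n - events, size=size)


def gamma_from_ci(
    mean: float, lo: float, hi: float, rng: np.random.Generator, size: int, name: str = ""
) -> np.ndarray:
    """Gamma draws moment-matched to a mean and normal-theory 95% CI.

    The CI width supplies the standard deviation (width / 3.92); a
    zero-width interval yields the constant mean.
    """
    if not (lo <= mean <= hi) or mean <= 0:
        raise ValueError(
            f"CI inconsistent with mean for parameter {name or 'unnamed'}: "
            f"mean={mean}, ci=({lo}, {hi})"
        )
    sd = (hi - lo) / 3.92
    if sd == 0:
        return np.full(size, mean)
    var = sd * sd
    shape = mean * mean / var
    scale = var / mean
    return rng.gamma(shape, scale, size=size)


def _truncnorm0(mean: float, lo: float, hi: float, rng, size: int) -> np.ndarray:
    sd = (hi - lo) / 3.92
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_pathway(
    counts: PhaseCounts, rng: np.random.Generator, size: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Independent Beta draws for the two pathway probabilities.

    Draws whose probabilities sum above one are redrawn (independence is
    the sampling assumption; the simplex constraint is structural).
    """
    alive = counts.left_alive
    p_re = beta_from_counts(counts.readmissions, alive, rng, size)
    p_ca = beta_from_counts(counts.care_no_admit, alive, rng, size)
    rejected = 0
    for _ in range(_MAX_REDRAW_ROUNDS):
        bad = p_re + p_ca > 1.0
        n_bad = int(bad.sum())
        if n_bad == 0:
            return p_re, p_ca, rejected
        rejected += n_bad
        p_re[bad] = beta_from_counts(counts.readmissions, alive, rng, n_bad)
        p_ca[bad] = beta_from_counts(counts.care_no_admit, alive, rng, n_bad)
    raise RuntimeError("pathway probabilities kept exceeding 1 after redraw cap")


def _sample_arm(
    counts: PhaseCounts,
    missed: Mapping[str, np.ndarray],
    rng: np.random.Generator,
    size: int,
) -> tuple[ArmInputs, int]:
    alive = counts.left_alive
    p_re, p_ca, rejected = _sample_pathway(counts, rng, size)
    return (
        ArmInputs(
            p_admit=beta_from_counts(counts.admitted, counts.n, rng, size),
            p_inhosp_death=beta_from_counts(counts.inhospital_deaths, counts.admitted, rng, size),
            p_7day_death=beta_from_counts(counts.deaths_7day, alive, rng, size),
            p_readmit=p_re,
            p_care_no_admit=p_ca,
            p_timely_bundle=beta_from_counts(counts.timely_bundle, counts.n, rng, size),
            mean_los=gamma_from_ci(counts.los_mean, *counts.los_ci, rng, size, "los_mean"),
            mean_readmit_los=gamma_from_ci(
                counts.readmit_los_mean, *counts.readmit_los_ci, rng, size, "readmit_los_mean"
            ),
            missed_days_by_pattern=missed,
            n_children=counts.n,
        ),
        rejected,
    )


def sample_inputs(
    base: BaseCase,
    n_draws: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    degenerate: bool = False,
) -> SampledInputs:
    """Draw ``n_draws`` joint input sets for the decision model.

    ``degenerate=True`` collapses every distribution to its point
    estimate (each draw equals the base case), which makes the PSA
    reproduce the deterministic model exactly.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if degenerate:
        pre_d, post_d = base.deterministic_arm_inputs()
        ones = np.ones(n_draws)
        expand = lambda inputs: replace(
            inputs,
            **{
                f: getattr(inputs, f) * ones
                for f in (
                    "p_admit",
                    "p_inhosp_death",
                    "p_7day_death",
                    "p_readmit",
                    "p_care_no_admit",
                    "p_timely_bundle",
                    "mean_los",
                    "mean_readmit_los",
                )
            },
            missed_days_by_pattern={k: v * ones for k, v in inputs.missed_days_by_pattern.items()},
        )
        sched = SampledSchedule(
            **{
                f: getattr(base.schedule, f) * ones
                for f in (
                    "gov_outpatient_visit",
                    "gov_inpatient_day",
                    "patient_outpatient_visit",
                    "patient_inpatient_day",
                )
            }
        )
        return SampledInputs(
            pre=expand(pre_d),
            post=expand(post_d),
            schedule=sched,
            daily_wage=base.econ.daily_wage * ones,
            age_at_death=base.econ.mean_age_at_death * ones,
            n_draws=n_draws,
        )

    missed = {
        k: gamma_from_ci(
            base.missed_days[k], *base.missed_days_ci[k], rng, n_draws, f"missed_days.{k}"
        )
        for k in HRU_PATTERNS
    }
    pre, rej_pre = _sample_arm(base.pre, missed, rng, n_draws)
    post, rej_post = _sample_arm(base.post, missed, rng, n_draws)
    if base.admission_penalty:
        from .sensitivity import apply_admission_penalty

        post = replace(
            post,
            p_admit=apply_admission_penalty(pre.p_admit, post.p_admit, base.admission_penalty),
        )
    sched = SampledSchedule(
        **{
            f: gamma_from_ci(getattr(base.schedule, f), *base.unit_cost_ci[f], rng, n_draws, f)
            for f in (
                "gov_outpatient_visit",
                "gov_inpatient_day",
                "patient_outpatient_visit",
                "patient_inpatient_day",
            )
        }
    )
    wage = gamma_from_ci(base.econ.daily_wage, *base.daily_wage_ci, rng, n_draws, "daily_wage")
    aad = _truncnorm0(base.econ.mean_age_at_death, *base.age_at_death_ci, rng, n_draws)
    return SampledInputs(
        pre=pre,
        post=post,
        schedule=sched,
        daily_wage=wage,
        age_at_death=aad,
        n_draws=n_draws,
        rejections=rej_pre + rej_post,
    )


@dataclass(frozen=True)
class PsaResult:
    draws: pd.DataFrame  # delta_yll + delta_cost per perspective, per 1000 children
    summary: dict
    ceac_curves: dict  # perspective -> DataFrame(lambda, probability_ce)
    n_draws: int
    rejections: int


def run_psa(
    base: BaseCase,
    n_draws: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    degenerate: bool = False,
    lambda_grid: np.ndarray | None = None,
    per_children: int = 1000,
) -> PsaResult:
    """Sample inputs, evaluate both arms per draw, and summarize.

    Incrementals are scaled per 1000 children.  The headline ICER per
    perspective is the ratio of mean incremental cost to mean YLL
    averted (the identity the reported "average ICER" satisfies); the
    mean of per-draw ratios is also reported.
    """
    sampled = sample_inputs(base, n_draws, seed, degenerate=degenerate)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(base.econ)

    results = {}
    for arm, inputs in (("pre", sampled.pre), ("post", sampled.post)):
        results[arm] = evaluate_arm(
            inputs,
            sampled.schedule,
            base.econ,
            arm,
            mode=base.mortality_mode,
            pre_inputs=sampled.pre,
            program_cost_child=base.program_cost_child,
            daily_wage=sampled.daily_wage,
            age_at_death=sampled.age_at_death,
            build_terminals=False,
        )

    delta_yll = per_children * (
        np.asarray(results["pre"].expected_yll) - np.asarray(results["post"].expected_yll)
    )
    draws = pd.DataFrame({"draw_index": np.arange(n_draws), "delta_yll": delta_yll})
    delta_cost = {}
    for k in PERSPECTIVES:
        delta_cost[k] = per_children * (
            np.asarray(results["post"].expected_cost[k])
            - np.asarray(results["pre"].expected_cost[k])
        )
        draws[f"delta_cost_{k}"] = delta_cost[k]
    if not np.all(np.isfinite(delta_yll)):
        raise RuntimeError("non-finite incremental effect in PSA draws")

    summary: dict = {"n_draws": n_draws, "rejections": sampled.rejections}
    ceac_curves: dict = {}
    mean_de = float(np.mean(delta_yll))
    summary["delta_yll_averted"] = {
        "mean": mean_de,
        "ci_low": float(np.percentile(delta_yll, 2.5)),
        "ci_high": float(np.percentile(delta_yll, 97.5)),
    }
    for k in PERSPECTIVES:
        dc = delta_cost[k]
        icer_defined = mean_de != 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            per_draw = np.where(delta_yll != 0.0, dc / delta_yll, np.nan)
        probs = ceac(delta_yll, dc, lambda_grid)
        ceac_curves[k] = pd.DataFrame({"lambda": lambda_grid, "probability_ce": probs})
        summary[k] = {
            "delta_cost": {
                "mean": float(np.mean(dc)),
                "ci_low": float(np.percentile(dc, 2.5)),
                "ci_high": float(np.percentile(dc, 97.5)),
            },
            "icer": float(np.mean(dc) / mean_de) if icer_defined else None,
            "icer_mean_of_draws": (
                float(np.nanmean(per_draw)) if np.any(delta_yll != 0.0) else None
            ),
            "quadrant_shares": classify_quadrants(delta_yll, dc),
            "probability_ce_at_hoc": _prob_at(lambda_grid, probs, base.econ.wtp_hoc),
            "probability_ce_at_gdp": _prob_at(lambda_grid, probs, base.econ.wtp_gdp),
        }
    return PsaResult(
        draws=draws,
        summary=summary,
        ceac_curves=ceac_curves,
        n_draws=n_draws,
        rejections=sampled.rejections,
    )


def _prob_at(lambdas: np.ndarray, probs: np.ndarray, lam: float) -> float | None:
    idx = np.where(np.isclose(lambdas, lam))[0]
    return float(probs[idx[0]]) if idx.size else None


def classify_quadrants(delta_yll: np.ndarray, delta_cost: np.ndarray) -> dict:
    """Shares of the cost-effectiveness plane quadrants.

    Southeast (more effective, cost-saving) is economic dominance;
    northeast is more effective at added cost; the western quadrants are
    less effective.  Shares partition to one.
    """
    de = np.asarray(delta_yll)
    dc = np.asarray(delta_cost)
    if de.size == 0:
        raise ValueError("no draws to classify")
    eff = de > 0
    saving = dc < 0
    return {
        "SE": float(np.mean(eff & saving)),
        "NE": float(np.mean(eff & ~saving)),
        "NW": float(np.mean(~eff & ~saving)),
        "SW": float(np.mean(~eff & saving)),
    }


def ceac(delta_yll: np.ndarray, delta_cost: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
    """Probability of cost-effectiveness at each willingness-to-pay.

    A draw counts as cost-effective at ``lambda`` when its net monetary
    benefit ``lambda * dE - dC`` is non-negative.
    """
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.ndim != 1 or np.any(lam < 0) or np.any(np.diff(lam) < 0):
        raise ValueError("lambda grid must be 1-D, non-negative and ascending")
    nmb = lam[:, None] * np.asarray(delta_yll)[None, :] - np.asarray(delta_cost)[None, :]
    return np.mean(nmb >= 0, axis=1)


def default_lambda_grid(
    econ: EconomicParams, lambda_max: float = 1000.0, step: float = 1.0
) -> np.ndarray:
    """0..lambda_max grid always containing the HOC and WHO thresholds."""
    grid = np.arange(0.0, lambda_max + step / 2, step)
    grid = np.union1d(grid, [econ.wtp_hoc, econ.wtp_gdp])
    return grid
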