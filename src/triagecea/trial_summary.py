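"""Phase-level summaries and pre/post bivariate comparisons.

Aggregates patient-level records into the proportion estimates (with 95%
confidence intervals), relative risks, absolute risk reductions, and
hypothesis tests reported for a two-phase (pre/post) triage trial:
admission and post-discharge care-seeking rates, mortality components,
lengths of stay, and caregiver missed workdays by resource-use stratum.

Proportion intervals default to the Wilson score method (Clopper-Pearson
is selectable); relative-risk intervals use the Katz log-normal
approximation; differences in proportions use a Wald interval.  Discrete
outcomes are compared with a chi-squared test, falling back to Fisher's
exact test when any 2x2 cell is small; continuous outcomes use Student's
t-based intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .synthetic_trial import HRU_PATTERNS, PatientRecord

__all__ = [
    "ProportionEstimate",
    "ComparisonResult",
    "MeanEstimate",
    "PhaseSummary",
    "estimate_proportion",
    "compare_phases",
    "compare_means",
    "summarize_phase",
    "comparison_table",
]

CiMethod = Literal["wilson", "clopper_pearson"]
_SM_METHOD = {"wilson": "wilson", "clopper_pearson": "beta"}


@dataclass(frozen=True)
class ProportionEstimate:
    """A sample proportion with its 95% confidence interval."""

    events: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    ci_method: str

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0 <= self.events <= self.n):
            raise ValueError("events must lie in [0, n]")
        if not (
            -1e-12 <= self.ci_low <= self.point + 1e-12
            and self.point - 1e-12 <= self.ci_high <= 1 + 1e-12
        ):
            raise ValueError("interval must bracket the point estimate within [0, 1]")

    def pct(self, decimals: int = 1) -> str:
        """Render as the tables do: 'point (low to high)' in percent."""
        return (
            f"{self.point * 100:.{decimals}f} "
            f"({self.ci_low * 100:.{decimals}f} to {self.ci_high * 100:.{decimals}f})"
        )


@dataclass(frozen=True)
class MeanEstimate:
    """A sample mean with a t-based 95% CI; degenerate when n < 2."""

    n: int
    mean: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    """Post-vs-pre contrast for one binary outcome."""

    rr: float  # post/pre risk ratio; nan when undefined
    arr_pp: float  # post - pre, percentage points
    rr_ci: tuple[float, float]
    arr_ci: tuple[float, float]  # percentage points
    p_value: float
    test_used: str  # "chi_squared" | "fisher_exact"
    rr_defined: bool = True


def estimate_proportion(
    events: int, n: int, method: CiMethod = "wilson"
) -> ProportionEstimate:
    """Point estimate and 95% CI for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= events <= n):
        raise ValueError(f"events must lie in [0, n], got {events}/{n}")
    if method not in _SM_METHOD:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(events, n, alpha=0.05, method=_SM_METHOD[method])
    return ProportionEstimate(
        events=int(events),
        n=int(n),
        point=events / n,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_method=method,
    )


def _katz_rr_ci(e1: int, n1: int, e0: int, n0: int) -> tuple[float, float]:
    """Log-normal (Katz) 95% CI for the risk ratio (group 1 vs group 0)."""
    if e1 == 0 or e0 == 0:
        return (float("nan"), float("nan"))
    log_rr = math.log((e1 / n1) / (e0 / n0))
    se = math.sqrt(1 / e1 - 1 / n1 + 1 / e0 - 1 / n0)
    z = stats.norm.ppf(0.975)
    return (math.exp(log_rr - z * se), math.exp(log_rr + z * se))


def compare_phases(
    pre: ProportionEstimate,
    post: ProportionEstimate,
    small_cell_rule: Literal["observed", "expected"] = "observed",
) -> ComparisonResult:
    """Relative risk, absolute difference and test for post vs pre.

    The chi-squared test (without continuity correction) is replaced by
    Fisher's exact test when any 2x2 cell is below five.  By default the
    rule inspects observed cells; ``small_cell_rule='expected'`` switches
    to expected counts under independence.
    """
    table = np.array(
        [
            [pre.events, pre.n - pre.events],
            [post.events, post.n - post.events],
        ]
    )
    if small_cell_rule == "observed":
        small = table.min() < 5
    elif small_cell_rule == "expected":
        expected = stats.contingency.expected_freq(table)
        small = expected.min() < 5
    else:
        raise ValueError(f"unknown small_cell_rule {small_cell_rule!r}")

    if small:
        _, p_value = stats.fisher_exact(table)
        test_used = "fisher_exact"
    else:
        _, p_value, _, _ = stats.chi2_contingency(table, correction=False)
        test_used = "chi_squared"

    arr = post.point - pre.point
    z = stats.norm.ppf(0.975)
    se_arr = math.sqrt(
        pre.point * (1 - pre.point) / pre.n + post.point * (1 - post.point) / post.n
    )
    arr_ci = (100 * (arr - z * se_arr), 100 * (arr + z * se_arr))

    rr_defined = pre.point > 0
    rr = post.point / pre.point if rr_defined else float("nan")
    rr_ci = (
        _katz_rr_ci(post.events, post.n, pre.events, pre.n)
        if rr_defined
        else (float("nan"), float("nan"))
    )
    return ComparisonResult(
        rr=rr,
        arr_pp=100 * arr,
        rr_ci=rr_ci,
        arr_ci=arr_ci,
        p_value=float(p_value),
        test_used=test_used,
        rr_defined=rr_defined,
    )


def compare_means(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Welch t-test for a continuous outcome; returns (difference, p)."""
    t = stats.ttest_ind(post, pre, equal_var=False)
    return float(np.mean(post) - np.mean(pre)), float(t.pvalue)


def _mean_ci(values: Sequence[float]) -> MeanEstimate:
    n = len(values)
    if n == 0:
        raise ValueError("cannot summarize an empty sample")
    m = float(np.mean(values))
    if n < 2 or float(np.std(values, ddof=1)) == 0.0:
        return MeanEstimate(n=n, mean=m, ci_low=m, ci_high=m, degenerate=True)
    se = float(np.std(values, ddof=1)) / math.sqrt(n)
    t = stats.t.ppf(0.975, n - 1)
    return MeanEstimate(n=n, mean=m, ci_low=m - t * se, ci_high=m + t * se)


@dataclass(frozen=True)
class PhaseSummary:
    """All phase-level quantities the comparison tables report.

    ``readmission`` and ``care_seeking`` are marginal over all enrolled
    children (how the tables print them); ``readmission_given_alive`` and
    ``care_no_admit_given_alive`` condition on leaving the hospital alive
    (how the decision tree consumes them).  Denominator-less quantities
    (e.g. in-hospital mortality with no admissions) are ``None`` and
    listed in ``undefined``.
    """

    phase: str
    n: int
    timely_bundle: ProportionEstimate
    admission: ProportionEstimate
    inhospital_mortality: ProportionEstimate | None
    mortality_7day: ProportionEstimate | None
    total_mortality: ProportionEstimate
    care_seeking: ProportionEstimate  # any care after leaving, marginal
    readmission: ProportionEstimate  # marginal
    readmission_given_alive: ProportionEstimate | None
    care_no_admit_given_alive: ProportionEstimate | None
    los: MeanEstimate | None
    readmit_los: MeanEstimate | None
    missed_days_by_pattern: dict[str, MeanEstimate]
    lost_to_followup: ProportionEstimate
    undefined: tuple[str, ...] = field(default_factory=tuple)


def summarize_phase(
    records: Sequence[PatientRecord], ci_method: CiMethod = "wilson"
) -> PhaseSummary:
    """Aggregate one phase's records into table-style estimates."""
    if not records:
        raise ValueError("cannot summarize an empty cohort")
    phases = {r.phase for r in records}
    if len(phases) > 1:
        raise ValueError(f"records span multiple phases: {sorted(phases)}")
    n = len(records)

    def prop(events: int, denom: int) -> ProportionEstimate:
        return estimate_proportion(events, denom, method=ci_method)

    admitted = [r for r in records if r.admitted]
    alive = [r for r in records if r.left_alive]
    deaths_hosp = sum(r.died_in_hospital for r in records)
    deaths_7day = sum(r.died_7day for r in records)
    readmits = [r for r in alive if r.postdischarge_pathway == "readmitted"]
    care_only = [r for r in alive if r.postdischarge_pathway == "care_no_admit"]

    undefined: list[str] = []
    inhosp = None
    if admitted:
        inhosp = prop(deaths_hosp, len(admitted))
    else:
        undefined.append("inhospital_mortality")
    mort7 = None
    readm_alive = None
    care_alive = None
    if alive:
        mort7 = prop(deaths_7day, len(alive))
        readm_alive = prop(len(readmits), len(alive))
        care_alive = prop(len(care_only), len(alive))
    else:
        undefined += ["mortality_7day", "readmission_given_alive", "care_no_admit_given_alive"]

    los = _mean_ci([r.los_days for r in admitted]) if admitted else None
    if not admitted:
        undefined.append("los")
    readmit_los = (
        _mean_ci([r.readmit_los_days for r in readmits]) if readmits else None
    )
    if not readmits:
        undefined.append("readmit_los")

    missed: dict[str, MeanEstimate] = {}
    for pat in HRU_PATTERNS:
        vals = [r.caregiver_missed_days for r in records if r.pattern == pat]
        if vals:
            missed[pat] = _mean_ci(vals)

    return PhaseSummary(
        phase=next(iter(phases)),
        n=n,
        timely_bundle=prop(sum(r.timely_bundle for r in records), n),
        admission=prop(len(admitted), n),
        inhospital_mortality=inhosp,
        mortality_7day=mort7,
        total_mortality=prop(deaths_hosp + deaths_7day, n),
        care_seeking=prop(len(readmits) + len(care_only), n),
        readmission=prop(len(readmits), n),
        readmission_given_alive=readm_alive,
        care_no_admit_given_alive=care_alive,
        los=los,
        readmit_los=readmit_los,
        missed_days_by_pattern=missed,
        lost_to_followup=prop(sum(r.lost_to_followup for r in records), n),
        undefined=tuple(undefined),
    )


_TABLE_ROWS = [
    ("timely_bundle", "Received sepsis bundle within one hour"),
    ("inhospital_mortality", "In-hospital mortality for admitted patients"),
    ("mortality_7day", "7-day mortality after leaving hospital"),
    ("total_mortality", "Total mortality"),
    ("admission", "Rate of admission"),
    ("care_seeking", "Rate of seeking any care after leaving hospital"),
    ("readmission", "Rate of readmission after leaving hospital"),
]


def comparison_table(pre: PhaseSummary, post: PhaseSummary) -> pd.DataFrame:
    """Pre/post outcome table mirroring the trial's published layout."""
    rows = []
    for attr, label in _TABLE_ROWS:
        a: ProportionEstimate | None = getattr(pre, attr)
        b: ProportionEstimate | None = getattr(post, attr)
        if a is None or b is None:
            rows.append({"outcome": label, "pre": "undefined", "post": "undefined"})
            continue
        cmp = compare_phases(a, b)
        rows.append(
            {
                "outcome": label,
                "pre": a.pct(),
                "post": b.pct(),
                "p_value": round(cmp.p_value, 3),
                "test": cmp.test_used,
                "rr": round(cmp.rr, 2) if cmp.rr_defined else None,
                "rr_ci_low": round(cmp.rr_ci[0], 2) if cmp.rr_defined else None,
                "rr_ci_high": round(cmp.rr_ci[1], 2) if cmp.rr_defined else None,
                "arr_pp": round(cmp.arr_pp, 1),
                "arr_ci_low": round(cmp.arr_ci[0], 1),
                "arr_ci_high": round(cmp.arr_ci[1], 1),
            }
        )
    return pd.DataFrame(rows)
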