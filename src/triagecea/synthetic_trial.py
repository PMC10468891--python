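"""Synthetic patient-level cohorts for a pre/post triage trial.

Generates one record per enrolled child with the trajectory the economic
model consumes: admission at the referral hospital, length of stay,
in-hospital death, post-discharge care-seeking (readmission elsewhere or
outpatient care without admission), death within seven days of leaving the
hospital, timely receipt of the sepsis bundle, and caregiver workdays lost.

The generator draws each trajectory sequentially from phase-level
parameters (admission probability, conditional mortality, pathway
probabilities, mean stays) so that downstream aggregation recovers the
generating parameters up to sampling error.  Integer day counts (length of
stay, missed workdays) use a shifted Poisson, ``1 + Poisson(mean - 1)``,
which is positive, integer valued, and has exactly the configured mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HRU_PATTERNS",
    "PatientRecord",
    "PhaseParams",
    "hru_pattern",
    "generate_phase",
    "exclude_low_volume_months",
    "records_to_dataframe",
    "dataframe_to_records",
    "write_records_csv",
    "read_records_csv",
]

#: The six health-resource-utilization strata used for caregiver missed
#: workdays: admitted vs not at the referral hospital, crossed with the
#: post-discharge pathway (readmitted anywhere / sought care without
#: admission / no further care).
HRU_PATTERNS = (
    "admit_none",
    "admit_readmit",
    "admit_care",
    "nonadmit_none",
    "nonadmit_readmit",
    "nonadmit_care",
)

PATHWAYS = ("readmitted", "care_no_admit", "none")


class ValidationError(ValueError):
    """A parameter or record violates a structural constraint."""


def hru_pattern(admitted: bool, pathway: str | None) -> str:
    """Map (admitted, post-discharge pathway) to the missed-workday stratum.

    Children who die in hospital have no post-discharge pathway and fall in
    the ``*_none`` stratum of their admission arm.
    """
    prefix = "admit" if admitted else "nonadmit"
    if pathway is None or pathway == "none":
        return f"{prefix}_none"
    if pathway == "readmitted":
        return f"{prefix}_readmit"
    if pathway == "care_no_admit":
        return f"{prefix}_care"
    raise ValidationError(f"unknown postdischarge pathway: {pathway!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One enrolled child's clinical and resource-use trajectory."""

    patient_id: str
    phase: str  # "pre" | "post"
    enrollment_month: int  # month index within the phase, 0-based
    age_years: float
    admitted: bool
    los_days: int  # 0 iff not admitted
    died_in_hospital: bool
    timely_bundle: bool
    postdischarge_pathway: str | None  # None iff died in hospital
    readmit_los_days: int
    died_7day: bool
    caregiver_missed_days: int
    lost_to_followup: bool

    def __post_init__(self) -> None:
        if (self.los_days > 0) != self.admitted:
            raise ValidationError("los_days must be positive iff admitted")
        if self.died_in_hospital and not self.admitted:
            raise ValidationError("died_in_hospital requires admitted")
        if self.died_in_hospital and self.postdischarge_pathway is not None:
            raise ValidationError(
                "postdischarge_pathway undefined for in-hospital deaths"
            )
        if not self.died_in_hospital and self.postdischarge_pathway not in PATHWAYS:
            raise ValidationError(
                f"postdischarge_pathway must be one of {PATHWAYS} for survivors"
            )
        if (self.readmit_los_days > 0) != (self.postdischarge_pathway == "readmitted"):
            raise ValidationError(
                "readmit_los_days must be positive iff pathway is 'readmitted'"
            )
        if self.died_7day and self.died_in_hospital:
            raise ValidationError("died_7day requires leaving hospital alive")

    @property
    def left_alive(self) -> bool:
        return not self.died_in_hospital

    @property
    def pattern(self) -> str:
        return hru_pattern(self.admitted, self.postdischarge_pathway)


_PROB_FIELDS = (
    "p_admit",
    "p_inhosp_death",
    "p_7day_death",
    "p_readmit",
    "p_care_no_admit",
    "p_timely_bundle",
    "p_lost_followup",
)


@dataclass(frozen=True)
class PhaseParams:
    """Generative parameters for one trial phase.

    Pathway probabilities (``p_readmit``, ``p_care_no_admit``) are
    conditional on leaving the referral hospital alive; ``p_inhosp_death``
    is conditional on admission; ``p_7day_death`` applies marginally to
    every child who leaves alive, independent of the pathway.
    """

    n_patients: int
    p_admit: float
    p_inhosp_death: float
    p_7day_death: float
    p_readmit: float
    p_care_no_admit: float
    p_timely_bundle: float
    p_lost_followup: float = 0.015
    los_mean: float = 4.0
    readmit_los_mean: float = 4.0
    missed_days_mean_by_pattern: Mapping[str, float] = field(
        default_factory=lambda: {
            "admit_none": 4.0,
            "admit_readmit": 12.0,
            "admit_care": 6.0,
            "nonadmit_none": 2.0,
            "nonadmit_readmit": 6.0,
            "nonadmit_care": 4.0,
        }
    )
    age_at_death_mean: float = 2.0
    age_mean: float = 2.0
    age_sd: float = 2.2
    n_months: int = 9

    def __post_init__(self) -> None:
        if not (isinstance(self.n_patients, (int, np.integer)) and self.n_patients > 0):
            raise ValidationError("n_patients must be a positive integer")
        for name in _PROB_FIELDS:
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if self.p_readmit + self.p_care_no_admit > 1.0 + 1e-12:
            raise ValidationError("p_readmit + p_care_no_admit must not exceed 1")
        for name in ("los_mean", "readmit_los_mean", "age_at_death_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        missing = set(HRU_PATTERNS) - set(self.missed_days_mean_by_pattern)
        if missing:
            raise ValidationError(f"missed_days_mean_by_pattern missing {sorted(missing)}")
        for k in HRU_PATTERNS:
            if self.missed_days_mean_by_pattern[k] <= 0:
                raise ValidationError(f"missed_days_mean_by_pattern[{k!r}] must be positive")
        if self.n_months < 1:
            raise ValidationError("n_months must be >= 1")


def _shifted_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Positive integer day counts with the requested mean (1 + Poisson(mean-1))."""
    if mean < 1.0:
        raise ValidationError(f"count distribution needs mean >= 1, got {mean}")
    return 1 + rng.poisson(mean - 1.0, size=size)


def generate_phase(
    params: PhaseParams, seed: int | np.random.SeedSequence, phase: str = "pre"
) -> list[PatientRecord]:
    """Draw a full cohort of patient trajectories for one phase.

    The draw order is fixed, so identical ``(params, seed)`` give identical
    cohorts.  Trajectories are sequential: admission, then (if admitted)
    length of stay and in-hospital death, then for children leaving alive a
    post-discharge pathway and an independent 7-day death indicator, then
    caregiver missed workdays from the stratum-specific mean.
    """
    rng = np.random.default_rng(seed)
    n = params.n_patients

    month = rng.integers(0, params.n_months, size=n)
    # Age is generated for realism only; it does not enter the economic
    # model.  Rounded so records survive a CSV round-trip exactly.
    age = np.round(np.abs(rng.normal(params.age_mean, params.age_sd, size=n)), 3)
    admitted = rng.random(n) < params.p_admit
    los = np.where(admitted, _shifted_poisson(rng, params.los_mean, n), 0)
    died_hosp = admitted & (rng.random(n) < params.p_inhosp_death)
    timely = rng.random(n) < params.p_timely_bundle

    alive = ~died_hosp
    u = rng.random(n)
    pathway = np.full(n, "none", dtype=object)
    pathway[u < params.p_readmit + params.p_care_no_admit] = "care_no_admit"
    pathway[u < params.p_readmit] = "readmitted"
    pathway[~alive] = None

    readmit_los = np.where(
        (pathway == "readmitted"),
        _shifted_poisson(rng, params.readmit_los_mean, n),
        0,
    )
    died_7day = alive & (rng.random(n) < params.p_7day_death)
    lost = rng.random(n) < params.p_lost_followup

    missed = np.empty(n, dtype=int)
    draws = {
        k: _shifted_poisson(rng, params.missed_days_mean_by_pattern[k], n)
        for k in HRU_PATTERNS
    }
    for i in range(n):
        missed[i] = draws[hru_pattern(bool(admitted[i]), pathway[i])][i]

    return [
        PatientRecord(
            patient_id=f"{phase}-{i:05d}",
            phase=phase,
            enrollment_month=int(month[i]),
            age_years=float(age[i]),
            admitted=bool(admitted[i]),
            los_days=int(los[i]),
            died_in_hospital=bool(died_hosp[i]),
            timely_bundle=bool(timely[i]),
            postdischarge_pathway=pathway[i],
            readmit_los_days=int(readmit_los[i]),
            died_7day=bool(died_7day[i]),
            caregiver_missed_days=int(missed[i]),
            lost_to_followup=bool(lost[i]),
        )
        for i in range(n)
    ]


def exclude_low_volume_months(
    records: Sequence[PatientRecord], threshold_fraction: float = 0.5
) -> list[PatientRecord]:
    """Drop months whose enrollment fell below a fraction of the phase median.

    Within each phase, months whose enrollment count is strictly below
    ``threshold_fraction`` times that phase's median monthly count are
    removed.  This mirrors the exclusion of months where outpatient
    attendance collapsed (pandemic travel restrictions): the rule, not any
    particular month list, is the algorithm.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValidationError("threshold_fraction must lie in (0, 1)")
    if not records:
        return []
    counts: dict[str, dict[int, int]] = {}
    for r in records:
        counts.setdefault(r.phase, {}).setdefault(r.enrollment_month, 0)
        counts[r.phase][r.enrollment_month] += 1
    keep: set[tuple[str, int]] = set()
    for phase, by_month in counts.items():
        if len(by_month) < 2:
            raise ValidationError(
                f"phase {phase!r} has fewer than 2 distinct months; median rule undefined"
            )
        cutoff = threshold_fraction * float(np.median(list(by_month.values())))
        for m, c in by_month.items():
            if c >= cutoff:
                keep.add((phase, m))
    return [r for r in records if (r.phase, r.enrollment_month) in keep]


# -- CSV round-trip ----------------------------------------------------------

_COLUMNS = [f.name for f in fields(PatientRecord)]


def records_to_dataframe(records: Iterable[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in records])
    return df


def dataframe_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in _COLUMNS}
        if pd.isna(d["postdischarge_pathway"]) or d["postdischarge_pathway"] == "":
            d["postdischarge_pathway"] = None
        for c in ("enrollment_month", "los_days", "readmit_los_days", "caregiver_missed_days"):
            d[c] = int(d[c])
        for c in ("admitted", "died_in_hospital", "timely_bundle", "died_7day", "lost_to_followup"):
            d[c] = bool(d[c])
        out.append(PatientRecord(**d))
    return out


def write_records_csv(records: Iterable[PatientRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)


def read_records_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    return dataframe_to_records(df)
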