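"""Configuration loading and validation.

One YAML file carries everything the pipeline needs: per-phase trial
counts (from which point probabilities and Beta uncertainty are derived),
the unit-cost schedule by perspective, economic and demographic
parameters, Monte Carlo settings, and the scenario list.

Counts, rather than proportions, are the primary representation: the
point estimate of each probability is ``events / n`` and its probabilistic
sensitivity distribution is ``Beta(events, n - events)``, so the same
numbers drive the deterministic model and the Monte Carlo analysis.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .costing import EconomicParams, ProgramCostItem, UnitCostSchedule
from .decision_model import ArmInputs
from .synthetic_trial import HRU_PATTERNS, PhaseParams

__all__ = [
    "ConfigError",
    "PhaseCounts",
    "AppConfig",
    "load_config",
    "default_config_path",
    "load_default_config",
]


class ConfigError(ValueError):
    """A configuration document is missing or violates the schema."""


@dataclass(frozen=True)
class PhaseCounts:
    """Observed event counts for one trial phase.

    ``readmissions`` and ``care_no_admit`` count children who left the
    hospital alive; their conditional probabilities use the survivors'
    denominator ``n - inhospital_deaths``.
    """

    n: int
    admitted: int
    inhospital_deaths: int
    deaths_7day: int
    readmissions: int
    care_no_admit: int
    timely_bundle: int
    lost_to_followup: int = 0
    n_months: int = 9
    los_mean: float = 4.0
    los_ci: tuple[float, float] = (4.0, 4.0)
    readmit_los_mean: float = 4.0
    readmit_los_ci: tuple[float, float] = (4.0, 4.0)
    age_mean: float = 2.0
    age_sd: float = 2.2

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("phase n must be positive")
        for name in (
            "admitted",
            "inhospital_deaths",
            "deaths_7day",
            "readmissions",
            "care_no_admit",
            "timely_bundle",
            "lost_to_followup",
        ):
            v = getattr(self, name)
            if v < 0 or v > self.n:
                raise ConfigError(f"count {name}={v} outside [0, n={self.n}]")
        if self.inhospital_deaths > self.admitted:
            raise ConfigError("inhospital_deaths cannot exceed admitted")

    @property
    def left_alive(self) -> int:
        return self.n - self.inhospital_deaths

    def phase_params(self, missed_days: Mapping[str, float]) -> PhaseParams:
        alive = self.left_alive
        return PhaseParams(
            n_patients=self.n,
            p_admit=self.admitted / self.n,
            p_inhosp_death=(self.inhospital_deaths / self.admitted) if self.admitted else 0.0,
            p_7day_death=(self.deaths_7day / alive) if alive else 0.0,
            p_readmit=(self.readmissions / alive) if alive else 0.0,
            p_care_no_admit=(self.care_no_admit / alive) if alive else 0.0,
            p_timely_bundle=self.timely_bundle / self.n,
            p_lost_followup=self.lost_to_followup / self.n,
            los_mean=self.los_mean,
            readmit_los_mean=self.readmit_los_mean,
            missed_days_mean_by_pattern=dict(missed_days),
            age_mean=self.age_mean,
            age_sd=self.age_sd,
            n_months=self.n_months,
        )

    def arm_inputs(self, missed_days: Mapping[str, float]) -> ArmInputs:
        p = self.phase_params(missed_days)
        return ArmInputs(
            p_admit=p.p_admit,
            p_inhosp_death=p.p_inhosp_death,
            p_7day_death=p.p_7day_death,
            p_readmit=p.p_readmit,
            p_care_no_admit=p.p_care_no_admit,
            p_timely_bundle=p.p_timely_bundle,
            mean_los=self.los_mean,
            mean_readmit_los=self.readmit_los_mean,
            missed_days_by_pattern=dict(missed_days),
            n_children=self.n,
        )


@dataclass(frozen=True)
class AppConfig:
    pre: PhaseCounts
    post: PhaseCounts
    schedule: UnitCostSchedule
    econ: EconomicParams
    missed_days: dict[str, float]
    missed_days_ci: dict[str, tuple[float, float]]
    unit_cost_ci: dict[str, tuple[float, float]]  # keyed like schedule fields
    daily_wage_ci: tuple[float, float]
    age_at_death_ci: tuple[float, float]
    n_draws: int = 10_000
    lambda_max: float = 1000.0
    lambda_step: float = 1.0
    scenarios: tuple[dict, ...] = field(default_factory=tuple)
    raw: dict = field(default_factory=dict, compare=False)

    def pre_inputs(self) -> ArmInputs:
        return self.pre.arm_inputs(self.missed_days)

    def post_inputs(self) -> ArmInputs:
        return self.post.arm_inputs(self.missed_days)


def _require(d: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in d:
        raise ConfigError(f"missing required config key: {path}.{key}")
    return d[key]


def _ci(value: Any, path: str) -> tuple[float, float]:
    if (
        not isinstance(value, (list, tuple))
        or len(value) != 2
        or not all(isinstance(x, (int, float)) for x in value)
    ):
        raise ConfigError(f"{path} must be a [low, high] pair")
    lo, hi = float(value[0]), float(value[1])
    if lo > hi:
        raise ConfigError(f"{path}: low bound exceeds high bound")
    return lo, hi


def _phase_counts(d: Mapping[str, Any], path: str) -> PhaseCounts:
    kwargs: dict[str, Any] = {}
    for key in (
        "n",
        "admitted",
        "inhospital_deaths",
        "deaths_7day",
        "readmissions",
        "care_no_admit",
        "timely_bundle",
    ):
        kwargs[key] = int(_require(d, key, path))
    for key, cast in (
        ("lost_to_followup", int),
        ("n_months", int),
        ("los_mean", float),
        ("readmit_los_mean", float),
        ("age_mean", float),
        ("age_sd", float),
    ):
        if key in d:
            kwargs[key] = cast(d[key])
    for key in ("los_ci", "readmit_los_ci"):
        if key in d:
            kwargs[key] = _ci(d[key], f"{path}.{key}")
    try:
        return PhaseCounts(**kwargs)
    except ConfigError:
        raise
    except ValueError as exc:  # dataclass-level validation
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(source: str | Path | Mapping[str, Any]) -> AppConfig:
    """Parse and validate a configuration document (path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = copy.deepcopy(dict(source))
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")

    trial = _require(doc, "trial", "")
    pre = _phase_counts(_require(trial, "pre", "trial"), "trial.pre")
    post = _phase_counts(_require(trial, "post", "trial"), "trial.post")

    md = _require(doc, "missed_days", "")
    missed_days: dict[str, float] = {}
    missed_days_ci: dict[str, tuple[float, float]] = {}
    for pattern in HRU_PATTERNS:
        entry = _require(md, pattern, "missed_days")
        missed_days[pattern] = float(_require(entry, "mean", f"missed_days.{pattern}"))
        missed_days_ci[pattern] = _ci(
            _require(entry, "ci", f"missed_days.{pattern}"), f"missed_days.{pattern}.ci"
        )

    uc = _require(doc, "unit_costs", "")
    schedule_kwargs: dict[str, Any] = {
        "currency_year": int(uc.get("currency_year", 2021)),
        "source_label": str(uc.get("source_label", "")),
    }
    unit_cost_ci: dict[str, tuple[float, float]] = {}
    for side, prefix in (("government", "gov"), ("patient", "patient")):
        block = _require(uc, side, "unit_costs")
        for item in ("outpatient_visit", "inpatient_day"):
            entry = _require(block, item, f"unit_costs.{side}")
            key = f"{prefix}_{item}"
            schedule_kwargs[key] = float(_require(entry, "mean", f"unit_costs.{side}.{item}"))
            unit_cost_ci[key] = _ci(
                _require(entry, "ci", f"unit_costs.{side}.{item}"),
                f"unit_costs.{side}.{item}.ci",
            )
    try:
        schedule = UnitCostSchedule(**schedule_kwargs)
    except ValueError as exc:
        raise ConfigError(f"unit_costs: {exc}") from exc

    ec = _require(doc, "economics", "")
    items = []
    for i, item in enumerate(ec.get("program_cost_items", [])):
        items.append(
            ProgramCostItem(
                label=str(_require(item, "label", f"economics.program_cost_items[{i}]")),
                amount=float(_require(item, "amount", f"economics.program_cost_items[{i}]")),
                currency=str(item.get("currency", "USD")),
                year=int(item.get("year", 2021)),
            )
        )
    wage = _require(ec, "daily_wage", "economics")
    econ_kwargs = dict(
        daily_wage=float(_require(wage, "mean", "economics.daily_wage")),
        life_expectancy=float(_require(ec, "life_expectancy", "economics")),
        bundle_mortality_or=float(_require(ec, "bundle_mortality_or", "economics")),
        discount_rate=float(ec.get("discount_rate", 0.03)),
        program_horizon_years=int(ec.get("program_horizon_years", 5)),
        program_cost_items=tuple(items),
        annual_children=int(ec.get("annual_children", 28_000)),
        mean_age_at_death=float(
            _require(ec, "mean_age_at_death", "economics")["mean"]
            if isinstance(ec.get("mean_age_at_death"), dict)
            else ec.get("mean_age_at_death", 2.0)
        ),
        wtp_hoc=float(ec.get("wtp_hoc", 174.12)),
        wtp_gdp=float(ec.get("wtp_gdp", 883.89)),
        ugx_per_usd=float(ec.get("ugx_per_usd", 3587.075)),
        deflator={int(k): float(v) for k, v in ec.get("deflator", {2021: 100.0}).items()},
    )
    try:
        econ = EconomicParams(**econ_kwargs)
    except ValueError as exc:
        raise ConfigError(f"economics: {exc}") from exc

    aad = ec.get("mean_age_at_death", {})
    age_ci = (
        _ci(aad["ci"], "economics.mean_age_at_death.ci")
        if isinstance(aad, dict) and "ci" in aad
        else (econ.mean_age_at_death, econ.mean_age_at_death)
    )
    wage_ci = (
        _ci(wage["ci"], "economics.daily_wage.ci")
        if "ci" in wage
        else (econ.daily_wage, econ.daily_wage)
    )

    psa = doc.get("psa", {})
    scenarios = tuple(doc.get("scenarios", []) or ())

    return AppConfig(
        pre=pre,
        post=post,
        schedule=schedule,
        econ=econ,
        missed_days=missed_days,
        missed_days_ci=missed_days_ci,
        unit_cost_ci=unit_cost_ci,
        daily_wage_ci=wage_ci,
        age_at_death_ci=age_ci,
        n_draws=int(psa.get("n_draws", 10_000)),
        lambda_max=float(psa.get("lambda_max", 1000.0)),
        lambda_step=float(psa.get("lambda_step", 1.0)),
        scenarios=scenarios,
        raw=doc,
    )


def default_config_path() -> Path:
    """Path of the packaged default configuration."""
    return Path(resources.files("triagecea").joinpath("data/default_config.yaml"))


def load_default_config() -> AppConfig:
    return load_config(default_config_path())
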