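"""Pipeline orchestration: generate, summarize, model, PSA, scenarios, report.

``run_pipeline`` executes the whole analysis from one configuration file
and a single root seed, writing machine-readable CSV/JSON outputs and a
run manifest.  All randomness is spawned deterministically from the root
seed (one child stream per stage), so a rerun with the same config and
seed reproduces every CSV byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AppConfig, load_config
from .costing import annual_program_cost, program_cost_per_child, total_program_capital
from .decision_model import evaluate_arm, incremental_results
from .psa import BaseCase, default_lambda_grid, run_psa
from .sensitivity import ScenarioSpec, run_scenario, tornado_table
from .synthetic_trial import generate_phase, write_records_csv
from .trial_summary import comparison_table, summarize_phase

__all__ = ["RunManifest", "run_pipeline", "threshold_report"]

log = logging.getLogger("triagecea")


@dataclass
class RunManifest:
    config_path: str
    config_sha256: str
    seed: int
    n_draws: int
    version: str
    timestamp: str
    outputs: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def threshold_report(ceac_df: pd.DataFrame, econ, target: float = 0.95) -> dict:
    """Cost-effectiveness verdicts at the HOC and WHO thresholds.

    Reports the probability of cost-effectiveness at each configured
    willingness-to-pay threshold and the smallest grid value at which the
    probability reaches ``target`` (flagged when never reached).
    """
    lam = ceac_df["lambda"].to_numpy()
    p = ceac_df["probability_ce"].to_numpy()

    def at(value: float) -> float | None:
        idx = np.where(np.isclose(lam, value))[0]
        return float(p[idx[0]]) if idx.size else None

    reached = np.where(p >= target)[0]
    return {
        "probability_ce_at_hoc": at(econ.wtp_hoc),
        "probability_ce_at_gdp": at(econ.wtp_gdp),
        "wtp_hoc": econ.wtp_hoc,
        "wtp_gdp": econ.wtp_gdp,
        "target_probability": target,
        "lambda_at_target": float(lam[reached[0]]) if reached.size else None,
        "target_reached": bool(reached.size),
    }


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    n_draws: int | None = None,
) -> RunManifest:
    """Run the full analysis and write all outputs under ``out_dir``."""
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg: AppConfig = load_config(config_path)
    n_draws = cfg.n_draws if n_draws is None else n_draws

    manifest = RunManifest(
        config_path=str(config_path),
        config_sha256=hashlib.sha256(config_path.read_bytes()).hexdigest(),
        seed=seed,
        n_draws=n_draws,
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    def emit(name: str):
        manifest.outputs.append(name)
        return out / name

    root = np.random.SeedSequence(seed)
    seed_gen, seed_psa, seed_scen = root.spawn(3)

    # 1. Synthetic cohorts.
    log.info("generating synthetic cohorts")
    gen_seeds = seed_gen.spawn(2)
    records = {
        phase: generate_phase(
            getattr(cfg, phase).phase_params(cfg.missed_days), gen_seeds[i], phase=phase
        )
        for i, phase in enumerate(("pre", "post"))
    }
    for phase in ("pre", "post"):
        write_records_csv(records[phase], emit(f"cohort_{phase}.csv"))

    # 2. Phase summaries and bivariate comparisons.
    log.info("summarizing phases")
    summaries = {phase: summarize_phase(records[phase]) for phase in ("pre", "post")}
    comparison_table(summaries["pre"], summaries["post"]).to_csv(
        emit("outcomes_table.csv"), index=False
    )
    missed_rows = []
    for phase in ("pre", "post"):
        for pat, est in summaries[phase].missed_days_by_pattern.items():
            missed_rows.append(
                {"phase": phase, "pattern": pat, "n": est.n, "mean_days": est.mean,
                 "ci_low": est.ci_low, "ci_high": est.ci_high,
                 "productivity_cost": est.mean * cfg.econ.daily_wage}
            )
    pd.DataFrame(missed_rows).to_csv(emit("missed_days_table.csv"), index=False)

    # 3. Deterministic decision model.
    log.info("evaluating decision model")
    pcc = program_cost_per_child(annual_program_cost(cfg.econ), cfg.econ.annual_children)
    base = BaseCase.from_config(cfg, program_cost_child=pcc)
    pre_inputs, post_inputs = base.deterministic_arm_inputs()
    arm_results = {}
    for arm, inputs in (("pre", pre_inputs), ("post", post_inputs)):
        res = evaluate_arm(
            inputs, cfg.schedule, cfg.econ, arm,
            pre_inputs=pre_inputs, program_cost_child=pcc,
        )
        arm_results[arm] = res
        res.terminal_table().to_csv(emit(f"terminals_{arm}.csv"), index=False)
    model = incremental_results(arm_results["pre"], arm_results["post"])
    _write_json(
        {
            "program_capital": total_program_capital(cfg.econ),
            "annual_program_cost": annual_program_cost(cfg.econ),
            "program_cost_per_child": pcc,
            "per_arm": {
                arm: {
                    "expected_cost": arm_results[arm].expected_cost,
                    "expected_yll": arm_results[arm].expected_yll,
                    "death_rate": arm_results[arm].death_rate,
                }
                for arm in ("pre", "post")
            },
            "incremental": {
                "delta_cost_per_1000": model.delta_cost,
                "delta_yll_averted_per_1000": model.delta_yll_averted,
                "icer": model.icer,
                "icer_defined": model.icer_defined,
            },
        },
        emit("model_result.json"),
    )

    # 4. Probabilistic sensitivity analysis.
    log.info("running PSA (%d draws)", n_draws)
    lam = default_lambda_grid(cfg.econ, cfg.lambda_max, cfg.lambda_step)
    psa = run_psa(base, n_draws=n_draws, seed=seed_psa, lambda_grid=lam)
    psa.draws.to_csv(emit("psa_draws.csv"), index=False)
    for persp, curve in psa.ceac_curves.items():
        curve.to_csv(emit(f"ceac_{persp}.csv"), index=False)
    _write_json(psa.summary, emit("psa_summary.json"))

    # 5. Scenario analyses.
    scen_results = []
    scen_seeds = seed_scen.spawn(max(len(cfg.scenarios), 1))
    for i, scen in enumerate(cfg.scenarios):
        spec = ScenarioSpec.from_mapping(scen)
        log.info("scenario %s", spec.name)
        res = run_scenario(spec, base, n_draws=n_draws, seed=scen_seeds[i], records=records)
        scen_results.append(res)
        sub = out / "scenarios" / spec.name
        sub.mkdir(parents=True, exist_ok=True)
        _write_json(res.psa.summary, sub / "psa_summary.json")
        manifest.outputs.append(f"scenarios/{spec.name}/psa_summary.json")
    if scen_results:
        tornado_table(scen_results).to_csv(emit("tornado.csv"), index=False)

    # 6. Threshold verdicts (societal perspective).
    _write_json(
        threshold_report(psa.ceac_curves["societal"], cfg.econ),
        emit("threshold_report.json"),
    )

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
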