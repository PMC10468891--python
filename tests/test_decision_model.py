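"""Decision-tree evaluation: YLL discounting, bundle linkage, incrementals."""

from dataclasses import replace

import numpy as np
import pytest

from triagecea.decision_model import (
    ArmInputs,
    ArmResult,
    ModelResult,
    discounted_yll_per_death,
    evaluate_arm,
    incremental_results,
    link_bundle_to_mortality,
)


class TestDiscountedYll:
    def test_zero_rate_is_plain_difference(self):
        assert discounted_yll_per_death(62.0, 2.0, 0.0) == 60.0

    def test_three_percent_sixty_years(self):
        # closed form (1 - 1.03^-60) / 0.03
        assert discounted_yll_per_death(62.0, 2.0, 0.03) == pytest.approx(27.68, abs=0.005)

    def test_single_remaining_year(self):
        assert discounted_yll_per_death(62.0, 61.0, 0.03) == pytest.approx(1 / 1.03)

    def test_closed_form_agreement_for_integer_horizons(self):
        for T, r in [(10, 0.01), (35, 0.03), (60, 0.05)]:
            assert discounted_yll_per_death(T + 2.0, 2.0, r) == pytest.approx(
                (1 - (1 + r) ** -T) / r, abs=1e-9
            )

    def test_fractional_final_year_between_neighbors(self):
        lo = discounted_yll_per_death(62.0, 2.0, 0.03)
        mid = discounted_yll_per_death(62.5, 2.0, 0.03)
        hi = discounted_yll_per_death(63.0, 2.0, 0.03)
        assert lo < mid < hi

    def test_discounting_reduces_yll(self):
        assert discounted_yll_per_death(62.0, 2.0, 0.03) < 60.0

    def test_death_after_life_expectancy_rejected(self):
        with pytest.raises(ValueError):
            discounted_yll_per_death(2.0, 2.0, 0.03)

    def test_vectorized_over_age_at_death(self):
        ages = np.array([1.0, 2.0, 3.0])
        out = discounted_yll_per_death(62.0, ages, 0.03)
        assert out.shape == (3,)
        assert np.all(np.diff(out) < 0)  # dying older loses fewer years


class TestBundleLinkage:
    def test_zero_bundle_change_leaves_mortality(self):
        assert link_bundle_to_mortality(0.009, 0.0, 0.64) == pytest.approx(0.009)

    def test_unit_odds_ratio_is_identity(self):
        assert link_bundle_to_mortality(0.12, 0.5, 1.0) == pytest.approx(0.12)

    def test_hand_odds_arithmetic(self):
        # p=0.01 -> odds 0.010101; halving the odds gives p ~= 0.005025
        assert link_bundle_to_mortality(0.01, 1.0, 0.5) == pytest.approx(0.005025, abs=1e-6)

    def test_protective_or_reduces_mortality_when_bundle_improves(self):
        assert link_bundle_to_mortality(0.02, 0.3, 0.64) < 0.02

    def test_invalid_or_rejected(self):
        with pytest.raises(ValueError):
            link_bundle_to_mortality(0.01, 0.5, 0.0)


class TestEvaluateArm:
    def test_terminal_probabilities_partition(self, arm_results):
        for res in arm_results.values():
            total = res.terminal_table()["probability"].sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_no_deaths_no_yll(self, cfg):
        zero = ArmInputs(
            p_admit=0.2,
            p_inhosp_death=0.0,
            p_7day_death=0.0,
            p_readmit=0.02,
            p_care_no_admit=0.05,
            p_timely_bundle=0.01,
            missed_days_by_pattern=cfg.missed_days,
        )
        res = evaluate_arm(zero, cfg.schedule, cfg.econ, "pre")
        assert res.expected_yll == 0.0 and res.death_rate == 0.0

    def test_death_rate_composes_to_published_total_mortality(self, arm_results):
        # admission x in-hospital death + surviving fraction x 7-day death
        assert round(arm_results["pre"].death_rate * 100, 1) == 0.9
        assert round(arm_results["post"].death_rate * 100, 1) == 0.3

    def test_expected_yll_monotone_in_death_probabilities(self, cfg, base_case):
        pre, _ = base_case.deterministic_arm_inputs()
        base = evaluate_arm(pre, cfg.schedule, cfg.econ, "pre")
        for field in ("p_inhosp_death", "p_7day_death"):
            bumped = evaluate_arm(
                replace(pre, **{field: getattr(pre, field) + 0.01}),
                cfg.schedule,
                cfg.econ,
                "pre",
            )
            assert bumped.expected_yll > base.expected_yll

    def test_expected_cost_monotone_in_stay_and_unit_cost(self, cfg, base_case):
        pre, _ = base_case.deterministic_arm_inputs()
        base = evaluate_arm(pre, cfg.schedule, cfg.econ, "pre")
        longer = evaluate_arm(replace(pre, mean_los=pre.mean_los + 1), cfg.schedule, cfg.econ, "pre")
        assert longer.expected_cost["societal"] > base.expected_cost["societal"]
        dearer = evaluate_arm(
            pre, replace(cfg.schedule, gov_inpatient_day=cfg.schedule.gov_inpatient_day + 1),
            cfg.econ, "pre",
        )
        assert dearer.expected_cost["government"] > base.expected_cost["government"]
        assert dearer.expected_cost["patient"] == pytest.approx(base.expected_cost["patient"])

    def test_bundle_linked_equals_observed_at_zero_delta(self, cfg, base_case):
        pre, _ = base_case.deterministic_arm_inputs()
        observed = evaluate_arm(pre, cfg.schedule, cfg.econ, "pre")
        post_same_bundle = replace(pre, p_timely_bundle=pre.p_timely_bundle)
        linked = evaluate_arm(
            post_same_bundle, cfg.schedule, cfg.econ, "post",
            mode="bundle_linked", pre_inputs=pre,
        )
        assert linked.death_rate == pytest.approx(observed.death_rate)

    def test_bundle_linked_mode_moves_mortality_with_bundle_uptake(self, cfg, base_case):
        pre, post = base_case.deterministic_arm_inputs()
        improved = replace(post, p_timely_bundle=pre.p_timely_bundle + 0.5)
        linked = evaluate_arm(
            improved, cfg.schedule, cfg.econ, "post",
            mode="bundle_linked", pre_inputs=pre,
        )
        observed_pre = evaluate_arm(pre, cfg.schedule, cfg.econ, "pre")
        assert linked.death_rate < observed_pre.death_rate

    def test_program_cost_charged_to_post_government_ledger(self, cfg, base_case):
        pre, _ = base_case.deterministic_arm_inputs()
        with_program = evaluate_arm(
            pre, cfg.schedule, cfg.econ, "post", program_cost_child=0.05
        )
        without = evaluate_arm(pre, cfg.schedule, cfg.econ, "pre", program_cost_child=0.05)
        diff = with_program.expected_cost["government"] - without.expected_cost["government"]
        assert diff == pytest.approx(0.05)
        assert with_program.expected_cost["patient"] == pytest.approx(
            without.expected_cost["patient"]
        )


class TestIncrementalResults:
    def test_published_ratio_identities(self):
        # The reported average ICERs equal dC/dE of the reported incrementals.
        def icer(dc, de):
            pre = ArmResult("pre", {"government": 0, "patient": 0, "societal": 0}, de / 1000, 0, 0)
            post = ArmResult("post", {"government": dc / 1000, "patient": dc / 1000, "societal": dc / 1000}, 0.0, 0, 0)
            return incremental_results(pre, post).icer["societal"]

        assert round(icer(-1321.86, 86.3), 2) == -15.32
        assert round(icer(5.34, 86.3), 2) == 0.06
        assert round(icer(-1319.33, 86.4), 2) == -15.27

    def test_identical_arms_flagged_undefined(self, arm_results):
        inc = incremental_results(arm_results["pre"], arm_results["pre"])
        assert not inc.icer_defined
        assert np.isnan(inc.icer["societal"])
        assert inc.delta_cost["societal"] == 0.0

    def test_cost_saving_and_effective_has_negative_icer(self, arm_results):
        inc = incremental_results(arm_results["pre"], arm_results["post"])
        assert inc.delta_yll_averted > 0
        assert inc.delta_cost["societal"] < 0
        assert inc.icer["societal"] < 0

    def test_scaling_per_1000_children(self, arm_results):
        inc = incremental_results(arm_results["pre"], arm_results["post"])
        per_child = (
            arm_results["pre"].expected_yll - arm_results["post"].expected_yll
        )
        assert inc.delta_yll_averted == pytest.approx(1000 * per_child)
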