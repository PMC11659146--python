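"""Cohort trace construction and cost/QALY accrual."""

import numpy as np
import pytest

from hcc_cea.engine import (
    MODES,
    ArmScenario,
    accrue,
    arm_scenario,
    build_trace,
    per_cycle_drug_cost,
    run_base_case,
    run_strategy,
)
from hcc_cea.params import ModelSettings, SurvivalParams
from hcc_cea.survival import restricted_mean


def _zero_scenario(**overrides) -> ArmScenario:
    base = dict(
        arm="combination", drug_cost_per_cycle=0.0, follow_up_cost=0.0,
        subsequent_cost=0.0, bsc_cost=0.0, p_subsequent=0.0, ae_cost=0.0,
        ae_disutility=0.0, u_pfs=1.0, u_pd=1.0, annual_discount_rate=0.0,
    )
    base.update(overrides)
    return ArmScenario(**base)


@pytest.mark.parametrize("mode", MODES)
@pytest.mark.parametrize("arm", ["combination", "sorafenib"])
class TestTraceInvariants:
    def test_cohort_starts_progression_free(self, bundle, arm, mode):
        tr = build_trace(bundle.strategies[arm], bundle.settings, mode)
        assert (tr.occ_pfs[0], tr.occ_pd[0], tr.occ_dead[0]) == (1.0, 0.0, 0.0)

    def test_occupancy_conservation_and_death_monotone(self, bundle, arm, mode):
        tr = build_trace(bundle.strategies[arm], bundle.settings, mode)
        total = tr.occ_pfs + tr.occ_pd + tr.occ_dead
        np.testing.assert_allclose(total, 1.0, atol=1e-9)
        assert np.all((tr.occ_pfs >= 0) & (tr.occ_pfs <= 1))
        assert np.all((tr.occ_pd >= 0) & (tr.occ_pd <= 1))
        assert np.all(np.diff(tr.occ_dead) >= -1e-15)


def test_partitioned_death_occupancy_tracks_os_curve(bundle):
    tr = build_trace(bundle.strategies["combination"], bundle.settings)
    # S_OS(12) = 0.743 for the combination arm, so 25.7% have died by cycle 12
    assert tr.occ_dead[12] == pytest.approx(1 - 0.743, abs=5e-4)


def test_modes_agree_on_totals_within_two_percent(bundle):
    for arm in bundle.strategies:
        part = run_strategy(bundle, arm, "partitioned_survival")
        markov = run_strategy(bundle, arm, "state_transition")
        assert markov.total_cost == pytest.approx(part.total_cost, rel=0.02)
        assert markov.total_qalys == pytest.approx(part.total_qalys, rel=0.02)


def test_unknown_mode_rejected(bundle):
    with pytest.raises(ValueError, match="unknown mode"):
        build_trace(bundle.strategies["sorafenib"], bundle.settings, "microsim")


class TestDrugCost:
    def test_combination_dosing_arithmetic(self, bundle):
        costs = {k: v.value for k, v in bundle.costs.items()}
        # 2 camrelizumab doses + daily rivoceranib over 30.4375 days
        assert per_cycle_drug_cost("combination", costs, bundle.settings) == \
            pytest.approx(2 * 438.19 + 30.4375 * 15.67, abs=1e-9)
        assert per_cycle_drug_cost("combination", costs, bundle.settings) == \
            pytest.approx(1353.34, abs=0.05)

    def test_sorafenib_dosing_arithmetic(self, bundle):
        costs = {k: v.value for k, v in bundle.costs.items()}
        assert per_cycle_drug_cost("sorafenib", costs, bundle.settings) == \
            pytest.approx(1626.58, abs=0.01)
        short = ModelSettings(days_per_cycle=28.0)
        assert per_cycle_drug_cost("sorafenib", costs, short) == \
            pytest.approx(1496.32, abs=0.01)

    def test_unknown_arm_rejected(self, bundle):
        with pytest.raises(ValueError, match="unknown arm"):
            per_cycle_drug_cost("lenvatinib", {}, bundle.settings)


class TestAccrual:
    def test_immortal_undiscounted_cohort_accrues_one_qaly_per_year(self):
        strat_params = SurvivalParams(gamma=1.0, lam=1e-12)
        settings = ModelSettings(horizon_cycles=12, annual_discount_rate=0.0)
        from hcc_cea.params import StrategyDef

        strat = StrategyDef(
            os=strat_params, pfs=strat_params, p_subsequent_therapy=0.0,
            subsequent_mix={"lenvatinib": 1.0}, adverse_events={},
        )
        tr = build_trace(strat, settings)
        out = accrue(tr, _zero_scenario(), settings)
        assert out.total_qalys == pytest.approx(1.0, abs=1e-9)
        assert out.total_cost == 0.0

    def test_annual_discount_convention(self):
        """The increment one year in is discounted by exactly 1/1.03."""
        strat_params = SurvivalParams(gamma=1.0, lam=1e-12)
        settings = ModelSettings(horizon_cycles=24)
        from hcc_cea.params import StrategyDef

        strat = StrategyDef(
            os=strat_params, pfs=strat_params, p_subsequent_therapy=0.0,
            subsequent_mix={"lenvatinib": 1.0}, adverse_events={},
        )
        tr = build_trace(strat, settings)
        out = accrue(tr, _zero_scenario(annual_discount_rate=0.03), settings)
        inc = out.trace.disc_qaly_increment
        assert inc[12] / inc[0] == pytest.approx(1 / 1.03, rel=1e-9)
        assert 1 / 1.03 == pytest.approx(0.97087, abs=5e-6)

    def test_breakdown_sums_to_total(self, base_outcomes):
        for out in base_outcomes.values():
            assert sum(out.cost_breakdown.values()) == \
                pytest.approx(out.total_cost, abs=1e-6)
            assert np.sum(out.trace.disc_cost_increment) == \
                pytest.approx(out.total_cost, abs=1e-6)
            assert np.sum(out.trace.disc_qaly_increment) == \
                pytest.approx(out.total_qalys, abs=1e-12)

    def test_combination_gains_more_qalys_and_costs_more(self, base_outcomes):
        combo, sor = base_outcomes["combination"], base_outcomes["sorafenib"]
        assert combo.total_qalys > sor.total_qalys
        assert combo.total_cost > sor.total_cost

    def test_discounting_monotonicity(self, bundle):
        for arm in bundle.strategies:
            lo = run_strategy(bundle, arm,
                              scenario=arm_scenario(bundle, arm, annual_discount_rate=0.0))
            hi = run_strategy(bundle, arm,
                              scenario=arm_scenario(bundle, arm, annual_discount_rate=0.05))
            assert hi.total_cost < lo.total_cost
            assert hi.total_qalys < lo.total_qalys

    def test_equal_utilities_reduce_to_discounted_mean_survival(self, bundle):
        """With u_pd = u_pfs = u and no AE disutility, total QALYs equal
        u * (discounted restricted mean OS) / 12."""
        b = bundle.model_copy(deep=True)
        b.settings.half_cycle_correction = True  # accrual becomes the trapezoid rule
        arm = "sorafenib"
        sc = arm_scenario(b, arm, utilities={"progressed": 0.76},
                          disutilities={k: 0.0 for k in b.disutilities})
        out = run_strategy(b, arm, scenario=sc)
        rm = restricted_mean(
            b.strategies[arm].os, 120.0, refine=1, annual_discount_rate=0.03
        )
        assert out.total_qalys == pytest.approx(0.76 * rm / 12.0, rel=1e-3)

    def test_zero_ae_incidence_removes_exactly_the_ae_component(self, bundle):
        arm = "combination"
        base = run_strategy(bundle, arm)
        sc = arm_scenario(
            bundle, arm,
            incidences={k: 0.0 for k in bundle.strategies[arm].adverse_events},
        )
        no_ae = run_strategy(bundle, arm, scenario=sc)
        assert no_ae.cost_breakdown["adverse_events"] == 0.0
        assert base.total_cost - no_ae.total_cost == \
            pytest.approx(base.cost_breakdown["adverse_events"], abs=1e-9)
        assert no_ae.total_qalys > base.total_qalys  # disutility gone too

    def test_half_cycle_correction_shrinks_totals_slightly(self, bundle):
        b = bundle.model_copy(deep=True)
        b.settings.half_cycle_correction = True
        for arm in bundle.strategies:
            plain = run_strategy(bundle, arm)
            hcc = run_strategy(b, arm)
            assert hcc.total_qalys < plain.total_qalys
            assert hcc.total_qalys == pytest.approx(plain.total_qalys, rel=0.05)

    def test_finite_subsequent_duration_caps_second_line_cost(self, bundle):
        def sub_cost(dur):
            b = bundle.model_copy(deep=True)
            b.settings.subsequent_duration_cycles = dur
            return run_strategy(b, "sorafenib").cost_breakdown["subsequent_therapy"]

        until_death = run_strategy(bundle, "sorafenib").cost_breakdown["subsequent_therapy"]
        assert sub_cost(6) < sub_cost(24) < until_death
        # and supportive care picks up the remainder: totals stay ordered
        b6 = bundle.model_copy(deep=True)
        b6.settings.subsequent_duration_cycles = 6
        assert run_strategy(b6, "sorafenib").total_cost < \
            run_strategy(bundle, "sorafenib").total_cost


def test_base_case_runs_both_arms(bundle):
    outs = run_base_case(bundle)
    assert set(outs) == {"combination", "sorafenib"}
    for out in outs.values():
        assert out.total_cost > 0 and 0 < out.total_qalys < 10
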