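"""Cost/effect accrual, GPAP truncation, ICER and NMHB behaviour."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nsclc_cea.economics import (
    Comparison,
    DOMINANT,
    accrue_costs,
    compare,
    discount_factor,
    evaluate_comparison,
    evaluate_strategy,
    gpap_paid_weights,
    nmhb,
    sae_cost_per_cycle,
)
from nsclc_cea.markov import ArmSpec, run_arm
from nsclc_cea.parameters import DAYS_PER_YEAR


def zero_costs(params, keep=()):
    """Copy of the registry with every cost parameter zeroed except `keep`."""
    values = {p.name: 0.0 for p in params.iter_params()
              if p.name.startswith("cost_") and p.name not in keep}
    return params.with_values(values)


class TestDiscounting:
    def test_no_elapsed_time(self):
        assert discount_factor(0, 0.03, 21.0) == 1.0

    def test_zero_rate(self):
        assert discount_factor(123, 0.0, 21.0) == 1.0

    def test_one_year_at_three_percent(self):
        one_year_cycles = DAYS_PER_YEAR / 21.0
        assert discount_factor(one_year_cycles, 0.03, 21.0) == pytest.approx(
            1.0 / 1.03, rel=1e-12
        )

    def test_zero_rate_makes_discounted_equal_undiscounted(self, params):
        res = evaluate_strategy("control", replace(params, discount_annual=0.0))
        assert res.pf_ly == pytest.approx(res.pf_ly_discounted, rel=1e-12)
        assert res.ly == pytest.approx(res.ly_discounted, rel=1e-12)


class TestSaeCost:
    def test_gefitinib_arm_formula(self, params):
        assert sae_cost_per_cycle(0.07, params) == pytest.approx(44.3975)

    def test_control_arm_formula(self, params):
        assert sae_cost_per_cycle(0.03, params) == pytest.approx(19.0275)

    def test_no_events_no_cost(self, params):
        assert sae_cost_per_cycle(0.0, params) == 0.0

    def test_zero_platinum_probability_rejected(self, params):
        bad = replace(params, p_sae_platinum=params.p_sae_platinum.__class__(
            "p_sae_platinum", 0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            sae_cost_per_cycle(0.07, bad)


class TestEffects:
    def test_unit_utilities_make_qaly_equal_discounted_ly(self, params):
        mp = params.with_values({"utility_pfs": 1.0, "utility_pd": 1.0})
        res = evaluate_strategy("control", mp)
        assert res.qaly == pytest.approx(res.ly_discounted, rel=1e-12)

    def test_pf_ly_bounded_by_ly_and_qaly_by_ly(self, params):
        for strategy in ("control", "gefitinib"):
            res = evaluate_strategy(strategy, params)
            assert res.pf_ly <= res.ly
            assert res.qaly <= res.ly

    def test_raising_pfs_utility_raises_qalys(self, params):
        lo = evaluate_strategy("control", params.with_value("utility_pfs", 0.5))
        hi = evaluate_strategy("control", params.with_value("utility_pfs", 0.8))
        assert hi.qaly > lo.qaly
        assert hi.ly == lo.ly  # utilities do not move survival


class TestCosts:
    def test_components_sum_to_total(self, params):
        arm = ArmSpec("gef", params.pfs_control, receives_gefitinib=True, genotyped=True)
        trace = run_arm(arm, params)
        comp = accrue_costs(trace, arm, params)
        parts = [v for k, v in comp.items() if k != "total"]
        assert comp["total"] == pytest.approx(sum(parts), rel=1e-12)

    def test_end_of_life_isolation(self, params):
        """With every other cost zeroed, cost is EoL times discounted deaths."""
        mp = zero_costs(params, keep=("cost_endoflife",))
        arm = ArmSpec("ctrl", mp.pfs_control)
        trace = run_arm(arm, mp)
        comp = accrue_costs(trace, arm, mp)
        cycles = np.arange(trace.n_cycles + 1)
        df = discount_factor(cycles, mp.discount_annual, mp.cycle_days)
        expected = float(np.sum(df * trace.new_deaths)) * mp.cost_endoflife.base
        assert comp["total"] == pytest.approx(expected, rel=1e-12)
        assert comp["sae"] == 0.0  # sae scales with the zeroed platinum cycle cost

    def test_gefitinib_drug_cost_only_on_treated_arm(self, params):
        trace_arm = ArmSpec("ctrl", params.pfs_control)
        comp = accrue_costs(run_arm(trace_arm, params), trace_arm, params)
        assert comp["gefitinib"] == 0.0
        assert comp["genotyping"] == 0.0

    def test_per_cycle_drug_price(self, params):
        # 21 days at $77.8 per 250 mg dose
        assert params.cycle_days * params.cost_gefitinib_250mg.base == pytest.approx(
            1633.8
        )

    @pytest.mark.parametrize("name", ["cost_gefitinib_250mg", "cost_endoflife",
                                      "cost_secondline_cycle", "cost_supportive_cycle"])
    def test_raising_any_cost_weakly_raises_total(self, params, name):
        lo = evaluate_strategy("gefitinib", params)
        hi = evaluate_strategy("gefitinib", params.with_value(
            name, params.get(name).base * 1.5))
        assert hi.cost >= lo.cost - 1e-9

    def test_secondline_capped_at_four_cycles(self, params):
        """Zeroing all but chemo: cost bounded by 4 cycles per progressor."""
        mp = zero_costs(params, keep=("cost_secondline_cycle",))
        mp = replace(mp, discount_annual=0.0)
        arm = ArmSpec("ctrl", mp.pfs_control)
        trace = run_arm(arm, mp)
        comp = accrue_costs(trace, arm, mp)
        max_chemo = (mp.p_secondline.base * 4 * mp.cost_secondline_cycle.base)
        assert 0.0 < comp["total"] <= max_chemo + 1e-9


class TestGpap:
    def test_paid_window_is_six_months_prorated(self, params):
        w = gpap_paid_weights(replace(params, gpap_enabled=True))
        paid_cycles = 6.0 * (DAYS_PER_YEAR / 12.0) / 21.0  # 8.696
        assert np.all(w[1:8 + 1] == 1.0)
        assert w[9] == pytest.approx(paid_cycles - 8.0)
        assert np.all(w[10:] == 0.0)

    def test_gpap_never_increases_cost(self, params):
        full = evaluate_strategy("gefitinib", replace(params, gpap_enabled=False))
        gpap = evaluate_strategy("gefitinib", replace(params, gpap_enabled=True))
        assert gpap.cost < full.cost
        assert gpap.qaly == full.qaly  # assistance changes who pays, not outcomes

    def test_gpap_equals_full_price_when_exposure_short(self, params):
        # horizon shorter than the paid window: nothing is donated
        mp = replace(params, horizon_years=8 * 21.0 / 365.25)
        full = evaluate_strategy("gefitinib", replace(mp, gpap_enabled=False))
        gpap = evaluate_strategy("gefitinib", replace(mp, gpap_enabled=True))
        assert gpap.cost == pytest.approx(full.cost, rel=1e-12)


class TestComparison:
    def test_base_case_deltas_positive(self, params):
        _, _, cmp_ = evaluate_comparison(params)
        assert cmp_.delta_cost > 0
        assert cmp_.delta_qaly > 0
        assert cmp_.icer_per_qaly == pytest.approx(
            cmp_.delta_cost / cmp_.delta_qaly, rel=1e-12
        )

    def test_rounded_published_deltas_divide_consistently(self):
        # the printed deltas: 26,149.9 / 0.46 QALYs
        assert 26149.9 / 0.46 == pytest.approx(56847.6, abs=0.1)

    def test_free_benefit_gives_zero_icer(self):
        a = _result(cost=100.0, qaly=1.0)
        b = _result(cost=100.0, qaly=1.1)
        assert compare(a, b).icer_per_qaly == 0.0

    def test_dominance_flag(self):
        a = _result(cost=200.0, qaly=1.0)
        b = _result(cost=100.0, qaly=1.1)
        assert compare(a, b).dominance == DOMINANT

    def test_zero_delta_effectiveness_flagged_undefined(self):
        a = _result(cost=100.0, qaly=1.0)
        b = _result(cost=200.0, qaly=1.0)
        cmp_ = compare(a, b)
        assert cmp_.icer_per_qaly is None


class TestNmhb:
    def test_arithmetic(self):
        cmp_ = Comparison(7178.2, 0.46, 0.74, None, None)
        assert nmhb(16349.1, cmp_) == pytest.approx(16349.1 * 0.46 - 7178.2)

    def test_zero_wtp_is_negative_delta_cost(self):
        cmp_ = Comparison(500.0, 0.3, 0.3, None, None)
        assert nmhb(0.0, cmp_) == -500.0

    def test_strictly_increasing_in_wtp_for_positive_delta_qaly(self):
        cmp_ = Comparison(500.0, 0.3, 0.3, None, None)
        values = [nmhb(w, cmp_) for w in np.linspace(0, 1e5, 11)]
        assert np.all(np.diff(values) > 0)


def _result(cost, qaly):
    from nsclc_cea.economics import StrategyResult

    return StrategyResult("x", cost, qaly, max(qaly, 1.0) + 1.0, qaly,
                          qaly, max(qaly, 1.0) + 1.0, {})
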