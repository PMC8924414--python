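"""Cohort engine: traces, discounting, accumulation, ICER, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from markovce import (CEResults, CohortTrace, CostEffectivenessModel,
                      CostInputs, EconResult, ModelConfig, TransitionMatrix,
                      UtilitySet, ValidationError, accumulate, build_trace,
                      compute_icer, discount_factor, run_scenario)
from markovce.model import round2

from conftest import brute_force_econ, random_matrix

NO_DISCOUNT = ModelConfig(horizon=2, annual_discount_rate=0.0)


def matrices(low=0.0, high=1.0):
    return st.builds(
        lambda a, b, w: TransitionMatrix(a, (1 - a) * w, (1 - a) * (1 - w), b, 1 - b),
        a=st.floats(low, high), b=st.floats(low, high), w=st.floats(0, 1))


class TestTrace:
    def test_absorbing_pfs_stays_put(self):
        m = TransitionMatrix(1.0, 0.0, 0.0, 0.5, 0.5)
        trace = build_trace(m, ModelConfig(horizon=10))
        assert np.allclose(trace.occupancy[:, 0], 1.0)

    def test_total_population_first_cycles(self, total_pembro):
        matrix, _, _, config = total_pembro
        occ = build_trace(matrix, config).occupancy
        assert occ[0] == pytest.approx((1.0, 0.0, 0.0))
        assert occ[1] == pytest.approx((0.781, 0.130, 0.089))
        # hand matrix multiplication: PD(2) = 0.130*0.900 + 0.781*0.130
        assert occ[2][1] == pytest.approx(0.21853)

    def test_malformed_occupancy_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            CohortTrace(np.array([[1.0, 0.0, 0.0], [0.6, 0.3, 0.2]]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(matrices())
    def test_conservation_and_death_monotonicity(self, m):
        occ = build_trace(m, ModelConfig(horizon=24)).occupancy
        assert np.allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(occ[:, 2]) >= -1e-12)


class TestDiscounting:
    def test_cycle_zero_undiscounted(self):
        assert discount_factor(0, ModelConfig()) == 1.0

    def test_zero_rate_never_discounts(self):
        cfg = ModelConfig(annual_discount_rate=0.0)
        assert all(discount_factor(t, cfg) == 1.0 for t in (0, 5, 59))

    def test_one_year_geometric_compounding(self):
        assert discount_factor(12, ModelConfig()) == pytest.approx(1 / 1.03)

    def test_simple_compounding_selectable(self):
        cfg = ModelConfig(discount_compounding="simple")
        assert cfg.monthly_discount_rate == 0.03 / 12
        with pytest.raises(ValidationError):
            ModelConfig(discount_compounding="quarterly")


class TestAccumulate:
    def test_zero_rewards_zero_result(self, total_pembro):
        matrix, _, _, config = total_pembro
        trace = build_trace(matrix, config)
        econ = accumulate(trace, CostInputs(0, 0, 0, 0),
                          UtilitySet(0.0, 0.0), config)
        assert econ.cost_total == 0.0 and econ.qaly_total == 0.0

    def test_two_cycle_toy_half_cycle_trapezoid(self):
        # stay-in-PFS 0.5, PFS cost 100/cycle, no discounting:
        # 100*(1+0.5)/2 + 100*(0.5+0.25)/2 = 112.5
        m = TransitionMatrix(0.5, 0.0, 0.5, 1.0, 0.0)
        trace = build_trace(m, NO_DISCOUNT)
        econ = accumulate(trace, CostInputs(100.0, 0.0, 0.0, 0.0),
                          UtilitySet(0.0, 0.0), NO_DISCOUNT)
        assert econ.cost_total == pytest.approx(112.5)

    def test_mismatched_horizon_rejected(self, total_pembro):
        matrix, costs, utilities, config = total_pembro
        trace = build_trace(matrix, ModelConfig(horizon=12))
        with pytest.raises(ValidationError, match="horizon"):
            accumulate(trace, costs, utilities, config)

    def test_total_population_pembrolizumab_total_cost(self, total_pembro):
        matrix, costs, utilities, config = total_pembro
        econ = accumulate(build_trace(matrix, config), costs, utilities, config)
        assert econ.cost_total == pytest.approx(34272.16, rel=0.01)
        assert econ.cost_total == pytest.approx(econ.cost_pfs + econ.cost_pd)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(matrices(), st.booleans(),
           st.floats(0, 5000), st.floats(0, 5000), st.floats(0, 1))
    def test_matches_brute_force_path_enumeration(self, m, hcc, pfs_cost, pd_cost, u):
        """Engine totals equal the path-probability-weighted enumeration."""
        cfg = ModelConfig(horizon=4, half_cycle_correction=hcc)
        utilities = UtilitySet(u, u * 0.8)
        econ = accumulate(build_trace(m, cfg), CostInputs(pfs_cost, 0, 0, pd_cost),
                          utilities, cfg)
        cost, qaly = brute_force_econ(m, pfs_cost, pd_cost, u, u * 0.8, cfg)
        assert econ.cost_total == pytest.approx(cost, abs=1e-9 * max(1, cost))
        assert econ.qaly_total == pytest.approx(qaly, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(matrices(), st.floats(0.0, 0.2))
    def test_discounting_never_increases_totals(self, m, rate):
        cfg0 = ModelConfig(horizon=24, annual_discount_rate=0.0)
        cfg = ModelConfig(horizon=24, annual_discount_rate=rate)
        costs = CostInputs(100.0, 0.0, 0.0, 50.0)
        utilities = UtilitySet()
        undisc = accumulate(build_trace(m, cfg0), costs, utilities, cfg0)
        disc = accumulate(build_trace(m, cfg), costs, utilities, cfg)
        assert disc.cost_total <= undisc.cost_total + 1e-9
        if rate == 0.0:
            assert disc.cost_total == pytest.approx(undisc.cost_total)


class TestICER:
    def test_direct_ratio(self):
        i = EconResult(100.0, 0.0, 0.25, 0.25)
        c = EconResult(0.0, 0.0, 0.0, 0.0)
        res = compute_icer(i, c)
        assert res.icer == pytest.approx(200.0)
        assert res.dominance == "none"

    def test_dominance_flags(self):
        cheap_effective = EconResult(10.0, 0.0, 0.5, 0.5)
        dear_ineffective = EconResult(100.0, 0.0, 0.1, 0.1)
        res = compute_icer(cheap_effective, dear_ineffective)
        assert res.dominance == "intervention_dominates" and res.icer is None
        res = compute_icer(dear_ineffective, cheap_effective)
        assert res.dominance == "intervention_dominated" and res.icer is None

    def test_zero_qaly_delta_flagged_not_divided(self):
        i = EconResult(100.0, 0.0, 0.2, 0.2)
        c = EconResult(50.0, 0.0, 0.2, 0.2)
        res = compute_icer(i, c)
        assert res.dominance == "undefined" and res.icer is None

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 100.0))
    def test_icer_scales_with_currency(self, k):
        """Rescaling every cost by k rescales the ICER by exactly k."""
        model = CostEffectivenessModel.from_subgroup("cps10")
        base = model.fit().comparison
        scaled = model.with_overrides(
            {name: k for name in ("drug_cost_pembrolizumab", "drug_cost_chemotherapy",
                                  "test_cost_pembrolizumab", "test_cost_chemotherapy",
                                  "ae_cost_pembrolizumab", "ae_cost_chemotherapy",
                                  "subsequent_therapy_cost")}).fit().comparison
        assert scaled.icer == pytest.approx(base.icer * k, rel=1e-12)


class TestScenario:
    def test_identity_override_is_base_case(self):
        base = run_scenario("cps10")
        same = run_scenario("cps10", {"drug_cost_pembrolizumab": 1.0})
        assert same.icer == pytest.approx(base.icer, rel=1e-14)

    def test_unknown_parameter_lists_valid_names(self):
        with pytest.raises(ValidationError, match="drug_cost_pembrolizumab"):
            run_scenario("cps10", {"pembro_price": 0.5})

    def test_halved_drug_cost_reduces_icer(self):
        base = run_scenario("cps10")
        half = run_scenario("cps10", {"drug_cost_pembrolizumab": 0.5})
        assert half.icer < base.icer
        assert half.delta_qaly == pytest.approx(base.delta_qaly)  # QALYs untouched


class TestResultsAPI:
    def test_summary_and_table_layout(self):
        res = CostEffectivenessModel.from_subgroup("total").fit()
        table = res.table()
        assert list(table.columns) == ["pembrolizumab", "chemotherapy"]
        assert table.loc["cost_total", "pembrolizumab"] == pytest.approx(
            table.loc["cost_pfs", "pembrolizumab"] + table.loc["cost_pd", "pembrolizumab"])
        text = res.summary()
        assert "half-cycle correction on" in text and "icer" in text

    def test_trace_frame_has_both_arms(self):
        res = CostEffectivenessModel.from_subgroup("total").fit()
        frame = res.trace_frame()
        assert frame.shape == (61, 6)
        assert frame.iloc[0]["pembrolizumab_PFS"] == 1.0

    def test_report_rounding_half_up(self):
        assert round2(1.005) == 1.01
        assert round2(2.674999) == 2.67
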