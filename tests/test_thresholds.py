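"""WTP benchmarks, parity thresholds, scenario matrix, surface, frontier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutricea import (
    MALNOURISHED_STRATA,
    EconParams,
    InterventionEffect,
    QuarterTransition,
    apply_effect,
    cost_per_daly,
    derive_transitions,
    max_supplement_cost,
    parity_frontier,
    retention_surface,
    run_cohort_model,
    scenario_table,
    willingness_to_pay,
)


class TestApplyEffect:
    def test_twenty_percent_reduction_arithmetic(self):
        t = QuarterTransition(0.716, 0.173, 0.111)
        (adj,) = apply_effect((t,), InterventionEffect(0.2, 0.2))
        assert adj.as_tuple() == pytest.approx((0.7728, 0.1384, 0.0888), abs=1e-12)

    def test_zero_effect_is_identity(self, severe):
        ts = derive_transitions(severe)[:2]
        for adj, t in zip(apply_effect(ts, InterventionEffect(0, 0)), ts):
            # survival is reconstructed as the complement, so identity
            # holds to the last ulp rather than bit-exactly
            assert adj.as_tuple() == pytest.approx(t.as_tuple(), abs=1e-15)

    def test_perfect_intervention_removes_all_events(self, severe):
        for adj in apply_effect(derive_transitions(severe)[:2],
                                InterventionEffect(1, 1)):
            assert adj.as_tuple() == (1.0, 0.0, 0.0)

    @given(r_mort=st.floats(0, 1), r_ltfu=st.floats(0, 1),
           p_dead=st.floats(0, 0.5), p_ltfu=st.floats(0, 0.5))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_triple_is_a_distribution(self, r_mort, r_ltfu, p_dead, p_ltfu):
        t = QuarterTransition(1 - p_dead - p_ltfu, p_dead, p_ltfu)
        (adj,) = apply_effect((t,), InterventionEffect(r_mort, r_ltfu))
        assert adj.p_alive >= t.p_alive - 1e-12
        assert sum(adj.as_tuple()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_reductions_rejected(self):
        with pytest.raises(ValueError):
            InterventionEffect(1.2, 0)
        with pytest.raises(ValueError):
            InterventionEffect(0, -0.1)


class TestWillingnessToPay:
    @pytest.mark.parametrize(
        "stratum, published",
        [("<16.0", 853.31), ("16.00-16.99", 847.53), ("17.00-18.49", 845.87)],
    )
    def test_published_benchmarks(self, tables, econ, stratum, published):
        wtp = willingness_to_pay(tables[stratum], econ).wtp
        assert wtp == pytest.approx(published, rel=0.005)

    def test_engineered_round_number(self, severe):
        # under certain survival, cost/DALY = lifetime / dalys exactly
        table = type(severe)(
            "sure", tuple(type(q)(i, 10, 10, 0, 0)
                          for i, q in enumerate(severe.quarters[:2], 1)))
        econ = EconParams(annual_art_cost=556,
                          lifetime_cost_per_survivor=7300.0,
                          dalys_per_survivor=7.3)
        assert willingness_to_pay(table, econ).wtp == pytest.approx(1000.0)

    def test_ordering_tracks_early_mortality(self, tables, econ):
        # the severe stratum wastes the most early ART spend on
        # non-survivors, so its cost per DALY averted is highest
        wtps = [willingness_to_pay(tables[s], econ).wtp
                for s in MALNOURISHED_STRATA]
        assert wtps[0] > wtps[1] > wtps[2]


class TestMaxSupplementCost:
    @pytest.mark.parametrize(
        "stratum, r, published",
        [
            ("<16.0", (0.2, 0.2), 10.99),
            ("<16.0", (0.2, 0.0), 5.49),
            ("<16.0", (0.0, 0.2), 5.48),
            ("<16.0", (0.5, 0.5), 27.48),
            ("16.00-16.99", (0.2, 0.2), 6.86),
            ("16.00-16.99", (0.5, 0.5), 17.20),
            ("17.00-18.49", (0.5, 0.5), 13.01),
        ],
    )
    def test_published_thresholds(self, tables, econ, stratum, r, published):
        s_star = max_supplement_cost(tables[stratum], econ, *r)
        assert s_star == pytest.approx(published, rel=0.03)

    def test_zero_effect_admits_zero_spend(self, tables, econ):
        for s in MALNOURISHED_STRATA:
            assert max_supplement_cost(tables[s], econ, 0, 0) == pytest.approx(
                0.0, abs=1e-9
            )

    def test_inverse_consistency(self, tables, econ):
        # plugging S* back as a per-entry supplement cost must return the
        # combined program to the stratum WTP exactly
        for stratum in MALNOURISHED_STRATA:
            table = tables[stratum]
            wtp = willingness_to_pay(table, econ).wtp
            for r in ((0.2, 0.2), (0.5, 0.1), (0.05, 0.4)):
                s_star = max_supplement_cost(table, econ, *r)
                adj = run_cohort_model(
                    apply_effect(derive_transitions(table)[:2],
                                 InterventionEffect(*r)), econ)
                achieved = cost_per_daly(adj, s_star * adj.supplement_exposure)
                assert achieved == pytest.approx(wtp, rel=1e-9)

    @given(r=st.tuples(st.floats(0, 0.9), st.floats(0, 0.9)),
           bump=st.floats(0.001, 0.1))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_each_effect(self, tables, r, bump):
        econ = EconParams()
        table = tables["<16.0"]
        base = max_supplement_cost(table, econ, *r)
        assert max_supplement_cost(table, econ, r[0] + bump, r[1]) >= base - 1e-9
        assert max_supplement_cost(table, econ, r[0], r[1] + bump) >= base - 1e-9

    def test_symmetric_effects_near_equal_in_severe_stratum(self, severe, econ):
        mort_only = max_supplement_cost(severe, econ, 0.2, 0.0)
        ltfu_only = max_supplement_cost(severe, econ, 0.0, 0.2)
        assert abs(mort_only - ltfu_only) < 0.10


class TestScenarioTable:
    def test_shape_and_published_scenarios(self, tables, econ):
        m = scenario_table(tables, econ)
        assert list(m.columns) == list(MALNOURISHED_STRATA)
        assert list(m.index) == [(0.2, 0.0), (0.0, 0.2), (0.2, 0.2), (0.5, 0.5)]

    def test_consistent_with_pointwise_solver(self, tables, econ):
        m = scenario_table(tables, econ)
        assert m.loc[(0.2, 0.2), "<16.0"] == pytest.approx(
            max_supplement_cost(tables["<16.0"], econ, 0.2, 0.2))

    def test_missing_stratum_raises(self, tables, econ):
        subset = {"<16.0": tables["<16.0"]}
        with pytest.raises(KeyError, match="16.00-16.99"):
            scenario_table(subset, econ)


class TestRetentionSurface:
    def test_origin_is_historical_retention(self, severe):
        surf = retention_surface(severe, [0.0], [0.0])
        assert surf.pct_alive[0] == pytest.approx(100 * 0.716 * 0.858)

    @pytest.mark.parametrize(
        "stratum, gain", [("<16.0", 18), ("17.00-18.49", 10)]
    )
    def test_published_gains_at_half_reductions(self, tables, stratum, gain):
        surf = retention_surface(tables[stratum], [0.0, 0.5], [0.0, 0.5])
        surf = surf.set_index(["r_mort", "r_ltfu"]).pct_alive
        delta = surf[(0.5, 0.5)] - surf[(0.0, 0.0)]
        assert round(delta) == gain

    def test_surface_monotone_in_both_effects(self, severe):
        grid = np.linspace(0, 0.5, 6)
        surf = retention_surface(severe, grid, grid).pivot(
            index="r_mort", columns="r_ltfu", values="pct_alive").to_numpy()
        assert (np.diff(surf, axis=0) >= -1e-12).all()
        assert (np.diff(surf, axis=1) >= -1e-12).all()


class TestParityFrontier:
    def test_frontier_passes_through_known_threshold(self, severe, econ):
        s_star = max_supplement_cost(severe, econ, 0.2, 0.2)
        front = parity_frontier(severe, econ, s_star, resolution=0.005)
        idx = (front.r_mort - 0.2).abs().idxmin()
        assert front.loc[idx, "r_mort"] == pytest.approx(0.2, abs=0.005)
        assert front.loc[idx, "r_ltfu"] == pytest.approx(0.2, abs=0.01)

    def test_zero_price_collapses_to_origin(self, severe, econ):
        front = parity_frontier(severe, econ, 0.0)
        assert len(front) == 1
        assert front.iloc[0].tolist() == [0.0, 0.0]

    def test_r_ltfu_decreasing_in_r_mort(self, severe, econ):
        front = parity_frontier(severe, econ, 10.0, resolution=0.02)
        assert len(front) > 3
        assert (np.diff(front.r_ltfu.to_numpy()) <= 1e-9).all()
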