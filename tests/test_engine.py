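"""Cohort engine: transition structure, propagation, rewards, oracles."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

import polypill_cea as pc
from polypill_cea.engine import base_values, run_cohort
from polypill_cea.lifetable import LifeTable
from polypill_cea.states import HealthState as S, N_STATES


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate,cycle,expected",
        [(0.03, 0, 1.0), (0.058, 1, 1 / 1.058), (0.03, 2, 1 / 1.0609)],
    )
    def test_values(self, rate, cycle, expected):
        assert pc.discount_factor(rate, cycle) == pytest.approx(expected, rel=1e-12)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            pc.discount_factor(-0.01, 1)


class TestInterpolateRisk:
    @pytest.mark.parametrize(
        "age,expected",
        [(35, 0.011), (60, 0.0525), (85, 0.094), (100, 0.094), (20, 0.011)],
    )
    def test_linear_with_clamping(self, age, expected):
        got = pc.interpolate_risk(age, 0.011, 0.094, 35, 85)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            pc.interpolate_risk(50, 0.5, 0.1, 35, 85)


class TestApplyRelativeEffect:
    def test_null_effect_is_identity(self):
        for p in (0.0, 0.005, 0.5, 0.99):
            assert pc.apply_relative_effect(p, 1.0) == pytest.approx(p, rel=1e-12)

    def test_polypill_stroke_reduction(self):
        got = pc.apply_relative_effect(0.005, 0.43)
        assert got == pytest.approx(0.0021531, abs=1e-7)

    def test_zero_risk_preserved(self):
        assert pc.apply_relative_effect(0.0, 0.43) == 0.0

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            pc.apply_relative_effect(1.0, 0.5)
        with pytest.raises(ValueError):
            pc.apply_relative_effect(0.5, -1.0)


class TestOtherCauseMortality:
    def test_smr_examples(self):
        lt = LifeTable(ages=np.array([35, 36]), qx=np.array([0.01, 1.0]))
        assert pc.other_cause_mortality(lt, 35, 1.0) == pytest.approx(0.01)
        assert pc.other_cause_mortality(lt, 35, 2.72) == pytest.approx(
            1 - 0.99**2.72, rel=1e-12
        )
        assert 1 - 0.99**2.72 == pytest.approx(0.02697, abs=1e-5)

    def test_high_qx_not_capped_prematurely(self):
        lt = LifeTable(ages=np.array([80, 81]), qx=np.array([0.6, 1.0]))
        got = pc.other_cause_mortality(lt, 80, 2.72)
        assert got == pytest.approx(1 - 0.4**2.72, rel=1e-12)
        assert got < 1.0

    def test_age_outside_table_rejected(self):
        lt = LifeTable(ages=np.array([35, 36]), qx=np.array([0.01, 1.0]))
        with pytest.raises(ValueError):
            pc.other_cause_mortality(lt, 50, 1.0)


class TestEventFatality:
    def test_stroke_and_hf_constant(self, base_params):
        from polypill_cea.engine import event_fatality

        assert event_fatality("stroke", 40, "male", base_params) == 0.19
        assert event_fatality("stroke", 80, "female", base_params) == 0.19
        assert event_fatality("hf", 50, "blend", base_params) == 0.17

    @pytest.mark.parametrize(
        "age,sex,expected",
        [(35, "male", 0.19), (60, "male", 0.275), (85, "male", 0.36),
         (35, "female", 0.23), (35, "blend", 0.21)],
    )
    def test_mi_fatality_age_sex(self, base_params, age, sex, expected):
        from polypill_cea.engine import event_fatality

        got = event_fatality("mi", age, sex, base_params)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_unknown_event_rejected(self, base_params):
        from polypill_cea.engine import event_fatality

        with pytest.raises(ValueError):
            event_fatality("angina", 40, "male", base_params)


class TestTransitionMatrix:
    @pytest.mark.parametrize("age", [35, 50, 70, 84, 99])
    def test_rows_sum_to_one_every_arm(self, base_params, base_strategies, age):
        for strat in base_strategies:
            m = pc.build_transition_matrix(age, strat, base_params)
            assert m.shape == (N_STATES, N_STATES)
            assert np.all(m >= 0) and np.all(m <= 1)
            np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-12)

    def test_structural_topology(self, base_params, base_strategies):
        m = pc.build_transition_matrix(60, base_strategies[0], base_params)
        # chronic states: self or dead only
        for state in (S.STROKE, S.HF, S.POST_MI, S.POST_ANGINA, S.PVD):
            others = [j for j in range(N_STATES) if j not in (state, S.DEAD)]
            assert np.all(m[state, others] == 0)
        # acute tunnels empty into their post state or dead
        assert m[S.ACUTE_MI, S.ACUTE_MI] == 0
        assert m[S.ACUTE_MI, S.POST_MI] > 0
        assert m[S.ACUTE_ANGINA, S.POST_ANGINA] > 0
        # dead is absorbing
        assert m[S.DEAD, S.DEAD] == 1.0 and np.all(m[S.DEAD, :S.DEAD] == 0)
        # no direct entry into post states from event-free
        assert m[S.EVENT_FREE, S.POST_MI] == 0
        assert m[S.EVENT_FREE, S.POST_ANGINA] == 0

    def test_polypill_stroke_entry_composition(self, base_params, base_strategies):
        poly = next(s for s in base_strategies if s.label == "polypill")
        m = pc.build_transition_matrix(35, poly, base_params)
        p_stroke = 1 - (1 - 0.005) ** 0.43
        assert m[S.EVENT_FREE, S.STROKE] == pytest.approx(
            p_stroke * (1 - 0.19), rel=1e-12
        )

    def test_identity_configuration(self, minimal_params):
        params = minimal_params(stroke_risk=0.02, fatal_stroke=0.0, qx=0.0)
        strat = pc.build_strategy_set(params)[0]
        m = pc.build_transition_matrix(36, strat, params)
        assert m[S.EVENT_FREE, S.STROKE] == pytest.approx(0.02, rel=1e-12)
        assert m[S.EVENT_FREE, S.DEAD] == 0.0
        assert m[S.EVENT_FREE, S.EVENT_FREE] == pytest.approx(0.98, rel=1e-12)

    def test_excessive_competing_risks_error_names_age(self, base_params):
        strat = pc.build_strategy_set(base_params)[0]
        values = base_values(base_params)
        values["risk.stroke"] = 0.95
        values["risk.angina.low"] = values["risk.angina.high"] = 0.9
        with pytest.raises(ValueError, match="age"):
            pc.run_cohort(base_params, strat, values=values)


class TestDegenerateChains:
    def test_single_alive_state_accrues_cycle_length(self, minimal_params):
        params = minimal_params(qx=0.0, max_age=45)  # 10 cycles, no deaths
        strat = pc.build_strategy_set(params)[0]
        res = pc.run_cohort(params, strat)
        assert res.qalys == pytest.approx(10.0, abs=1e-12)
        assert res.cost == pytest.approx(0.0, abs=1e-12)

    def test_two_state_geometric_series(self, minimal_params):
        # p(death) = 0.1/cycle, 3% QALY discount, start-of-cycle accrual
        params = minimal_params(
            qx=0.1, max_age=235, discount_qaly=0.03, half_cycle=False
        )
        strat = pc.build_strategy_set(params)[0]
        res = pc.run_cohort(params, strat, collect_trace=False)
        x = 0.9 / 1.03
        brute = sum(x**t for t in range(200))
        assert res.qalys == pytest.approx(brute, abs=1e-10)
        assert res.qalys == pytest.approx(1 / (1 - x), abs=1e-6)
        assert res.qalys == pytest.approx(7.9231, abs=1e-4)

    @pytest.mark.parametrize("half_cycle", [False, True])
    def test_three_state_brute_force_oracle(self, minimal_params, half_cycle):
        """Event-free / stroke / dead chain vs independent enumeration."""
        params = minimal_params(
            qx=0.05,
            max_age=55,
            stroke_risk=0.02,
            fatal_stroke=0.19,
            smr_stroke=2.72,
            stroke_cost=1215.5,
            stroke_utility=0.63,
            discount_cost=0.058,
            discount_qaly=0.03,
            half_cycle=half_cycle,
        )
        strat = pc.build_strategy_set(params)[0]
        res = pc.run_cohort(params, strat, collect_trace=False)

        # independent oracle: explicit 3-state matrix iterated cycle by cycle
        qx, p_s, f, smr = 0.05, 0.02, 0.19, 2.72
        m = np.array(
            [
                [1 - p_s - qx, p_s * (1 - f), p_s * f + qx],
                [0.0, (1 - qx) ** smr, 1 - (1 - qx) ** smr],
                [0.0, 0.0, 1.0],
            ]
        )
        util = np.array([1.0, 0.63, 0.0])
        cost = np.array([0.0, 1215.5, 0.0])
        x = np.array([1.0, 0.0, 0.0])
        total_c = total_q = 0.0
        for t in range(20):
            x_next = x @ m
            xr = 0.5 * (x + x_next) if half_cycle else x
            total_c += (xr @ cost) / 1.058**t
            total_q += (xr @ util) / 1.03**t
            x = x_next
        assert res.cost == pytest.approx(total_c, abs=1e-10)
        assert res.qalys == pytest.approx(total_q, abs=1e-10)


class TestCohortInvariants:
    def test_conservation_and_monotone_death(self, base_params, base_strategies):
        for strat in base_strategies:
            res = pc.run_cohort(base_params, strat)
            occ = res.trace.occupancy
            np.testing.assert_allclose(occ.sum(axis=-1), 1.0, atol=1e-12)
            dead = occ[:, S.DEAD]
            assert np.all(np.diff(dead) >= -1e-15)

    def test_qaly_bounds(self, base_params, base_strategies):
        strat = base_strategies[0]
        res = pc.run_cohort(base_params, strat, collect_trace=False)
        values = base_values(base_params)
        for key in list(values):
            if key.startswith("util."):
                values[key] = 1.0
        disc_ly = pc.run_cohort(
            base_params, strat, values=values, collect_trace=False
        ).qalys
        undisc = replace(
            base_params, settings=replace(base_params.settings, discount_qaly=0.0)
        )
        undisc_ly = pc.run_cohort(
            undisc, strat, values=values, collect_trace=False
        ).qalys
        assert res.qalys <= disc_ly <= undisc_ly

    def test_discount_rate_monotonicity(self, base_params, base_strategies):
        strat = base_strategies[0]
        costs, qalys = [], []
        for r in (0.0, 0.03, 0.058, 0.10):
            p = replace(
                base_params,
                settings=replace(
                    base_params.settings, discount_cost=r, discount_qaly=r
                ),
            )
            res = pc.run_cohort(p, strat, collect_trace=False)
            costs.append(res.cost)
            qalys.append(res.qalys)
        assert all(a > b for a, b in zip(costs, costs[1:]))
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_protective_effect_never_reduces_qalys(self, base_params):
        strat = next(
            s for s in pc.build_strategy_set(base_params) if s.label == "polypill"
        )
        base = base_values(base_params)
        for e in (1.0, 0.8, 0.5):
            base_e = dict(base)
            for event in ("stroke", "hf", "mi", "angina", "pvd"):
                base_e[f"eff.polypill.{event}"] = e
            res = pc.run_cohort(
                base_params, strat, values=base_e, collect_trace=False
            )
            if e == 1.0:
                ref = res.qalys
            else:
                assert res.qalys >= ref

    def test_vectorized_run_matches_scalar(self, base_params, base_strategies):
        strat = base_strategies[0]
        values = base_values(base_params)
        vec = {k: np.full(3, v) for k, v in values.items()}
        scalar = pc.run_cohort(base_params, strat, collect_trace=False)
        vector = pc.run_cohort(
            base_params, strat, values=vec, collect_trace=False
        )
        np.testing.assert_allclose(vector.cost, scalar.cost, rtol=1e-12)
        np.testing.assert_allclose(vector.qalys, scalar.qalys, rtol=1e-12)

    def test_trace_frame_shape(self, base_params, base_strategies):
        res = pc.run_cohort(base_params, base_strategies[0])
        df = res.trace.to_frame()
        assert len(df) == base_params.settings.max_age - base_params.settings.start_age
        assert {"age", "event_free", "dead", "cycle_cost_disc"} <= set(df.columns)
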