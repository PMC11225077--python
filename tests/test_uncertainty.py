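"""Tornado, PSA sampling, CEAC and CE-plane quadrants."""

from __future__ import annotations

import copy

import numpy as np
import pytest

import polypill_cea as pc
from polypill_cea.engine import run_cohort
from polypill_cea.parameters import parameters_from_dict
from polypill_cea.states import HealthState as S
from polypill_cea.synthetic import base_config_dict
from polypill_cea.uncertainty import PSAResult, ceac, quadrant_summary, run_psa, tornado


class TestTornado:
    def test_zero_delta_gives_zero_spreads(self, base_params):
        bars = pc.tornado(base_params, delta=0.0)
        assert bars and all(b.spread == 0.0 for b in bars)

    def test_zero_influence_parameter(self, base_params):
        # calibrated drug-cost scale is 0, so pack prices cannot matter
        bars = pc.tornado(
            base_params, parameters=["price.polypill", "price.enalapril"]
        )
        assert all(b.spread == 0.0 for b in bars)

    def test_bars_sorted_by_absolute_spread(self, base_params):
        bars = pc.tornado(base_params, delta=0.2)
        spreads = [abs(b.spread) for b in bars]
        assert spreads == sorted(spreads, reverse=True)

    def test_additive_cost_parameter_matches_finite_difference(self, base_params):
        """NMB spread of a pure cost input equals its linear contribution."""
        wtp = base_params.settings.wtp
        bars = pc.tornado(
            base_params, comparison=("polypill", "enalapril"),
            delta=0.2, parameters=["cost.stroke"], wtp=wtp,
        )
        (bar,) = bars
        strategies = {s.label: s for s in pc.build_strategy_set(base_params)}
        d = {}
        rate = base_params.settings.discount_cost
        for label in ("polypill", "enalapril"):
            occ = run_cohort(base_params, strategies[label]).trace.occupancy
            avg = 0.5 * (occ[:-1, S.STROKE] + occ[1:, S.STROKE])
            disc = (1.0 + rate) ** (-np.arange(avg.size))
            d[label] = float(avg @ disc)
        expected = -2 * 0.2 * base_params.state_costs["stroke"].mean * (
            d["polypill"] - d["enalapril"]
        )
        assert bar.spread == pytest.approx(expected, rel=1e-9)

    def test_icer_outcome_supported(self, base_params):
        bars = pc.tornado(base_params, outcome="icer",
                          parameters=["util.post_angina", "cost.acute_mi"])
        assert len(bars) == 2 and all(np.isfinite(b.spread) for b in bars)

    def test_one_sided_variant(self, base_params):
        bars = pc.tornado(base_params, parameters=["cost.acute_mi"],
                          symmetric=False)
        base_bars = pc.tornado(base_params, parameters=["cost.acute_mi"])
        assert bars[0].low != base_bars[0].low
        assert bars[0].high == pytest.approx(base_bars[0].high)

    def test_invalid_inputs_rejected(self, base_params):
        with pytest.raises(ValueError):
            pc.tornado(base_params, parameters=[])
        with pytest.raises(ValueError):
            pc.tornado(base_params, parameters=["no.such.input"])
        with pytest.raises(ValueError):
            pc.tornado(base_params, comparison=("polypill", "placebo"))
        with pytest.raises(ValueError):
            pc.tornado(base_params, outcome="cost")


class TestPSA:
    def test_same_seed_is_bitwise_identical(self, base_params):
        a = run_psa(base_params, n=40, seed=11)
        b = run_psa(base_params, n=40, seed=11)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        for key in a.values:
            assert np.array_equal(np.asarray(a.values[key]),
                                  np.asarray(b.values[key]))
        c = run_psa(base_params, n=40, seed=12)
        assert not np.array_equal(a.costs, c.costs)

    def test_draws_recover_input_means(self, base_params):
        """Feasibility-independent inputs: sample mean within 3 SE."""
        psa = run_psa(base_params, n=4000, seed=5)
        checks = {
            "cost.stroke": 1215.5,
            "cost.acute_mi": 11461.6,
            "price.polypill": 42.85,
            "util.stroke": 0.63,  # capped SD, mean preserved
            "smr.stroke": 2.72,
        }
        for key, mean in checks.items():
            draws = np.asarray(psa.values[key])
            se = draws.std() / np.sqrt(draws.size)
            assert abs(draws.mean() - mean) < 3 * se, key

    def test_samples_are_valid(self, base_params):
        psa = run_psa(base_params, n=300, seed=9)
        assert np.all(psa.costs >= 0)
        assert np.all(psa.qalys >= 0)
        assert psa.n_resampled >= 0
        lo = np.asarray(psa.values["risk.mi.low"])
        hi = np.asarray(psa.values["risk.mi.high"])
        assert np.all(lo <= hi)

    def test_long_frame_format(self, base_params):
        psa = run_psa(base_params, n=10, seed=1)
        df = psa.to_frame()
        assert len(df) == 10 * 6
        assert {"iteration", "strategy", "cost", "qalys"} <= set(df.columns)

    def test_zero_sd_collapses_to_deterministic(self):
        cfg = copy.deepcopy(base_config_dict())

        def zero_sd(node):
            if isinstance(node, dict):
                for key in ("sd", "sd_low", "sd_high"):
                    if key in node:
                        node[key] = 0.0
                for val in node.values():
                    zero_sd(val)

        for section in ("baseline_risks", "utilities", "state_costs",
                        "drug_prices", "effects", "mortality"):
            zero_sd(cfg[section])
        params = parameters_from_dict(cfg)
        psa = run_psa(params, n=5, seed=3)
        det = {r.label: r for r in pc.run_all_strategies(params,
                                                         collect_trace=False)}
        for j, label in enumerate(psa.labels):
            np.testing.assert_allclose(psa.costs[:, j], det[label].cost,
                                       rtol=1e-12)
            np.testing.assert_allclose(psa.qalys[:, j], det[label].qalys,
                                       rtol=1e-12)

    def test_n_must_be_positive(self, base_params):
        with pytest.raises(ValueError):
            run_psa(base_params, n=0, seed=1)


def synthetic_psa(costs, qalys, labels):
    costs = np.asarray(costs, dtype=float)
    return PSAResult(n=costs.shape[0], seed=0, labels=list(labels),
                     costs=costs, qalys=np.asarray(qalys, dtype=float),
                     values={})


class TestCEAC:
    def test_probabilities_sum_to_one(self, base_params):
        psa = run_psa(base_params, n=200, seed=2)
        df = ceac(psa, pc.default_wtp_grid())
        sums = df.groupby("wtp")["probability"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_default_grid_contains_threshold(self):
        assert 21768.0 in pc.default_wtp_grid()

    def test_single_strategy_has_probability_one(self):
        psa = synthetic_psa([[10.0]] * 4, [[1.0]] * 4, ["only"])
        df = ceac(psa, [0.0, 1000.0, 21768.0])
        assert np.all(df["probability"] == 1.0)

    def test_zero_wtp_reduces_to_minimal_cost(self, base_params):
        psa = run_psa(base_params, n=150, seed=4)
        df = ceac(psa, [0.0])
        mins = psa.costs.min(axis=1, keepdims=True)
        ties = (psa.costs == mins).astype(float)
        ties /= ties.sum(axis=1, keepdims=True)
        expected = ties.mean(axis=0)
        got = df.set_index("strategy")["probability"]
        for j, label in enumerate(psa.labels):
            assert got[label] == pytest.approx(expected[j], abs=1e-12)

    def test_always_dominant_strategy_is_flat_at_one(self):
        rng = np.random.default_rng(0)
        n = 50
        costs = np.column_stack([rng.uniform(0, 10, n),
                                 rng.uniform(20, 30, n)])
        qalys = np.column_stack([rng.uniform(5, 6, n),
                                 rng.uniform(1, 2, n)])
        psa = synthetic_psa(costs, qalys, ["winner", "loser"])
        df = ceac(psa, [0.0, 5000.0, 21768.0, 60000.0])
        w = df[df["strategy"] == "winner"]["probability"]
        assert np.all(w == 1.0)

    def test_exact_ties_split_equally(self):
        psa = synthetic_psa([[5.0, 5.0]], [[2.0, 2.0]], ["a", "b"])
        df = ceac(psa, [1000.0])
        assert np.all(df["probability"] == 0.5)


class TestQuadrants:
    def test_fractions_partition_unity(self, base_params):
        psa = run_psa(base_params, n=120, seed=8)
        quad = quadrant_summary(psa, "polypill")
        totals = quad[["northeast", "southeast", "southwest", "northwest"]].sum(axis=1)
        np.testing.assert_allclose(totals, 1.0, atol=1e-12)
        assert set(quad["comparator"]) == set(psa.labels) - {"polypill"}

    def test_identical_draws_fill_single_quadrant(self):
        costs = np.tile([10.0, 30.0], (5, 1))
        qalys = np.tile([3.0, 2.0], (5, 1))
        psa = synthetic_psa(costs, qalys, ["ref", "other"])
        quad = quadrant_summary(psa, "ref").iloc[0]
        assert quad["southeast"] == 1.0
        assert quad[["northeast", "southwest", "northwest"]].sum() == 0.0

    def test_unknown_reference_rejected(self, base_params):
        psa = run_psa(base_params, n=5, seed=1)
        with pytest.raises(ValueError):
            quadrant_summary(psa, "placebo")
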