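"""Selection strategies, aggregation arithmetic and the Q statistic."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedfolio as sf
from seedfolio.errors import ConfigError, NumericalError
from seedfolio.selection import SelectionResult


class TestWeightedYieldVectors:
    def test_single_farm_weight_cancels(self):
        df = pd.DataFrame({"variety": ["a"], "area": [0.37],
                           "yhat": [50.0], "yield": [48.0]})
        p, r = sf.weighted_yield_vectors(df)
        assert p["a"] == pytest.approx(50.0)
        assert r["a"] == pytest.approx(48.0)

    def test_weighted_mean_arithmetic(self):
        """areas (1, 3) and predictions (40, 60): p = (40 + 180)/4 = 55."""
        df = pd.DataFrame({"variety": ["a", "a"], "area": [1.0, 3.0],
                           "yhat": [40.0, 60.0], "yield": [40.0, 60.0]})
        p, _ = sf.weighted_yield_vectors(df)
        assert p["a"] == 55.0

    def test_equal_areas_reduce_to_plain_mean(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"variety": ["a"] * 6, "area": [0.5] * 6,
                           "yhat": rng.normal(50, 5, 6),
                           "yield": rng.normal(50, 5, 6)})
        p, r = sf.weighted_yield_vectors(df)
        np.testing.assert_allclose(p["a"], df["yhat"].mean())
        np.testing.assert_allclose(r["a"], df["yield"].mean())

    def test_nonpositive_area_rejected(self):
        df = pd.DataFrame({"variety": ["a"], "area": [0.0],
                           "yhat": [1.0], "yield": [1.0]})
        with pytest.raises(ConfigError):
            sf.weighted_yield_vectors(df)


class TestBestVarietyStrategy:
    def test_two_variety_hand_computation(self):
        p = pd.Series({"a": 10.0, "b": 20.0})
        r = pd.Series({"a": 12.0, "b": 18.0})
        chosen, ratio = sf.best_variety_strategy(p, r)
        assert chosen == "b"
        assert ratio == pytest.approx(18.0 / 15.0)

    def test_perfect_prediction_ratio_at_least_one(self):
        rng = np.random.default_rng(1)
        r = pd.Series(rng.normal(50, 5, 10),
                      index=[f"v{i}" for i in range(10)])
        _, ratio = sf.best_variety_strategy(r, r)
        assert ratio >= 1.0

    def test_single_variety_parity(self):
        p = pd.Series({"a": 42.0})
        _, ratio = sf.best_variety_strategy(p, p)
        assert ratio == 1.0

    def test_tie_breaks_to_lowest_index(self):
        p = pd.Series({"b": 5.0, "a": 5.0})
        chosen, _ = sf.best_variety_strategy(p, p)
        assert chosen == "a"


class TestAggregateContributions:
    def test_hand_computed_two_sites(self):
        """areas (2, 1), rows 100% one variety each -> x = (2/3, 1/3)."""
        contribs = pd.DataFrame([[100.0, 0.0], [0.0, 100.0]],
                                index=["s1", "s2"], columns=["a", "b"])
        x = sf.aggregate_contributions(
            contribs, pd.Series({"s1": 2.0, "s2": 1.0}))
        np.testing.assert_allclose(x, [2 / 3, 1 / 3])
        assert x.sum() == pytest.approx(1.0)

    def test_identical_rows_independent_of_areas(self):
        row = [60.0, 30.0, 10.0]
        contribs = pd.DataFrame([row] * 4, index=list("wxyz"),
                                columns=["a", "b", "c"])
        x = sf.aggregate_contributions(
            contribs, pd.Series([0.1, 0.9, 0.4, 0.2], index=list("wxyz")))
        np.testing.assert_allclose(x, np.array(row) / 100.0)

    def test_single_site_returns_its_row(self):
        contribs = pd.DataFrame([[70.0, 30.0]], index=["s"],
                                columns=["a", "b"])
        x = sf.aggregate_contributions(contribs, pd.Series({"s": 0.5}))
        np.testing.assert_allclose(x, [0.7, 0.3])

    def test_bad_row_sum_rejected(self):
        contribs = pd.DataFrame([[50.0, 30.0]], index=["s"],
                                columns=["a", "b"])
        with pytest.raises(ConfigError):
            sf.aggregate_contributions(contribs, pd.Series({"s": 1.0}))


class TestTruncateTop5:
    def test_all_above_floor_unchanged(self):
        x = pd.Series({"a": 0.65, "b": 0.12, "c": 0.12, "d": 0.11})
        out = sf.truncate_top5(x)
        assert len(out.varieties) == 4
        np.testing.assert_allclose(out.shares, [65.0, 12.0, 12.0, 11.0])

    def test_renormalization_after_drop(self):
        x = pd.Series({"a": 0.50, "b": 0.45, "c": 0.05})
        out = sf.truncate_top5(x)
        np.testing.assert_allclose(out.shares, [100 * 50 / 95, 100 * 45 / 95])

    def test_fallback_single_largest(self):
        x = pd.Series({f"v{i}": 1 / 12 for i in range(12)})
        out = sf.truncate_top5(x)
        assert len(out.varieties) == 1
        np.testing.assert_allclose(out.shares, [100.0])

    def test_at_most_five_kept(self):
        x = pd.Series(np.full(8, 0.125), index=[f"v{i}" for i in range(8)])
        out = sf.truncate_top5(x)
        assert len(out.varieties) <= 5

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=12))
    def test_invariants_hold_for_arbitrary_shares(self, raw):
        x = pd.Series(raw, index=[f"v{i:02d}" for i in range(len(raw))])
        out = sf.truncate_top5(x)
        assert 1 <= len(out.varieties) <= 5
        assert out.shares.sum() == pytest.approx(100.0)
        assert (out.shares > 0).all()
        if len(out.varieties) > 1:
            assert (out.shares >= 10.0 - 1e-9).all()


class TestPortfolioYield:
    @pytest.mark.parametrize("shares,yields,expected", [
        ([100.0], [50.0], 50.0),
        ([50.0, 50.0], [40.0, 60.0], 50.0),
        ([200 / 3, 100 / 3], [30.0, 60.0], 40.0),
    ])
    def test_weighted_sums(self, shares, yields, expected):
        names = [f"v{i}" for i in range(len(shares))]
        sel = SelectionResult(names, np.array(shares),
                              pd.Series(dtype=float))
        Y = sf.portfolio_yield(sel, pd.Series(yields, index=names))
        assert Y == pytest.approx(expected)

    def test_missing_yield_renormalizes(self):
        sel = SelectionResult(["a", "b"], np.array([50.0, 50.0]),
                              pd.Series(dtype=float))
        Y = sf.portfolio_yield(sel, pd.Series({"a": 44.0, "b": np.nan}))
        assert Y == pytest.approx(44.0)

    def test_no_yields_at_all_raises(self):
        sel = SelectionResult(["a"], np.array([100.0]),
                              pd.Series(dtype=float))
        with pytest.raises(NumericalError):
            sf.portfolio_yield(sel, pd.Series({"a": np.nan}))


class TestImprovementQ:
    @pytest.mark.parametrize("ratios,expected", [
        ([1.0, 1.0, 1.0], 0.0),
        ([1.10, 1.00], 5.0),
        ([1.0672], 6.72),
    ])
    def test_mean_ratio_convention(self, ratios, expected):
        assert sf.improvement_Q(ratios) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            sf.improvement_Q([])


@pytest.fixture(scope="module")
def dominant_setup():
    """Ten varieties, one with a 15 bu/ac edge and no G×E of its own."""
    cfg = sf.GenConfig(n_varieties=10, n_farms=25, seed=7, noise_sd=1.5)
    truth = sf.generate_truth(cfg, gxe_sd=0.5)
    eff = np.zeros(10)
    eff[0] = 15.0
    truth = dataclasses.replace(truth, variety_effect=eff,
                                variety_temp_opt=np.full(10, 3200.0))
    return sf.generate_experiment(cfg, truth)


@pytest.fixture(scope="module")
def anticorrelated_setup():
    """Equal-mean varieties whose temperature optima sit at opposite ends
    of the climate range, so hot years reverse the cold-year ranking."""
    cfg = sf.GenConfig(n_varieties=8, n_farms=15, seed=11, noise_sd=1.5)
    truth = sf.generate_truth(cfg, gxe_sd=0.5)
    opts = np.where(np.arange(8) % 2 == 0, 2950.0, 3450.0)
    coefs = dict(truth.env_coefs)
    coefs["temp_curv"] = 14.0
    truth = dataclasses.replace(truth, variety_effect=np.zeros(8),
                                variety_temp_opt=opts, env_coefs=coefs)
    return sf.generate_experiment(cfg, truth)


class TestEvaluateStrategy:
    def test_dominant_variety_recovered_by_all_strategies(self,
                                                          dominant_setup):
        spec = sf.ModelSpec("rf", seed=0)
        best = sf.evaluate_strategy("best", dominant_setup, spec, 0.0,
                                    frontier_points=40)
        for sel in best.selections.values():
            assert sel.varieties == ["V001"]
        assert best.q_pct > 0
        for strategy, kw in (("local_pi", {}),
                             ("global_pi", {"global_pi": 19.0})):
            rep = sf.evaluate_strategy(strategy, dominant_setup, spec, 0.0,
                                       frontier_points=40, **kw)
            assert all("V001" in sel.varieties
                       for sel in rep.selections.values())
            assert rep.q_pct > 0

    def test_diversification_cuts_across_year_risk(self,
                                                   anticorrelated_setup):
        spec = sf.ModelSpec("rf", seed=0)
        best = sf.evaluate_strategy("best", anticorrelated_setup, spec, 0.0,
                                    frontier_points=40)
        local = sf.evaluate_strategy("local_pi", anticorrelated_setup, spec,
                                     0.0, frontier_points=40)
        assert local.risk < best.risk
        assert any(len(sel.varieties) > 1
                   for sel in local.selections.values())

    def test_global_pi_at_least_matches_local(self, anticorrelated_setup):
        """A freely chosen global risk level dominates heterogeneous local
        budgets on this seeded instance (regression check)."""
        spec = sf.ModelSpec("rf", seed=0)
        local = sf.evaluate_strategy("local_pi", anticorrelated_setup, spec,
                                     0.0, frontier_points=40)
        glob = sf.evaluate_strategy("global_pi", anticorrelated_setup, spec,
                                    0.0, global_pi=19.0, frontier_points=40)
        assert glob.q_pct >= local.q_pct

    def test_unknown_strategy_rejected(self, small_data):
        with pytest.raises(ConfigError):
            sf.evaluate_strategy("nope", small_data[0],
                                 sf.ModelSpec("rf"), 0.9)

    def test_global_pi_requires_value(self, small_data):
        with pytest.raises(ConfigError):
            sf.evaluate_strategy("global_pi", small_data[0],
                                 sf.ModelSpec("rf"), 0.9)


class TestGridSearch:
    def test_grid_cardinalities(self):
        """Default published sweep: 26 YDT values; 77 PI values per YDT."""
        ydt = np.round(np.arange(0.80, 1.05 + 1e-9, 0.01), 2)
        pi = np.arange(0.0, 19.0 + 1e-9, 0.25)
        assert len(ydt) == 26
        assert len(pi) == 77

    def test_single_point_grid_equals_direct_evaluation(self, small_data):
        exp, _, _ = small_data
        spec = sf.ModelSpec("rf", seed=0)
        best, surface = sf.grid_search(exp, spec, "best",
                                       ydt_grid=np.array([0.9]))
        direct = sf.evaluate_strategy("best", exp, spec, 0.9)
        assert len(surface) == 1
        assert best["q_pct"] == pytest.approx(direct.q_pct)

    def test_infeasible_points_recorded_not_dropped(self, small_data):
        exp, _, _ = small_data
        spec = sf.ModelSpec("mlr", seed=0)
        # a threshold beyond every mean ratio is infeasible but recorded
        _, surface = sf.grid_search(exp, spec, "best",
                                    ydt_grid=np.array([0.9, 9.9]))
        assert len(surface) == 2
        assert surface["q_pct"].isna().sum() == 1
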