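"""Regressor behaviour, error metrics, and leave-one-year-out validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedfolio as sf
from seedfolio.errors import ConfigError
from seedfolio.preprocess import FEATURE_COLUMNS, NUMERIC_FEATURES
from seedfolio.regression import Metrics


def _frame(n, rng, varieties=("a", "b", "c")):
    df = pd.DataFrame({c: rng.normal(size=n) for c in NUMERIC_FEATURES})
    df["year"] = rng.integers(2009, 2012, n)
    df["variety"] = rng.choice(list(varieties), n)
    return df[FEATURE_COLUMNS]


class TestFit:
    def test_mlr_recovers_linear_data(self):
        rng = np.random.default_rng(0)
        X = _frame(200, rng)
        y = (3.0 + 2.0 * X["temperature"] - 1.5 * X["ph"]
             + X["variety"].map({"a": 0.0, "b": 5.0, "c": -2.0}))
        model = sf.fit(sf.ModelSpec("mlr"), X, y)
        rmse = sf.metrics(y.to_numpy(), model.predict(X)).rmse
        assert rmse < 1e-8

    def test_knn_k1_memorizes_training(self):
        rng = np.random.default_rng(1)
        X = _frame(50, rng)
        y = rng.normal(50, 5, 50)
        model = sf.fit(sf.ModelSpec("knn", {"k": 1}), X, y)
        np.testing.assert_allclose(model.predict(X), y)

    def test_rf_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = _frame(80, rng)
        y = rng.normal(50, 5, 80)
        p1 = sf.fit(sf.ModelSpec("rf", seed=7), X, y).predict(X)
        p2 = sf.fit(sf.ModelSpec("rf", seed=7), X, y).predict(X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("method", ["rf", "knn", "whr"])
    def test_predictions_within_training_range(self, method, preprocessed):
        _, X, y, _ = preprocessed
        model = sf.fit(sf.ModelSpec(method, seed=0), X, y)
        yhat = model.predict(X)
        assert yhat.min() >= y.min() - 1e-9
        assert yhat.max() <= y.max() + 1e-9

    def test_unseen_variety_fallback_and_whr_error(self, preprocessed):
        _, X, y, _ = preprocessed
        query = X.iloc[:1].copy()
        query["variety"] = "NOT_A_VARIETY"
        rf = sf.fit(sf.ModelSpec("rf", seed=0), X, y)
        np.testing.assert_allclose(rf.predict(query), [y.mean()])
        whr = sf.fit(sf.ModelSpec("whr"), X, y)
        with pytest.raises(ConfigError, match="NOT_A_VARIETY"):
            whr.predict(query)


class TestWhr:
    def test_single_point_is_exact(self):
        X = pd.DataFrame([{c: 1.0 for c in NUMERIC_FEATURES}])
        X["variety"] = "v"
        X = X[FEATURE_COLUMNS]
        X2 = pd.concat([X, X.assign(variety="w")], ignore_index=True)
        model = sf.fit(sf.ModelSpec("whr", {"bandwidth": 0.5}), X2,
                       np.array([55.0, 20.0]))
        np.testing.assert_allclose(model.predict(X), [55.0])

    def test_infinite_bandwidth_limit_is_plain_mean(self):
        rng = np.random.default_rng(3)
        X = _frame(40, rng, varieties=("v",))
        y = np.where(np.arange(40) % 2, 40.0, 60.0)
        model = sf.fit(sf.ModelSpec("whr", {"bandwidth": 1e9}), X, y)
        np.testing.assert_allclose(model.predict(X.iloc[:3]), 50.0,
                                   rtol=1e-9)

    def test_hand_evaluated_kernel_mean(self):
        """Two training rows at standardized distances 0 and 1 from the
        query, h=1: estimate = (40 + 60 e^{-1/2}) / (1 + e^{-1/2})."""
        X = pd.DataFrame(50.0, index=range(2), columns=FEATURE_COLUMNS)
        X["variety"] = "v"
        # one feature differs; training sd of that feature defines the unit
        X.loc[1, "temperature"] = 52.0  # mean 51, sd 1 -> z = -1, +1
        y = np.array([40.0, 60.0])
        # h = 2 with rows 2 standardized units apart reproduces the
        # canonical case of distances {0, 1} at h = 1:
        # (40 + 60 e^{-1/2}) / (1 + e^{-1/2}) ~= 47.55
        model = sf.fit(sf.ModelSpec("whr", {"bandwidth": 2.0}), X, y)
        query = X.iloc[[0]]
        w2 = np.exp(-0.5)
        expected_q0 = (40.0 + 60.0 * w2) / (1.0 + w2)
        np.testing.assert_allclose(model.predict(query), [expected_q0])
        assert abs(expected_q0 - 47.55) < 0.01
        # query midway between the rows: distances 1 and 1 -> plain mean
        mid = X.iloc[[0]].copy()
        mid["temperature"] = 51.0
        np.testing.assert_allclose(model.predict(mid), [50.0])


class TestMetrics:
    def test_identity(self):
        y = np.array([1.0, 2.0, 3.0])
        m = sf.metrics(y, y)
        assert (m.rmse, m.mae) == (0.0, 0.0)
        np.testing.assert_allclose([m.pearson_r, m.spearman_rho], 1.0)

    def test_constant_offset(self):
        m = sf.metrics(np.zeros(2), np.ones(2))
        assert (m.rmse, m.mae) == (1.0, 1.0)

    def test_spearman_printed_formula(self):
        """Rank differences d = (1, -1, 0), N = 3:
        rho = 1 - 6*2/(3*8) = 0.5, and Pearson-of-ranks agrees."""
        y = np.array([1.0, 2.0, 3.0])
        yhat = np.array([2.0, 1.0, 3.0])
        m = sf.metrics(y, yhat)
        np.testing.assert_allclose(m.spearman_rho, 0.5)

    def test_rmse_dominates_mae(self, preprocessed):
        _, X, y, _ = preprocessed
        rng = np.random.default_rng(0)
        yhat = y.to_numpy() + rng.normal(0, 3, len(y))
        m = sf.metrics(y.to_numpy(), yhat)
        assert m.rmse >= m.mae >= 0

    def test_zero_variance_gives_nan_correlations(self):
        m = sf.metrics(np.array([1.0, 2.0]), np.array([5.0, 5.0]))
        assert np.isnan(m.pearson_r) and np.isnan(m.spearman_rho)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    def test_correlation_invariances(self, scale, shift):
        """rho is invariant under strictly monotone transforms of yhat;
        r under positive affine ones."""
        rng = np.random.default_rng(11)
        y = rng.normal(size=30)
        yhat = y + rng.normal(0, 0.5, 30)
        base = sf.metrics(y, yhat)
        affine = sf.metrics(y, scale * yhat + shift)
        np.testing.assert_allclose(affine.pearson_r, base.pearson_r,
                                   atol=1e-9)
        monotone = sf.metrics(y, np.exp(scale * yhat))
        np.testing.assert_allclose(monotone.spearman_rho, base.spearman_rho,
                                   atol=1e-12)


class TestLoyoValidate:
    def test_one_fold_per_year(self, preprocessed):
        _, X, y, _ = preprocessed
        report = sf.loyo_validate(sf.ModelSpec("mlr"), X, y)
        assert len(report.folds) == 7  # one per experiment year

    def test_oracle_model_near_noise_floor(self, noiseless_data):
        """With zero noise the generative truth predicts held-out years
        exactly; any fitted model can only do worse."""
        exp, _, truth = noiseless_data
        table, _ = sf.preprocess(exp, 0.0)
        X, y = sf.assemble_features(table)
        oracle = sf.TruthModel(truth)
        for year in X["year"].unique():
            mask = (X["year"] == year).to_numpy()
            m = sf.metrics(y[mask].to_numpy(), oracle.predict(X[mask]))
            assert m.rmse < 1e-2  # yields rounded to 3 decimals on output

    def test_rf_beats_mlr_on_curved_response(self, preprocessed):
        """The quadratic temperature-optimum term is invisible to a linear
        model; the forest captures it (fixed seed)."""
        _, X, y, _ = preprocessed
        rmse_rf = sf.loyo_validate(sf.ModelSpec("rf", seed=0), X, y).mean.rmse
        rmse_mlr = sf.loyo_validate(sf.ModelSpec("mlr"), X, y).mean.rmse
        assert rmse_rf < rmse_mlr

    def test_fitted_models_bounded_below_by_oracle(self, noiseless_data):
        exp, _, truth = noiseless_data
        table, _ = sf.preprocess(exp, 0.0)
        X, y = sf.assemble_features(table)
        report = sf.loyo_validate(sf.ModelSpec("rf", seed=0), X, y)
        assert report.mean.rmse > 1e-2  # strictly above the oracle's error

    def test_single_year_rejected(self, preprocessed):
        _, X, y, _ = preprocessed
        mask = (X["year"] == X["year"].iloc[0]).to_numpy()
        with pytest.raises(ConfigError):
            sf.loyo_validate(sf.ModelSpec("mlr"), X[mask], y[mask])


def test_model_persistence_round_trip(tmp_path, preprocessed):
    """A saved model reloads with identical predictions; a wrong format
    version is rejected."""
    import pickle

    _, X, y, _ = preprocessed
    model = sf.fit(sf.ModelSpec("rf", seed=0), X, y)
    path = tmp_path / "model.bin"
    model.save(path)
    back = sf.Model.load(path)
    np.testing.assert_array_equal(back.predict(X), model.predict(X))
    with open(path, "wb") as fh:
        pickle.dump({"version": -1, "model": None}, fh)
    with pytest.raises(ConfigError, match="version"):
        sf.Model.load(path)
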