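"""Yield regression models and leave-one-year-out validation.

Four regressors sit behind one ``fit``/``predict`` surface:

* ``mlr``  — multiple linear regression (one-hot variety),
* ``knn``  — k-nearest neighbours on standardized numerics + one-hot variety,
* ``rf``   — random forest, 100 trees with 5 features per split by default,
* ``whr``  — weighted-histograms regression: a Gaussian-kernel weighted
  mean over the query variety's training observations, the weights set by
  similarity of standardized numeric features. As the bandwidth grows the
  estimate tends to the variety's plain mean; an optional ``n_bins``
  reintroduces the explicit histogram discretization.

Validation is temporal: one fold per calendar year, the fold's year held
out and the model trained on the rest, because observations within a year
share weather and ordinary k-fold splits would leak it. Test rows whose
variety never occurs in the training years are skipped (and counted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .errors import ConfigError, NumericalError
from .preprocess import FEATURE_COLUMNS, NUMERIC_FEATURES

log = logging.getLogger(__name__)

METHODS = ("mlr", "knn", "rf", "whr")


@dataclass(frozen=True)
class ModelSpec:
    """Which regressor to fit and with what hyperparameters."""

    method: str = "rf"
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ConfigError(
                f"unknown method {self.method!r}; expected one of {METHODS}")


@dataclass
class Metrics:
    rmse: float
    mae: float
    pearson_r: float
    spearman_rho: float

    def as_dict(self) -> dict[str, float]:
        return {"rmse": self.rmse, "mae": self.mae,
                "pearson_r": self.pearson_r, "spearman_rho": self.spearman_rho}


@dataclass
class ValidationReport:
    """Per-held-out-year metrics plus their unweighted across-fold means."""

    folds: dict[int, Metrics]
    mean: Metrics
    n_test: dict[int, int]
    n_skipped: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"year": y, **m.as_dict(), "n_test": self.n_test[y],
                 "n_skipped_unseen_variety": self.n_skipped[y]}
                for y, m in sorted(self.folds.items())]
        rows.append({"year": "mean", **self.mean.as_dict(),
                     "n_test": sum(self.n_test.values()),
                     "n_skipped_unseen_variety": sum(self.n_skipped.values())})
        return pd.DataFrame(rows)


#: bumped whenever the persisted model layout changes
PERSISTENCE_VERSION = 1


class Model:
    """A fitted yield model: predicts bu/ac from the 15-column feature table."""

    def __init__(self, spec: ModelSpec, varieties: set[str],
                 train_mean: float):
        self.spec = spec
        self.varieties = varieties
        self.train_mean = train_mean

    def predict(self, X: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _unseen_mask(self, X: pd.DataFrame) -> np.ndarray:
        return ~X["variety"].astype(str).isin(self.varieties).to_numpy()

    def save(self, path) -> None:
        """Persist the fitted model with a format-version tag."""
        import pickle
        with open(path, "wb") as fh:
            pickle.dump({"version": PERSISTENCE_VERSION, "model": self}, fh)

    @staticmethod
    def load(path) -> "Model":
        import pickle
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != PERSISTENCE_VERSION:
            raise ConfigError(
                f"model file version {payload.get('version')} != "
                f"{PERSISTENCE_VERSION}")
        return payload["model"]


class _SklearnModel(Model):
    def __init__(self, spec, varieties, train_mean, pipeline,
                 variety_codes: dict[str, int] | None = None):
        super().__init__(spec, varieties, train_mean)
        self._pipeline = pipeline
        self._variety_codes = variety_codes

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X[FEATURE_COLUMNS].copy()
        X["variety"] = X["variety"].astype(str)
        if self._variety_codes is not None:  # ordinal encoding (rf)
            X["variety"] = X["variety"].map(self._variety_codes).fillna(-1)
        return X

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        unseen = self._unseen_mask(X)
        yhat = self._pipeline.predict(self._design(X))
        if unseen.any():
            log.warning("%s: %d rows with unseen variety -> training-mean "
                        "fallback", self.spec.method, int(unseen.sum()))
            yhat = np.where(unseen, self.train_mean, yhat)
        return np.asarray(yhat, dtype=float)


class WeightedHistogramModel(Model):
    """Similarity-weighted mean of the query variety's training yields."""

    def __init__(self, spec, varieties, train_mean, bandwidth, n_bins,
                 scaler_mean, scaler_sd, per_variety):
        super().__init__(spec, varieties, train_mean)
        self.bandwidth = bandwidth
        self.n_bins = n_bins
        self._mu = scaler_mean
        self._sd = scaler_sd
        self._per_variety = per_variety  # variety -> (Z, y)

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        return (X[NUMERIC_FEATURES].to_numpy(float) - self._mu) / self._sd

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        unseen = self._unseen_mask(X)
        if unseen.any():
            missing = sorted(set(X.loc[unseen, "variety"].astype(str)))
            raise ConfigError(
                "whr cannot predict varieties absent from training: "
                + ", ".join(missing[:5]))
        Z = self._standardize(X)
        out = np.empty(len(X), dtype=float)
        for i, (v, z) in enumerate(zip(X["variety"].astype(str), Z)):
            Zv, yv = self._per_variety[v]
            d2 = np.sum((Zv - z) ** 2, axis=1)
            w = np.exp(-d2 / (2.0 * self.bandwidth**2))
            total = w.sum()
            if total <= 1e-300:
                log.warning("whr: kernel weights underflowed for variety %s; "
                            "unweighted variety mean used", v)
                out[i] = yv.mean()
                continue
            if self.n_bins:
                edges = np.histogram_bin_edges(yv, bins=self.n_bins)
                mass, _ = np.histogram(yv, bins=edges, weights=w)
                centers = 0.5 * (edges[:-1] + edges[1:])
                out[i] = float((mass * centers).sum() / mass.sum())
            else:
                out[i] = float((w * yv).sum() / total)
        return out


def fit(spec: ModelSpec, X: pd.DataFrame, y: pd.Series | np.ndarray) -> Model:
    """Fit the requested regressor; deterministic given ``spec.seed``."""
    spec.validate()
    if len(X) < 2:
        raise ConfigError("need at least 2 training rows")
    y = np.asarray(y, dtype=float)
    varieties = set(X["variety"].astype(str))
    train_mean = float(y.mean())
    hp = dict(spec.hyperparams)

    if spec.method == "whr":
        bandwidth = float(hp.pop("bandwidth", 2.0))
        n_bins = hp.pop("n_bins", None)
        if bandwidth <= 0:
            raise ConfigError("whr bandwidth must be > 0")
        mu = X[NUMERIC_FEATURES].to_numpy(float).mean(axis=0)
        sd = X[NUMERIC_FEATURES].to_numpy(float).std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X[NUMERIC_FEATURES].to_numpy(float) - mu) / sd
        per_variety = {}
        for v, idx in X.groupby(X["variety"].astype(str)).indices.items():
            per_variety[v] = (Z[idx], y[idx])
        return WeightedHistogramModel(spec, varieties, train_mean,
                                      bandwidth, n_bins, mu, sd, per_variety)

    if spec.method == "mlr":
        pre = ColumnTransformer([
            ("variety", OneHotEncoder(handle_unknown="ignore"), ["variety"]),
        ], remainder="passthrough")
        est = Pipeline([("pre", pre), ("reg", LinearRegression())])
        codes = None
    elif spec.method == "knn":
        k = int(hp.pop("k", 5))
        pre = ColumnTransformer([
            ("variety", OneHotEncoder(handle_unknown="ignore"), ["variety"]),
            ("num", StandardScaler(), NUMERIC_FEATURES),
        ])
        est = Pipeline([
            ("pre", pre),
            ("reg", KNeighborsRegressor(n_neighbors=min(k, len(X)))),
        ])
        codes = None
    else:  # rf
        est = RandomForestRegressor(
            n_estimators=int(hp.pop("n_trees", 100)),
            max_features=hp.pop("features_per_split", 5),
            random_state=spec.seed,
            n_jobs=1,
        )
        codes = {v: i for i, v in enumerate(sorted(varieties))}

    model = _SklearnModel(spec, varieties, train_mean, est, codes)
    est.fit(model._design(X), y)
    return model


def metrics(y: np.ndarray, yhat: np.ndarray) -> Metrics:
    """RMSE, MAE, Pearson r and Spearman rho between real and predicted.

    Spearman is computed as the Pearson correlation of ranks, which equals
    the classical 1 - 6*sum(d^2)/(N(N^2-1)) form when ranks are untied.
    Zero variance on either side leaves the correlations NaN with a warning.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ConfigError("y and yhat must be equal-length 1-D arrays")
    if len(y) < 2:
        raise ConfigError("need N >= 2 for metrics")
    err = y - yhat
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(y) == 0 or np.std(yhat) == 0:
        log.warning("metrics: zero variance; correlations undefined (NaN)")
        return Metrics(rmse, mae, float("nan"), float("nan"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = float(stats.pearsonr(y, yhat).statistic)
        rho = float(stats.spearmanr(y, yhat).statistic)
    return Metrics(rmse, mae, r, rho)


def loyo_validate(spec: ModelSpec, X: pd.DataFrame,
                  y: pd.Series | np.ndarray) -> ValidationReport:
    """Leave-one-year-out validation over the ``year`` feature column."""
    y = np.asarray(y, dtype=float)
    years = sorted(X["year"].unique())
    if len(years) < 2:
        raise ConfigError("need at least 2 distinct years")
    folds: dict[int, Metrics] = {}
    n_test: dict[int, int] = {}
    n_skipped: dict[int, int] = {}
    for year in years:
        test_mask = (X["year"] == year).to_numpy()
        X_tr, y_tr = X.loc[~test_mask], y[~test_mask]
        X_te, y_te = X.loc[test_mask], y[test_mask]
        train_varieties = set(X_tr["variety"].astype(str))
        usable = X_te["variety"].astype(str).isin(train_varieties).to_numpy()
        skipped = int((~usable).sum())
        if skipped:
            log.info("fold %s: skipped %d rows with varieties unseen in "
                     "training", year, skipped)
        if usable.sum() < 2:
            log.warning("fold %s skipped entirely (%d usable rows)",
                        year, int(usable.sum()))
            continue
        model = fit(spec, X_tr, y_tr)
        yhat = model.predict(X_te.loc[usable])
        folds[int(year)] = metrics(y_te[usable], yhat)
        n_test[int(year)] = int(usable.sum())
        n_skipped[int(year)] = skipped
    if not folds:
        raise NumericalError("no usable validation folds")
    mean = Metrics(*(float(np.mean([getattr(m, f) for m in folds.values()]))
                     for f in ("rmse", "mae", "pearson_r", "spearman_rho")))
    return ValidationReport(folds, mean, n_test, n_skipped)
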