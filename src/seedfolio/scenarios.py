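"""Weather-scenario prediction cubes and variety covariance estimation.

Each historical year in the Region table is treated as one equiprobable
weather *scenario* for the coming season. Predicting every (variety, site,
scenario) combination gives a 3-D "prediction cube"; its per-(variety,
site) mean over scenarios is the expected yield used as the portfolio
return, and the covariance between two varieties is computed from their
flattened (site x scenario) layers with pairwise-complete deletion: any
position masked in either layer is dropped from both vectors before the
sample covariance (denominator n-1) is taken.

Pairwise deletion can produce an indefinite matrix; ``nearest_psd``
repairs it by eigenvalue clipping so the downstream quadratic program is
well posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericalError
from .preprocess import FEATURE_COLUMNS

log = logging.getLogger(__name__)


@dataclass
class PredictionCube:
    """variety x site x scenario-year array of predicted yields (NaN=masked)."""

    varieties: list[str]
    sites: list[str]
    years: list[int]
    values: np.ndarray  # (n_varieties, n_sites, n_years), NaN where masked

    def __post_init__(self):
        expected = (len(self.varieties), len(self.sites), len(self.years))
        if self.values.shape != expected:
            raise ConfigError(
                f"cube shape {self.values.shape} != axes {expected}")

    @property
    def mask(self) -> np.ndarray:
        """True where a prediction is available."""
        return np.isfinite(self.values)

    def layer(self, variety: str) -> np.ndarray:
        """A variety's (site x scenario) matrix."""
        return self.values[self.varieties.index(variety)]

    def subset(self, varieties: list[str]) -> "PredictionCube":
        idx = [self.varieties.index(v) for v in varieties]
        return PredictionCube(list(varieties), self.sites, self.years,
                              self.values[idx])


@dataclass
class VarietyCov:
    """Expected yields, covariance and joint-observation counts."""

    varieties: list[str]
    mu: np.ndarray            # (n,) mean predicted yield per variety
    sigma: np.ndarray         # (n, n) covariance, bu/ac squared
    n_pairs: np.ndarray       # (n, n) jointly observed cell counts
    psd_repaired: bool = False

    def submatrix(self, varieties: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self.varieties.index(v) for v in varieties]
        return self.mu[idx], self.sigma[np.ix_(idx, idx)]


def _region_features(sites_df: pd.DataFrame, year: int) -> pd.DataFrame:
    """One year's feature rows for every site (without variety)."""
    sub = sites_df[sites_df["year"] == year]
    if sub.empty:
        raise ConfigError(f"no region rows for scenario year {year}")
    return sub.reset_index(drop=True)


def build_cube(model, varieties: list[str], sites: pd.DataFrame,
               scenario_years: list[int] | None = None) -> PredictionCube:
    """Predict every (variety, site, scenario-year) cell from Region rows.

    ``sites`` is a Region-style table (one row per subregion x year, static
    soil covariates repeated). The scenario year doubles as the model's
    ``year`` feature. All requested varieties must be in the model's
    vocabulary (pre-condition); cells are unmasked everywhere since region
    covariates are complete.
    """
    if sites.empty:
        raise ConfigError("empty site table")
    unknown = [v for v in varieties if v not in model.varieties]
    if unknown:
        raise ConfigError(f"varieties not in model vocabulary: {unknown[:5]}")
    site_col = "subregion" if "subregion" in sites.columns else "farm"
    site_ids = sorted(sites[site_col].astype(str).unique())
    years = sorted(scenario_years if scenario_years is not None
                   else sites["year"].unique())
    values = np.full((len(varieties), len(site_ids), len(years)), np.nan)
    for yi, year in enumerate(years):
        feats = _region_features(sites, year)
        feats = feats.set_index(feats[site_col].astype(str)).loc[site_ids]
        base = feats.reset_index(drop=True)
        for vi, variety in enumerate(varieties):
            X = base.copy()
            X["variety"] = variety
            X["year"] = year
            values[vi, :, yi] = model.predict(X[FEATURE_COLUMNS])
    return PredictionCube(list(varieties), site_ids, [int(y) for y in years],
                          values)


def build_cube_from_trials(model, trials: pd.DataFrame) -> PredictionCube:
    """Evaluation-mode cube on Experiment data: only cells with a measured
    yield are unmasked; multiple observations of a cell average their
    predictions."""
    if trials.empty:
        raise ConfigError("empty trial table")
    df = trials.copy()
    df["variety"] = df["variety"].astype(str)
    usable = df["variety"].isin(model.varieties)
    if not usable.all():
        log.info("build_cube_from_trials: %d rows with out-of-vocabulary "
                 "varieties masked", int((~usable).sum()))
        df = df[usable]
    varieties = sorted(df["variety"].unique())
    sites = sorted(df["farm"].astype(str).unique())
    years = sorted(int(y) for y in df["year"].unique())
    df = df.reset_index(drop=True)
    df["_pred"] = model.predict(df[FEATURE_COLUMNS])
    cell = (df.groupby(["variety", "farm", "year"])["_pred"].mean())
    values = np.full((len(varieties), len(sites), len(years)), np.nan)
    v_ix = {v: i for i, v in enumerate(varieties)}
    s_ix = {s: i for i, s in enumerate(sites)}
    y_ix = {y: i for i, y in enumerate(years)}
    for (v, s, y), pred in cell.items():
        values[v_ix[v], s_ix[str(s)], y_ix[int(y)]] = pred
    return PredictionCube(varieties, sites, years, values)


def scenario_mean(cube: PredictionCube) -> pd.DataFrame:
    """Mean predicted yield over unmasked scenarios, per (site, variety).

    Scenarios are equiprobable, so the mean is unweighted. Fully masked
    (variety, site) pairs come back NaN and are logged.
    """
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(cube.mask, cube.values, np.nan), axis=2)
    n_empty = int((~cube.mask.any(axis=2)).sum())
    if n_empty:
        log.info("scenario_mean: %d (variety, site) pairs fully masked",
                 n_empty)
    return pd.DataFrame(means.T, index=pd.Index(cube.sites, name="site"),
                        columns=cube.varieties)


def pairwise_covariance(cube: PredictionCube) -> VarietyCov:
    """Pairwise-complete covariance between variety layers.

    For each pair, positions masked in either flattened layer are removed
    from both before the n-1 sample covariance. Entries with fewer than two
    joint observations are left NaN (nearest_psd fills them). On a complete
    cube this reduces to the ordinary sample covariance of the flattened
    layers.
    """
    n = len(cube.varieties)
    if n < 2:
        raise ConfigError("need >= 2 varieties for a covariance matrix")
    X = cube.values.reshape(n, -1)
    F = np.isfinite(X)
    Xz = np.where(F, X, 0.0)
    Ff = F.astype(float)
    n_pairs = Ff @ Ff.T
    Sxy = Xz @ Xz.T
    Sx = Xz @ Ff.T      # sum of x over joint support of (row, col)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Sxy - Sx * Sx.T / n_pairs) / (n_pairs - 1.0)
    cov[n_pairs < 2] = np.nan
    cov = 0.5 * (cov + cov.T)  # exact symmetry against float noise
    n_undef = int(np.isnan(cov).sum())
    if n_undef:
        log.warning("pairwise_covariance: %d entries with < 2 joint "
                    "observations left undefined", n_undef)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X, axis=1)
    return VarietyCov(list(cube.varieties), mu, cov,
                      n_pairs.astype(int))


def nearest_psd(cov: VarietyCov, tol: float = 1e-8) -> VarietyCov:
    """Repair a covariance matrix by eigenvalue clipping at zero.

    Undefined (NaN) entries are first filled with 0 (no information about
    the pair); if the result is already PSD within ``tol`` and nothing was
    filled, the input is returned unchanged with ``psd_repaired=False``.
    """
    sigma = np.asarray(cov.sigma, dtype=float)
    if not np.allclose(sigma, sigma.T, equal_nan=True):
        raise NumericalError("covariance matrix must be symmetric")
    filled = np.isnan(sigma).any()
    sigma = np.nan_to_num(sigma, nan=0.0)
    eigvals = np.linalg.eigvalsh(sigma)
    if not filled and eigvals[0] >= -tol:
        return VarietyCov(cov.varieties, cov.mu, sigma, cov.n_pairs,
                          psd_repaired=False)
    w, Q = np.linalg.eigh(sigma)
    repaired = (Q * np.maximum(w, 0.0)) @ Q.T
    repaired = 0.5 * (repaired + repaired.T)
    log.info("nearest_psd: clipped %d negative eigenvalues (min %.3e)",
             int((w < 0).sum()), float(w.min()))
    return VarietyCov(cov.varieties, cov.mu, repaired, cov.n_pairs,
                      psd_repaired=True)
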