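"""Seed-selection strategies, contribution aggregation and the Q statistic.

Three strategies are evaluated with leave-one-year-out validation on
Experiment-style data:

* **best** — pick the single variety with the highest area-weighted
  predicted yield in the held-out year;
* **local_pi** — per farm, run mean-variance portfolio optimisation with
  the farm's own PI as the risk-tolerance index, then aggregate
  contributions across farms (area-weighted) and truncate to at most five
  varieties with at least a 10% share;
* **global_pi** — as local_pi but with one fixed PI for every farm,
  representing a centrally managed selection.

The covariance matrix cannot come from historical yields (many variety
pairs never co-occur), so it is estimated once from a prediction cube
over all years without validation, with pairwise-complete deletion.

The improvement statistic Q is the mean over held-out years of the
selected portfolio's realized yield over the mean realized yield of all
varieties planted that year, reported as percent above parity; the
associated risk is the standard deviation of realized yearly portfolio
yields (bu/ac).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NumericalError, SeedfolioError
from .portfolio import efficient_frontier, risk_levels, select_by_pi
from .preprocess import assemble_features, preprocess
from .regression import ModelSpec, fit
from .scenarios import build_cube_from_trials, nearest_psd, \
    pairwise_covariance

log = logging.getLogger(__name__)

STRATEGIES = ("best", "local_pi", "global_pi")


@dataclass
class SelectionResult:
    """Final shares after the top-5 / >=10% truncation, in percent."""

    varieties: list[str]
    shares: np.ndarray            # percent, sums to 100
    pre_truncation: pd.Series     # fractional shares of every variety

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, index=self.varieties, name="share_pct")


@dataclass
class StrategyReport:
    strategy: str
    ydt: float
    yearly_portfolio_yield: dict[int, float]    # Y_l, bu/ac
    yearly_mean_yield: dict[int, float]         # m_l, bu/ac
    q_pct: float                                # 100 * (mean(Y_l/m_l) - 1)
    risk: float                                 # std of Y_l across years
    selections: dict[int, SelectionResult] = field(default_factory=dict)
    skipped_years: list[int] = field(default_factory=list)
    global_pi: float | None = None

    def to_frame(self) -> pd.DataFrame:
        years = sorted(self.yearly_portfolio_yield)
        return pd.DataFrame({
            "year": years,
            "portfolio_yield": [self.yearly_portfolio_yield[y] for y in years],
            "mean_yield": [self.yearly_mean_yield[y] for y in years],
            "ratio": [self.yearly_portfolio_yield[y] /
                      self.yearly_mean_yield[y] for y in years],
        })


def weighted_yield_vectors(df: pd.DataFrame,
                           pred_col: str = "yhat",
                           real_col: str = "yield",
                           ) -> tuple[pd.Series, pd.Series]:
    """Area-weighted mean predicted (p) and real (r) yield per variety.

    p_i = sum_j area_j yhat_j / sum_j area_j over the farms where variety i
    was planted; r_i the same with real yields.
    """
    if df.empty:
        raise ConfigError("empty evaluation table")
    area = df["area"].astype(float)
    if (area <= 0).any():
        raise ConfigError("areas must be positive")
    g = df.assign(_wp=area * df[pred_col], _wr=area * df[real_col],
                  _a=area).groupby(df["variety"].astype(str))
    sums = g[["_wp", "_wr", "_a"]].sum()
    if (sums["_a"] <= 0).any():
        raise ConfigError("zero total area for some variety")
    p = (sums["_wp"] / sums["_a"]).rename("p")
    r = (sums["_wr"] / sums["_a"]).rename("r")
    return p, r


def best_variety_strategy(p: pd.Series, r: pd.Series
                          ) -> tuple[str, float]:
    """argmax-p variety and its realized ratio r[chosen] / mean(r)."""
    if p.empty:
        raise ConfigError("empty prediction vector")
    p, r = p.sort_index(), r.sort_index()
    chosen = str(p.idxmax())  # first (lowest index) on ties
    return chosen, float(r[chosen] / r.mean())


def aggregate_contributions(contribs: pd.DataFrame,
                            areas: pd.Series) -> pd.Series:
    """Area-weighted aggregation of per-site contribution rows.

    Rows are per-site portfolios in percent (each summing to 100);
    x_i = sum_j area_j c_ji / sum_{m,n} area_m c_mn, returned as fractions
    summing to 1.
    """
    if contribs.empty:
        raise ConfigError("empty contribution table")
    areas = areas.loc[contribs.index].astype(float)
    if (areas <= 0).all():
        raise ConfigError("all site areas are zero")
    row_sums = contribs.sum(axis=1)
    if not np.allclose(row_sums, 100.0, atol=1e-6):
        raise ConfigError("contribution rows must each sum to 100%")
    weighted = contribs.mul(areas, axis=0).sum(axis=0)
    return weighted / weighted.sum()


def truncate_top5(x: pd.Series, min_share: float = 0.10,
                  max_varieties: int = 5) -> SelectionResult:
    """Drop shares below ``min_share``, keep at most ``max_varieties``
    largest (ties to the lowest index), renormalise to 100%.

    If nothing clears the floor, the single largest entry is kept at 100%.
    """
    if x.empty:
        raise ConfigError("empty share vector")
    x = x.sort_index()
    frac = x / x.sum()
    kept = frac[frac >= min_share - 1e-12]
    if kept.empty:
        kept = frac.iloc[[int(np.argmax(frac.to_numpy()))]]
    if len(kept) > max_varieties:
        order = np.lexsort((np.arange(len(kept)), -kept.to_numpy()))
        kept = kept.iloc[np.sort(order[:max_varieties])]
    shares = 100.0 * kept / kept.sum()
    return SelectionResult(list(shares.index), shares.to_numpy(), frac)


def portfolio_yield(selection: SelectionResult,
                    real_yields: pd.Series) -> float:
    """Y_l = sum_k y_k * share_k with shares as fractions.

    Kept varieties without a realized yield that year are dropped and the
    remaining shares renormalised (logged); if none remain, raises.
    """
    shares = selection.as_series() / 100.0
    available = shares.index.intersection(real_yields.dropna().index)
    if available.empty:
        raise NumericalError("no kept variety has a realized yield")
    if len(available) < len(shares):
        log.info("portfolio_yield: %d kept varieties lack realized yield; "
                 "shares renormalised", len(shares) - len(available))
        shares = shares[available] / shares[available].sum()
    return float((real_yields[shares.index] * shares).sum())


def improvement_Q(ratios: list[float] | np.ndarray) -> float:
    """Percent improvement: 100 * (mean of yearly Y_l/m_l ratios - 1)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ConfigError("need at least one usable year")
    if not np.all(np.isfinite(ratios)):
        raise NumericalError("non-finite yearly ratio (zero mean yield?)")
    return float(100.0 * (ratios.mean() - 1.0))


def _farm_portfolio_row(farm_df: pd.DataFrame, cov, pi: float,
                        frontier_points: int) -> pd.Series | None:
    """Optimal contribution row (percent) for one farm's varieties."""
    per_variety = farm_df.groupby(farm_df["variety"].astype(str))
    mu_local = per_variety["yhat"].mean()
    names = [v for v in mu_local.index if v in cov.varieties]
    if not names:
        return None
    mu_sub, sigma_sub = cov.submatrix(names)
    mu_sub = mu_local[names].to_numpy()  # farm-local expected yields
    try:
        frontier = efficient_frontier(mu_sub, sigma_sub, names,
                                      n_points=frontier_points)
    except SeedfolioError as exc:
        log.warning("farm frontier failed (%s); skipped", exc)
        return None
    levels = risk_levels(frontier)
    chosen = select_by_pi(frontier, levels, pi)
    return pd.Series(100.0 * chosen.weights, index=chosen.varieties)


def evaluate_strategy(strategy: str, trials: pd.DataFrame,
                      model_spec: ModelSpec, ydt: float,
                      global_pi: float | None = None,
                      frontier_points: int = 100,
                      min_share: float = 0.10,
                      max_varieties: int = 5) -> StrategyReport:
    """Leave-one-year-out evaluation of a selection strategy.

    ``trials`` is a raw Experiment-style table; preprocessing (YDT filter,
    duplicate merge, PI imputation) happens inside so grid search can vary
    the threshold. Years without any evaluable variety are excluded and
    recorded.
    """
    if strategy not in STRATEGIES:
        raise ConfigError(f"unknown strategy {strategy!r}")
    if strategy == "global_pi":
        if global_pi is None:
            raise ConfigError("global_pi strategy requires a PI value")
        if not (0.0 <= global_pi <= 19.0):
            raise ConfigError("global PI must be in [0, 19]")

    data, _kept = preprocess(trials, ydt)
    years = sorted(int(y) for y in data["year"].unique())
    if len(years) < 2:
        raise ConfigError("need >= 2 distinct years")

    cov = None
    if strategy in ("local_pi", "global_pi"):
        # covariance from predictions over all years, without validation
        X_all, y_all = assemble_features(data)
        full_model = fit(model_spec, X_all, y_all)
        cube = build_cube_from_trials(full_model, data)
        cov = nearest_psd(pairwise_covariance(cube))

    yearly_Y: dict[int, float] = {}
    yearly_m: dict[int, float] = {}
    selections: dict[int, SelectionResult] = {}
    skipped: list[int] = []
    for year in years:
        train = data[data["year"] != year]
        test = data[data["year"] == year].copy()
        train_varieties = set(train["variety"].astype(str))
        test = test[test["variety"].astype(str).isin(train_varieties)]
        if test.empty or len(train) < 2:
            skipped.append(year)
            continue
        X_tr, y_tr = assemble_features(train)
        model = fit(model_spec, X_tr, y_tr)
        X_te, _ = assemble_features(test)
        test["yhat"] = model.predict(X_te)
        p, r = weighted_yield_vectors(test)

        if strategy == "best":
            chosen, _ratio = best_variety_strategy(p, r)
            sel = SelectionResult([chosen], np.array([100.0]),
                                  (p * 0 + 0.0).astype(float))
        else:
            rows, areas = {}, {}
            for farm, farm_df in test.groupby(test["farm"].astype(str)):
                pi = (float(global_pi) if strategy == "global_pi"
                      else float(np.clip(farm_df["pi"].iloc[0], 0.0, 19.0)))
                row = _farm_portfolio_row(farm_df, cov, pi, frontier_points)
                if row is None:
                    continue
                rows[farm] = row
                areas[farm] = float(farm_df["area"].iloc[0])
            if not rows:
                skipped.append(year)
                continue
            contribs = (pd.DataFrame.from_dict(rows, orient="index")
                        .fillna(0.0).sort_index(axis=1))
            x = aggregate_contributions(contribs, pd.Series(areas))
            sel = truncate_top5(x, min_share, max_varieties)
        try:
            Y_l = portfolio_yield(sel, r)
        except NumericalError:
            skipped.append(year)
            continue
        yearly_Y[year] = Y_l
        yearly_m[year] = float(r.mean())
        selections[year] = sel

    if not yearly_Y:
        raise NumericalError("no evaluable year (YDT too strict?)")
    ratios = [yearly_Y[y] / yearly_m[y] for y in yearly_Y]
    q = improvement_Q(ratios)
    y_vals = np.array(list(yearly_Y.values()))
    risk = float(y_vals.std(ddof=1)) if len(y_vals) > 1 else 0.0
    return StrategyReport(strategy, ydt, yearly_Y, yearly_m, q, risk,
                          selections, skipped, global_pi)


def grid_search(trials: pd.DataFrame, model_spec: ModelSpec, strategy: str,
                ydt_grid: np.ndarray | None = None,
                pi_grid: np.ndarray | None = None,
                frontier_points: int = 100,
                ) -> tuple[dict, pd.DataFrame]:
    """Brute-force Q maximisation over YDT (and, for global_pi, PI) grids.

    Default grids follow the published sweep: YDT 0.80..1.05 step 0.01
    (26 values) and PI 0..19 step 0.25 (77 values). Infeasible grid points
    are recorded with NaN Q, not dropped. Ties break toward the smallest
    YDT, then the smallest PI.
    """
    if ydt_grid is None:
        ydt_grid = np.round(np.arange(0.80, 1.05 + 1e-9, 0.01), 2)
    ydt_grid = np.asarray(ydt_grid, dtype=float)
    if ydt_grid.size == 0:
        raise ConfigError("empty YDT grid")
    if strategy == "global_pi":
        if pi_grid is None:
            pi_grid = np.arange(0.0, 19.0 + 1e-9, 0.25)
        pi_grid = np.asarray(pi_grid, dtype=float)
        if pi_grid.size == 0:
            raise ConfigError("empty PI grid")
        combos = list(itertools.product(ydt_grid, pi_grid))
    else:
        combos = [(ydt, None) for ydt in ydt_grid]

    records = []
    for ydt, pi in combos:
        try:
            report = evaluate_strategy(strategy, trials, model_spec,
                                       float(ydt), global_pi=pi,
                                       frontier_points=frontier_points)
            records.append({"ydt": float(ydt), "pi": pi, "q_pct":
                            report.q_pct, "risk": report.risk})
        except SeedfolioError as exc:
            log.info("grid point ydt=%.2f pi=%s infeasible: %s", ydt, pi, exc)
            records.append({"ydt": float(ydt), "pi": pi,
                            "q_pct": np.nan, "risk": np.nan})
    surface = pd.DataFrame(records)
    if surface["q_pct"].isna().all():
        raise NumericalError("every grid point was infeasible")
    # argmax with ties toward smallest ydt then smallest pi (frame is
    # already in that lexicographic order)
    best_idx = int(surface["q_pct"].idxmax())
    best = surface.loc[best_idx].to_dict()
    return best, surface
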