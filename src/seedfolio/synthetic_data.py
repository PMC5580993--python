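"""Synthetic Experiment / Region table generator.

The real multi-environment soybean trial data this package was designed
around are proprietary, so this module generates tables with the same
structure and the statistical features the downstream analysis relies on:

* variety main effects on yield,
* a smooth environment response (weather + soil),
* genotype-by-environment interaction, built from two pieces: a
  per-variety quadratic temperature-optimum term (which reorders
  varieties across weather scenarios and so makes diversification
  genuinely useful) and a per-(variety, farm) random effect,
* unbalanced variety x farm x year coverage,
* missing soil-productivity-index (PI) values and duplicated
  (farm, planting date, variety) observations, so the preprocessing
  rules have something to do.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical configs produce byte-identical
tables. The ground-truth parameters are returned as :class:`TruthParams`
so recovery tests can compare fitted models against the generative
process.

Units follow the trial-data conventions: yield in bu/ac, seasonal
temperature as a growing-season sum in deg C, precipitation as a seasonal
sum in mm, solar radiation as a seasonal sum in W/m^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError

#: baseline yield (bu/ac) around which variety/environment effects act
BASELINE_YIELD = 50.0

#: regional centres/scales used to normalise weather inside the yield model
TEMP_CENTER, TEMP_SCALE = 3200.0, 300.0
PRECIP_CENTER, PRECIP_SCALE = 600.0, 150.0
SOLAR_CENTER, SOLAR_SCALE = 42000.0, 3000.0

#: temperature optimum of the commercial check variety (deg C season sum)
CHECK_TEMP_OPT = TEMP_CENTER
#: yield offset of the check variety over the baseline (bu/ac)
CHECK_EFFECT = 1.0

EXPERIMENT_COLUMNS = [
    "variety", "farm", "year", "planting_date", "latitude", "longitude",
    "temperature", "precipitation", "solar", "cec", "ph", "organic_matter",
    "soil_class", "clay", "silt", "sand", "area", "pi",
    "yield", "check_yield",
]

REGION_COLUMNS = [
    "subregion", "year", "latitude", "longitude",
    "temperature", "precipitation", "solar",
    "cec", "ph", "organic_matter", "clay", "silt", "sand", "area", "pi",
]


@dataclass(frozen=True)
class GenConfig:
    """Generator configuration; defaults are desk-scale, scalable upward."""

    n_varieties: int = 50
    n_farms: int = 40
    n_subregions: int = 100
    experiment_years: tuple[int, ...] = tuple(range(2009, 2016))
    region_years: tuple[int, ...] = tuple(range(2001, 2016))
    missing_pi_rate: float = 0.05
    duplicate_rate: float = 0.05
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_varieties < 1 or self.n_farms < 1 or self.n_subregions < 1:
            raise ConfigError("counts must be >= 1")
        if len(self.experiment_years) < 2:
            raise ConfigError("need at least 2 experiment years")
        if len(self.region_years) < 2:
            raise ConfigError("need at least 2 region years")
        for name in ("missing_pi_rate", "duplicate_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise ConfigError(f"{name} must be in [0, 1), got {rate}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthParams:
    """Ground truth of the generative yield model, one entry per variety."""

    variety_effect: np.ndarray        # (n_varieties,) bu/ac offsets
    variety_temp_opt: np.ndarray      # (n_varieties,) deg C season-sum optima
    env_coefs: dict[str, float]
    gxe_sd: float
    seed: int

    @property
    def n_varieties(self) -> int:
        return len(self.variety_effect)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variety_effect": self.variety_effect.tolist(),
            "variety_temp_opt": self.variety_temp_opt.tolist(),
            "env_coefs": dict(self.env_coefs),
            "gxe_sd": self.gxe_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthParams":
        payload = json.loads(Path(path).read_text())
        return cls(
            variety_effect=np.asarray(payload["variety_effect"], dtype=float),
            variety_temp_opt=np.asarray(payload["variety_temp_opt"], dtype=float),
            env_coefs=dict(payload["env_coefs"]),
            gxe_sd=float(payload["gxe_sd"]),
            seed=int(payload["seed"]),
        )


DEFAULT_ENV_COEFS: dict[str, float] = {
    "precip": 4.0,      # bu/ac per normalized precipitation unit
    "precip2": 2.0,     # concave penalty on normalized precipitation^2
    "solar": 2.0,
    "ph2": 1.5,         # penalty on (pH - 6.5)^2
    "om": 1.0,          # bu/ac per % organic matter above 4
    "silt": 1.5,        # per normalized silt share
    "temp_curv": 8.0,   # curvature of the temperature-optimum penalty
}


def variety_names(n: int) -> list[str]:
    return [f"V{i + 1:03d}" for i in range(n)]


def generate_truth(config: GenConfig, gxe_sd: float = 2.0) -> TruthParams:
    """Draw the generative parameters: variety effects ~ Normal(0, 5 bu/ac),
    temperature optima uniform over the regional weather range."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    effects = rng.normal(0.0, 5.0, size=config.n_varieties)
    temp_opts = rng.uniform(
        TEMP_CENTER - TEMP_SCALE, TEMP_CENTER + TEMP_SCALE,
        size=config.n_varieties,
    )
    return TruthParams(
        variety_effect=effects,
        variety_temp_opt=temp_opts,
        env_coefs=dict(DEFAULT_ENV_COEFS),
        gxe_sd=float(gxe_sd),
        seed=config.seed,
    )


def env_response(truth: TruthParams, df: pd.DataFrame) -> np.ndarray:
    """Deterministic environment response f_env (weather + soil), bu/ac.

    Shared by test and check varieties; excludes the per-variety
    temperature-optimum term.
    """
    c = truth.env_coefs
    p = (df["precipitation"].to_numpy(float) - PRECIP_CENTER) / PRECIP_SCALE
    s = (df["solar"].to_numpy(float) - SOLAR_CENTER) / SOLAR_SCALE
    return (
        c["precip"] * p
        - c["precip2"] * p**2
        + c["solar"] * s
        - c["ph2"] * (df["ph"].to_numpy(float) - 6.5) ** 2
        + c["om"] * (df["organic_matter"].to_numpy(float) - 4.0)
        + c["silt"] * (df["silt"].to_numpy(float) - 35.0) / 15.0
    )


def temp_penalty(truth: TruthParams, temperature: np.ndarray,
                 temp_opt: np.ndarray) -> np.ndarray:
    """Quadratic temperature-optimum penalty kappa * ((T - opt)/scale)^2."""
    z = (np.asarray(temperature, float) - np.asarray(temp_opt, float)) / TEMP_SCALE
    return truth.env_coefs["temp_curv"] * z**2


#: crop-failure floor: the generative mean saturates here instead of going
#: negative in hostile environments (part of the data-generating process,
#: so the oracle model reproduces it exactly)
YIELD_FLOOR = 0.1


def true_yield(truth: TruthParams, df: pd.DataFrame) -> np.ndarray:
    """Noise-free generative yield for rows carrying a ``variety`` column.

    max(baseline + variety effect + f_env - temperature penalty, floor);
    excludes the (variety, farm) random interaction and observation noise,
    i.e. the part of the process a covariate-driven model can in principle
    recover.
    """
    names = variety_names(truth.n_varieties)
    idx = pd.Index(names).get_indexer(df["variety"].astype(str))
    if (idx < 0).any():
        raise ConfigError("unknown variety label in dataframe")
    raw = (
        BASELINE_YIELD
        + truth.variety_effect[idx]
        + env_response(truth, df)
        - temp_penalty(truth, df["temperature"].to_numpy(float),
                       truth.variety_temp_opt[idx])
    )
    return np.maximum(raw, YIELD_FLOOR)


def check_yield_mean(truth: TruthParams, df: pd.DataFrame) -> np.ndarray:
    """Noise-free yield of the commercial check variety on the same rows."""
    raw = (
        BASELINE_YIELD
        + CHECK_EFFECT
        + env_response(truth, df)
        - temp_penalty(truth, df["temperature"].to_numpy(float),
                       np.full(len(df), CHECK_TEMP_OPT))
    )
    return np.maximum(raw, YIELD_FLOOR)


def _soil_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Static soil covariates for n sites; clay+silt+sand = 100 exactly."""
    texture = rng.dirichlet((2.0, 3.0, 2.5), size=n) * 100.0
    texture = np.round(texture, 2)
    # push rounding residue into sand so the simplex constraint is exact
    texture[:, 2] = np.round(100.0 - texture[:, 0] - texture[:, 1], 2)
    return pd.DataFrame({
        "cec": np.round(rng.uniform(5.0, 30.0, n), 2),
        "ph": np.round(rng.uniform(5.0, 8.0, n), 2),
        "organic_matter": np.round(rng.uniform(1.0, 8.0, n), 2),
        "clay": texture[:, 0],
        "silt": texture[:, 1],
        "sand": texture[:, 2],
        "pi": rng.integers(0, 20, n).astype(float),
        "area": np.round(rng.uniform(0.05, 1.0, n), 4),
    })


def _weather(rng: np.random.Generator, lat: np.ndarray, lon: np.ndarray,
             years: tuple[int, ...]) -> pd.DataFrame:
    """Season-sum weather per (site, year).

    Each year's anomaly is a smooth planar field over (lat, lon) plus small
    site-year noise, so nearby sites share weather trajectories (their
    across-year correlation decays with distance) while years differ enough
    to act as distinct scenarios.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    lat_n = (lat - lat.mean()) / max(lat.std(), 1e-9)
    lon_n = (lon - lon.mean()) / max(lon.std(), 1e-9)
    # static spatial gradient: colder to the north-west
    base_t = TEMP_CENTER - 120.0 * lat_n + 60.0 * lon_n
    base_p = PRECIP_CENTER + 60.0 * lon_n - 20.0 * lat_n
    base_s = SOLAR_CENTER - 800.0 * lat_n

    frames = []
    for year in years:
        a_t, b_t, c_t = rng.normal(0, 150), rng.normal(0, 70), rng.normal(0, 70)
        a_p, b_p, c_p = rng.normal(0, 80), rng.normal(0, 35), rng.normal(0, 35)
        a_s, b_s, c_s = rng.normal(0, 1200), rng.normal(0, 500), rng.normal(0, 500)
        n = len(lat)
        frames.append(pd.DataFrame({
            "year": year,
            "temperature": base_t + a_t + b_t * lat_n + c_t * lon_n
            + rng.normal(0, 25, n),
            "precipitation": np.maximum(
                base_p + a_p + b_p * lat_n + c_p * lon_n + rng.normal(0, 15, n),
                50.0),
            "solar": np.maximum(
                base_s + a_s + b_s * lat_n + c_s * lon_n + rng.normal(0, 300, n),
                20000.0),
        }))
    out = pd.concat(frames, ignore_index=True)
    for col in ("temperature", "precipitation", "solar"):
        out[col] = np.round(out[col], 2)
    return out


def gxe_matrix(config: GenConfig, truth: TruthParams) -> np.ndarray:
    """Per-(variety, farm) random interaction, consistent across years."""
    rng = np.random.default_rng((config.seed, 3))
    return rng.normal(0.0, truth.gxe_sd, size=(config.n_varieties, config.n_farms))


def generate_experiment(config: GenConfig, truth: TruthParams) -> pd.DataFrame:
    """Generate the Experiment table (one row per trial observation)."""
    config.validate()
    if truth.n_varieties != config.n_varieties:
        raise ConfigError("truth/config variety counts differ")
    rng = np.random.default_rng((config.seed, 1))

    farms = [f"F{i + 1:03d}" for i in range(config.n_farms)]
    lat = np.round(rng.uniform(38.0, 47.0, config.n_farms), 4)
    lon = np.round(rng.uniform(-98.0, -82.0, config.n_farms), 4)
    soil = _soil_table(rng, config.n_farms)
    weather = _weather(rng, lat, lon, config.experiment_years)

    n_v, n_f, n_y = config.n_varieties, config.n_farms, len(config.experiment_years)
    # unbalanced coverage: each variety is grown on a random ~half of the
    # farms, and each such (variety, farm) pair is observed in ~60% of years
    farm_ok = rng.random((n_v, n_f)) < 0.5
    cell_ok = farm_ok[:, :, None] & (rng.random((n_v, n_f, n_y)) < 0.6)
    # guarantee every variety at least one observation
    for v in range(n_v):
        if not cell_ok[v].any():
            cell_ok[v, rng.integers(n_f), rng.integers(n_y)] = True

    v_idx, f_idx, y_idx = np.nonzero(cell_ok)
    years_arr = np.asarray(config.experiment_years)

    planting_day = rng.integers(1, 29, size=(n_f, n_y))  # farm plants once/year

    rows = pd.DataFrame({
        "variety": np.asarray(variety_names(n_v))[v_idx],
        "farm": np.asarray(farms)[f_idx],
        "year": years_arr[y_idx],
        "latitude": lat[f_idx],
        "longitude": lon[f_idx],
    })
    rows["planting_date"] = [
        f"{y}-05-{d:02d}" for y, d in zip(rows["year"], planting_day[f_idx, y_idx])
    ]
    for col in soil.columns:
        rows[col] = soil[col].to_numpy()[f_idx]
    wx = weather.set_index("year")
    for col in ("temperature", "precipitation", "solar"):
        mat = wx[col].to_numpy().reshape(n_y, n_f)  # _weather emits year blocks
        rows[col] = mat[y_idx, f_idx]
    rows["soil_class"] = pd.Categorical.from_codes(
        rng.integers(0, 5, len(rows)), categories=list("ABCDE")).astype(str)

    # duplicate a fraction of keys 2-3 times (same covariates, new noise)
    if config.duplicate_rate > 0:
        dup_mask = rng.random(len(rows)) < config.duplicate_rate
        extra_counts = rng.integers(1, 3, size=int(dup_mask.sum()))
        extras = rows.loc[dup_mask].loc[
            rows.loc[dup_mask].index.repeat(extra_counts)]
        rows = pd.concat([rows, extras], ignore_index=True)

    gxe = gxe_matrix(config, truth)
    v_all = pd.Index(variety_names(n_v)).get_indexer(rows["variety"])
    f_all = pd.Index(farms).get_indexer(rows["farm"])
    det = true_yield(truth, rows) + gxe[v_all, f_all]
    noise = rng.normal(0.0, config.noise_sd, len(rows)) if config.noise_sd else 0.0
    check_noise = (rng.normal(0.0, config.noise_sd, len(rows))
                   if config.noise_sd else 0.0)
    rows["yield"] = np.round(np.maximum(det + noise, YIELD_FLOOR), 3)
    rows["check_yield"] = np.round(
        np.maximum(check_yield_mean(truth, rows) + check_noise,
                   YIELD_FLOOR), 3)

    if config.missing_pi_rate > 0:
        rows.loc[rng.random(len(rows)) < config.missing_pi_rate, "pi"] = np.nan

    return rows[EXPERIMENT_COLUMNS].reset_index(drop=True)


def generate_region(config: GenConfig, truth: TruthParams) -> pd.DataFrame:
    """Generate the Region table (one row per subregion x historical year)."""
    config.validate()
    rng = np.random.default_rng((config.seed, 2))
    n = config.n_subregions
    subregions = [f"S{i + 1:04d}" for i in range(n)]
    lat = np.round(rng.uniform(38.0, 47.0, n), 4)
    lon = np.round(rng.uniform(-98.0, -82.0, n), 4)
    soil = _soil_table(rng, n)
    weather = _weather(rng, lat, lon, config.region_years)

    n_y = len(config.region_years)
    out = pd.DataFrame({
        "subregion": np.tile(subregions, n_y),
        "year": np.repeat(np.asarray(config.region_years), n),
        "latitude": np.tile(lat, n_y),
        "longitude": np.tile(lon, n_y),
        "temperature": weather["temperature"].to_numpy(),
        "precipitation": weather["precipitation"].to_numpy(),
        "solar": weather["solar"].to_numpy(),
    })
    for col in ("cec", "ph", "organic_matter", "clay", "silt", "sand", "area", "pi"):
        out[col] = np.tile(soil[col].to_numpy(), n_y)
    return out[REGION_COLUMNS].reset_index(drop=True)


class TruthModel:
    """Oracle regressor that evaluates the generative mean function.

    Exposes the same ``predict``/``varieties`` surface as fitted models so it
    can stand in for one in validation and cube construction.
    """

    def __init__(self, truth: TruthParams):
        self.truth = truth
        self.varieties = set(variety_names(truth.n_varieties))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return true_yield(self.truth, X)


def simulate(config: GenConfig, out_dir: str | Path | None = None,
             gxe_sd: float = 2.0,
             ) -> tuple[pd.DataFrame, pd.DataFrame, TruthParams]:
    """Generate truth + Experiment + Region; optionally write CSV/JSON."""
    truth = generate_truth(config, gxe_sd=gxe_sd)
    experiment = generate_experiment(config, truth)
    region = generate_region(config, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        experiment.to_csv(out / "experiment.csv", index=False)
        region.to_csv(out / "region.csv", index=False)
        truth.to_json(out / "truth.json")
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2))
    return experiment, region, truth
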