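"""End-to-end driver: preprocess -> fit -> cube -> covariance -> frontier
-> selection, with every stage's outputs persisted next to a manifest.

The ``recommend`` entry point mirrors the production use: train the yield
model on the full (filtered) Experiment table, predict every kept variety
in every subregion under each historical weather scenario, take
scenario-mean expected yields and the pairwise-complete covariance,
optimise a portfolio per subregion at the subregion's own PI, aggregate
the contribution rows area-weighted across subregions and truncate to at
most five varieties with at least 10% each.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError
from .portfolio import efficient_frontier, risk_levels, select_by_pi
from .preprocess import FEATURE_COLUMNS, assemble_features, preprocess
from .regression import ModelSpec, fit
from .scenarios import build_cube, nearest_psd, pairwise_covariance, \
    scenario_mean
from .selection import SelectionResult, aggregate_contributions, \
    truncate_top5

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; constants default to the published design
    (100 frontier points, 20 risk levels, 10% minimum share, at most 5
    varieties, 15 weather scenarios)."""

    experiment_path: str = "experiment.csv"
    region_path: str = "region.csv"
    output_dir: str = "out"
    model: ModelSpec = field(default_factory=ModelSpec)
    ydt: float = 1.0
    frontier_points: int = 100
    n_risk_levels: int = 20
    min_share: float = 0.10
    max_varieties: int = 5
    scenario_years: tuple[int, ...] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model"] = {"method": self.model.method,
                      "hyperparams": dict(self.model.hyperparams),
                      "seed": self.model.seed}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        m = d.pop("model", {})
        spec = ModelSpec(method=m.get("method", "rf"),
                         hyperparams=dict(m.get("hyperparams", {})),
                         seed=int(m.get("seed", 0)))
        if d.get("scenario_years") is not None:
            d["scenario_years"] = tuple(int(y) for y in d["scenario_years"])
        return cls(model=spec, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _check_schema(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing column(s): "
                          + ", ".join(missing))


def recommend(experiment: pd.DataFrame, region: pd.DataFrame,
              config: RunConfig) -> tuple[SelectionResult, pd.DataFrame,
                                          pd.DataFrame]:
    """Region-level selection with local (per-subregion) PI.

    Returns (selection, per-subregion contribution table in percent,
    per-subregion dominant-variety table for mapping).
    """
    _check_schema(experiment, FEATURE_COLUMNS + ["yield", "check_yield",
                                                 "farm"], "experiment")
    _check_schema(region, [c for c in FEATURE_COLUMNS if c != "variety"]
                  + ["subregion"], "region")
    data, kept = preprocess(experiment, config.ydt)
    X, y = assemble_features(data)
    model = fit(config.model, X, y)
    varieties = sorted(kept & model.varieties)
    years = (list(config.scenario_years) if config.scenario_years
             else sorted(int(y) for y in region["year"].unique()))
    cube = build_cube(model, varieties, region, years)
    mu_site = scenario_mean(cube)                  # site x variety
    cov = nearest_psd(pairwise_covariance(cube))

    static = (region.sort_values("year")
              .groupby(region["subregion"].astype(str))
              .first())
    rows, areas, dominant = {}, {}, []
    for site in cube.sites:
        mu_s = mu_site.loc[site].dropna()
        names = [v for v in mu_s.index if v in cov.varieties]
        if not names:
            continue
        _, sigma_sub = cov.submatrix(names)
        frontier = efficient_frontier(mu_s[names].to_numpy(), sigma_sub,
                                      names, n_points=config.frontier_points)
        pi = float(np.clip(static.loc[site, "pi"], 0.0, 19.0))
        chosen = select_by_pi(frontier, risk_levels(frontier), pi)
        row = pd.Series(100.0 * chosen.weights, index=chosen.varieties)
        rows[site] = row
        areas[site] = float(static.loc[site, "area"])
        dominant.append({
            "subregion": site,
            "latitude": static.loc[site, "latitude"],
            "longitude": static.loc[site, "longitude"],
            "dominant_variety": row.idxmax(),
        })
    if not rows:
        raise ConfigError("no subregion produced a portfolio")
    contribs = (pd.DataFrame.from_dict(rows, orient="index")
                .fillna(0.0).sort_index(axis=1).sort_index())
    x = aggregate_contributions(contribs, pd.Series(areas))
    selection = truncate_top5(x, config.min_share, config.max_varieties)
    return selection, contribs, pd.DataFrame(dominant)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline from CSV inputs; persist all artifacts.

    Returns the manifest. Partial outputs are kept on failure, with the
    manifest marking the stage that failed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def mark(stage: str, **info) -> None:
        manifest["stages"][stage] = {"status": "ok", **info}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    try:
        experiment = pd.read_csv(config.experiment_path)
        region = pd.read_csv(config.region_path)
        mark("load", experiment_rows=len(experiment), region_rows=len(region))

        selection, contribs, dominant = recommend(experiment, region, config)
        contribs.rename_axis("subregion").to_csv(out / "contributions.csv")
        dominant.to_csv(out / "dominant_variety.csv", index=False)
        sel_frame = pd.DataFrame({
            "variety": selection.varieties,
            "share_pct": np.round(selection.shares, 6),
        })
        sel_frame.to_csv(out / "selection.csv", index=False)
        mark("recommend", n_selected=len(selection.varieties),
             total_share=float(selection.shares.sum()))
    except Exception as exc:
        manifest["stages"]["failed"] = {"status": "error", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    return manifest
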