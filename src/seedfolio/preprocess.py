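"""Trial-table preprocessing: yield-ratio filtering, duplicate merging,
PI imputation, and feature assembly.

The pipeline order is fixed: ``ydt_filter`` -> ``merge_duplicates`` ->
``impute_pi`` -> ``assemble_features``. Varieties are screened on the ratio
of their yield to the commercial check variety's yield grown alongside them;
a variety survives iff its mean ratio is at least the yield-difference
threshold (YDT), boundary inclusive. Observations sharing (farm, planting
date, variety, year) are merged to their mean yield, and missing soil
productivity index (PI) values are replaced by the mean of the observed
ones (kept fractional).
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import AllVarietiesEliminatedError, ConfigError, SchemaError

log = logging.getLogger(__name__)

#: the 15 model predictors (everything also available for the region)
FEATURE_COLUMNS = [
    "variety", "year", "latitude", "longitude", "ph", "cec", "organic_matter",
    "clay", "silt", "sand", "temperature", "precipitation", "solar",
    "area", "pi",
]

NUMERIC_FEATURES = [c for c in FEATURE_COLUMNS if c != "variety"]

#: columns never fed to the model (targets / not present for the region)
DROP_COLUMNS = ["yield", "check_yield", "yield_difference",
                "planting_date", "soil_class"]

DUPLICATE_KEY = ["farm", "planting_date", "variety", "year"]


def ydt_filter(trials: pd.DataFrame, ydt: float
               ) -> tuple[set[str], pd.DataFrame]:
    """Keep varieties whose mean yield / check-yield ratio is >= ``ydt``.

    Returns the kept variety set and the filtered table. The kept set is
    monotonically non-increasing in ``ydt``. Raises
    :class:`AllVarietiesEliminatedError` if nothing survives.
    """
    for col in ("variety", "yield", "check_yield"):
        if col not in trials.columns:
            raise SchemaError(f"missing required column: {col}")
    if (trials["check_yield"] <= 0).any():
        raise ConfigError("check_yield must be positive for every trial")
    ratio = trials["yield"] / trials["check_yield"]
    mean_ratio = ratio.groupby(trials["variety"]).mean()
    kept = set(mean_ratio.index[mean_ratio >= ydt])
    if not kept:
        raise AllVarietiesEliminatedError(
            f"YDT {ydt} eliminated all {mean_ratio.size} varieties")
    filtered = trials[trials["variety"].isin(kept)].reset_index(drop=True)
    log.info("ydt_filter(%.3f): kept %d/%d varieties, %d/%d rows",
             ydt, len(kept), mean_ratio.size, len(filtered), len(trials))
    return kept, filtered


def merge_duplicates(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing (farm, planting_date, variety, year).

    Each group becomes one row with the group-mean yield and check yield;
    covariates come from the group's first row (identical by construction —
    a conflict is logged and the first row wins). Missing planting dates
    participate as their own key value. Idempotent.
    """
    key_cols = [c for c in DUPLICATE_KEY if c in trials.columns]
    if not key_cols:
        raise SchemaError("missing duplicate-key columns")
    dup_mask = trials.duplicated(key_cols, keep=False)
    if not dup_mask.any():
        return trials.reset_index(drop=True)

    covariate_cols = [c for c in trials.columns
                      if c not in key_cols + ["yield", "check_yield"]]
    conflicts = (
        trials.loc[dup_mask]
        .groupby(key_cols, dropna=False, sort=False)[covariate_cols]
        .nunique()
    )
    n_conflicts = int((conflicts > 1).any(axis=1).sum())
    if n_conflicts:
        log.warning("merge_duplicates: %d duplicate groups had conflicting "
                    "covariates; first row's values used", n_conflicts)

    agg = {c: "first" for c in trials.columns if c not in key_cols}
    agg["yield"] = "mean"
    agg["check_yield"] = "mean"
    merged = (
        trials.groupby(key_cols, dropna=False, sort=False, as_index=False)
        .agg(agg)
    )
    merged = merged[list(trials.columns)]
    log.info("merge_duplicates: %d -> %d rows", len(trials), len(merged))
    return merged.reset_index(drop=True)


def impute_pi(trials: pd.DataFrame) -> pd.DataFrame:
    """Replace missing PI by the mean of observed PIs (kept fractional)."""
    if "pi" not in trials.columns:
        raise SchemaError("missing required column: pi")
    observed = trials["pi"].dropna()
    if observed.empty:
        raise ConfigError("cannot impute PI: no observed values")
    out = trials.copy()
    n_missing = int(out["pi"].isna().sum())
    if n_missing:
        out["pi"] = out["pi"].fillna(float(observed.mean()))
        log.info("impute_pi: filled %d missing values with %.4f",
                 n_missing, observed.mean())
    return out


def assemble_features(trials: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Project trials onto the 15 model predictors; return (X, yield)."""
    missing = [c for c in FEATURE_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if "yield" not in trials.columns:
        raise SchemaError("missing required column: yield")
    X = trials[FEATURE_COLUMNS].copy()
    X["variety"] = X["variety"].astype(str)
    if X[NUMERIC_FEATURES].isna().any().any():
        bad = [c for c in NUMERIC_FEATURES if X[c].isna().any()]
        raise SchemaError(f"missing values remain in: {', '.join(bad)} "
                          "(run impute_pi first)")
    y = trials["yield"].astype(float).rename("yield")
    return X, y


def preprocess(trials: pd.DataFrame, ydt: float
               ) -> tuple[pd.DataFrame, set[str]]:
    """Full pipeline: filter -> merge -> impute. Returns (table, kept set)."""
    kept, filtered = ydt_filter(trials, ydt)
    merged = merge_duplicates(filtered)
    return impute_pi(merged), kept


def to_numeric_frame(X: pd.DataFrame) -> pd.DataFrame:
    """Numeric block of a feature table (drops the categorical variety)."""
    return X[NUMERIC_FEATURES].astype(float)
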