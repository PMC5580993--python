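"""Global sensitivity and uncertainty analysis of a fitted yield model.

Two complementary techniques:

* **Morris elementary-effects screening** — r randomized one-at-a-time
  trajectories through a p-level grid on the unit hypercube; each factor's
  mean absolute elementary effect (mu*) measures direct influence and the
  standard deviation (sigma) measures involvement in interactions. Costs
  exactly r*(k+1) model evaluations.

* **Variance-based Sobol' indices via Saltelli's scheme** — a
  quasi-random design of exactly M*(2k+2) rows (two base blocks A and B
  from a scrambled Sobol' sequence plus the k column-swapped blocks in
  each direction) from which first-order (S_i), total-order (S_Ti),
  and closed second-order (S_ij) indices are estimated. The interaction
  index is S_Ii = S_Ti - S_i, so the identity S_Ti = S_i + S_Ii holds by
  construction. Estimates are reported raw (they can be slightly
  negative); optional bootstrap percentile intervals quantify estimator
  noise.

Factors are uniform on data-derived [min, max] bounds. A categorical
factor (the variety label) is sampled as a continuous uniform over its
index range and rounded to the nearest level at evaluation time.

The uncertainty analysis simply summarises the Monte-Carlo outputs
(histogram density, empirical CDF, quantiles) and is designed to reuse
the Saltelli sample's model evaluations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import ConfigError, NumericalError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Factor:
    name: str
    low: float
    high: float
    levels: tuple[str, ...] | None = None  # categorical label lookup

    def __post_init__(self):
        if not self.low < self.high:
            raise ConfigError(
                f"factor {self.name!r}: need low < high, got "
                f"[{self.low}, {self.high}]")


@dataclass(frozen=True)
class FactorSpace:
    """Uniform box over k factors, with optional categorical lookups."""

    factors: tuple[Factor, ...]

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, columns: list[str],
                       categorical: tuple[str, ...] = ("variety",)
                       ) -> "FactorSpace":
        """Bounds = column min/max; categorical columns become index ranges."""
        factors = []
        for col in columns:
            if col in categorical:
                levels = tuple(sorted(df[col].astype(str).unique()))
                if len(levels) < 2:
                    raise ConfigError(f"categorical factor {col!r} needs >= 2 "
                                      "levels")
                factors.append(Factor(col, 0.0, float(len(levels) - 1),
                                      levels=levels))
            else:
                lo, hi = float(df[col].min()), float(df[col].max())
                factors.append(Factor(col, lo, hi))
        return cls(tuple(factors))

    def transform(self, U: np.ndarray) -> pd.DataFrame:
        """Map unit-hypercube rows to a feature table with named columns."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if U.shape[1] != self.k:
            raise ConfigError(f"expected {self.k} columns, got {U.shape[1]}")
        data = {}
        for j, f in enumerate(self.factors):
            x = f.low + U[:, j] * (f.high - f.low)
            if f.levels is not None:
                idx = np.clip(np.rint(x).astype(int), 0, len(f.levels) - 1)
                data[f.name] = np.asarray(f.levels, dtype=object)[idx]
            else:
                data[f.name] = x
        return pd.DataFrame(data)


@dataclass
class MorrisResult:
    factors: list[str]
    mu_star: np.ndarray
    sigma: np.ndarray
    r: int
    n_evaluations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"factor": self.factors, "mu_star": self.mu_star,
                             "sigma": self.sigma})

    def top(self, n: int = 7) -> list[str]:
        """The n most important factors by mu* (screening cutoff)."""
        order = np.argsort(-self.mu_star, kind="stable")
        return [self.factors[i] for i in order[:n]]


@dataclass
class SobolResult:
    factors: list[str]
    s1: np.ndarray              # first order
    s_total: np.ndarray         # total order
    s_interaction: np.ndarray   # S_Ti - S_i
    s2: np.ndarray              # (k, k) closed second order, NaN on diagonal
    M: int
    n_evaluations: int
    s1_ci: np.ndarray | None = None      # (k, 2) percentile bootstrap
    s_total_ci: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "factor": self.factors, "s1": self.s1, "s_total": self.s_total,
            "s_interaction": self.s_interaction,
        })


@dataclass
class UncertaintyResult:
    outputs: np.ndarray
    bin_edges: np.ndarray
    density: np.ndarray          # integrates to 1 over the bins
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray
    quantiles: dict[float, float] = field(default_factory=dict)


def _evaluate(model, space: FactorSpace, U: np.ndarray) -> np.ndarray:
    X = space.transform(U)
    return np.asarray(model.predict(X), dtype=float)


def morris_sample(k: int, r: int, rng: np.random.Generator,
                  p: int = 4) -> np.ndarray:
    """r randomized Morris trajectories on a p-level grid in [0,1]^k.

    Returns an (r*(k+1), k) array; consecutive blocks of k+1 rows form one
    trajectory in which exactly one coordinate changes by +-delta per step,
    delta = p / (2(p-1)).
    """
    delta = p / (2.0 * (p - 1))
    grid = np.arange(p // 2) / (p - 1)  # base values that can move up by delta
    blocks = []
    for _ in range(r):
        base = rng.choice(grid, size=k)
        order = rng.permutation(k)
        direction = rng.choice([-1.0, 1.0], size=k)
        # flip directions that would leave [0,1]
        for j in range(k):
            if base[j] + direction[j] * delta < -1e-12:
                direction[j] = 1.0
            elif base[j] + direction[j] * delta > 1 + 1e-12:
                direction[j] = -1.0
        x = base.copy()
        traj = [x.copy()]
        for j in order:
            x = x.copy()
            x[j] += direction[j] * delta
            traj.append(x.copy())
        blocks.append(np.vstack(traj))
    return np.clip(np.vstack(blocks), 0.0, 1.0)


def morris_screen(model, space: FactorSpace, r: int = 10, seed: int = 0,
                  p: int = 4) -> MorrisResult:
    """Elementary-effects screening; exactly r*(k+1) model evaluations.

    Effects are finite differences in the rescaled [0,1] coordinates (the
    step's sign divides out), so mu* is in output units per full factor
    range.
    """
    if r < 2:
        raise ConfigError("need r >= 2 trajectories")
    rng = np.random.default_rng(seed)
    k = space.k
    design = morris_sample(k, r, rng, p=p)
    outputs = _evaluate(model, space, design)
    effects = np.empty((r, k))
    for t in range(r):
        block = design[t * (k + 1):(t + 1) * (k + 1)]
        f = outputs[t * (k + 1):(t + 1) * (k + 1)]
        for step in range(k):
            diff = block[step + 1] - block[step]
            j = int(np.argmax(np.abs(diff)))
            effects[t, j] = (f[step + 1] - f[step]) / diff[j]
    mu_star = np.abs(effects).mean(axis=0)
    sigma = effects.std(axis=0, ddof=1)
    return MorrisResult(space.names, mu_star, sigma, r, len(design))


def saltelli_sample(space_or_k, M: int, seed: int = 0) -> np.ndarray:
    """Saltelli design with exactly M*(2k+2) rows on the unit hypercube.

    Row layout: block A (M rows), block B (M rows), then AB_i for
    i = 1..k (A with column i taken from B) and BA_i for i = 1..k.
    A power-of-two M keeps the underlying Sobol' sequence balanced; other
    values are accepted with a logged warning.
    """
    k = space_or_k.k if isinstance(space_or_k, FactorSpace) else int(space_or_k)
    if M < 2:
        raise ConfigError("need base sample M >= 2")
    if M & (M - 1):
        log.warning("saltelli_sample: M=%d is not a power of two; the "
                    "Sobol' sequence loses balance", M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy also warns on non-power-of-2
        base = qmc.Sobol(d=2 * k, scramble=True, seed=seed).random(M)
    A, B = base[:, :k], base[:, k:]
    blocks = [A, B]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(k):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    return np.vstack(blocks)


def _sobol_from_blocks(fA, fB, fAB, fBA, V):
    M = len(fA)
    k = fAB.shape[1]
    s1 = np.array([np.mean(fB * (fAB[:, i] - fA)) for i in range(k)]) / V
    st = np.array([0.5 * np.mean((fA - fAB[:, i]) ** 2)
                   for i in range(k)]) / V
    s2 = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            vij = np.mean(fBA[:, i] * fAB[:, j] - fA * fB) / V
            s2[i, j] = s2[j, i] = vij - s1[i] - s1[j]
    return s1, st, s2


def sobol_indices(outputs: np.ndarray, k: int, M: int,
                  factors: list[str] | None = None,
                  n_boot: int = 0, seed: int = 0,
                  ci_level: float = 0.95) -> SobolResult:
    """Saltelli/Jansen estimators from outputs ordered as saltelli_sample.

    Estimates are reported raw — small negative values are sampling noise,
    not clipped away. ``n_boot`` > 0 adds percentile bootstrap intervals
    for S_i and S_Ti (resampling the M design rows).
    """
    outputs = np.asarray(outputs, dtype=float)
    expected = M * (2 * k + 2)
    if outputs.shape != (expected,):
        raise ConfigError(
            f"expected {expected} outputs (= M(2k+2)), got {outputs.shape}")
    fA = outputs[:M]
    fB = outputs[M:2 * M]
    fAB = outputs[2 * M:(2 + k) * M].reshape(k, M).T
    fBA = outputs[(2 + k) * M:].reshape(k, M).T
    V = float(np.var(np.concatenate([fA, fB]), ddof=1))
    if V <= 0:
        raise NumericalError("zero output variance; Sobol' indices undefined")
    s1, st, s2 = _sobol_from_blocks(fA, fB, fAB, fBA, V)
    names = factors if factors is not None else [f"x{i+1}" for i in range(k)]

    s1_ci = st_ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        s1_bs = np.empty((n_boot, k))
        st_bs = np.empty((n_boot, k))
        for b in range(n_boot):
            idx = rng.integers(0, M, M)
            Vb = float(np.var(np.concatenate([fA[idx], fB[idx]]), ddof=1))
            if Vb <= 0:
                s1_bs[b] = st_bs[b] = np.nan
                continue
            s1_b, st_b, _ = _sobol_from_blocks(
                fA[idx], fB[idx], fAB[idx], fBA[idx], Vb)
            s1_bs[b], st_bs[b] = s1_b, st_b
        lo, hi = 50 * (1 - ci_level), 50 * (1 + ci_level)
        s1_ci = np.nanpercentile(s1_bs, [lo, hi], axis=0).T
        st_ci = np.nanpercentile(st_bs, [lo, hi], axis=0).T

    return SobolResult(names, s1, st, st - s1, s2, M, expected,
                       s1_ci, st_ci)


def uncertainty(outputs: np.ndarray, bins: int = 50,
                quantile_levels: tuple[float, ...] = (0.05, 0.25, 0.5,
                                                      0.75, 0.95)
                ) -> UncertaintyResult:
    """Histogram density + empirical CDF + quantiles of Monte-Carlo outputs."""
    outputs = np.asarray(outputs, dtype=float)
    if len(outputs) < 100:
        raise ConfigError("need >= 100 outputs for a stable distribution")
    if np.ptp(outputs) == 0:
        edges = np.array([outputs[0] - 0.5, outputs[0] + 0.5])
        density = np.array([1.0])
    else:
        density, edges = np.histogram(outputs, bins=bins, density=True)
    xs = np.sort(outputs)
    ys = np.arange(1, len(xs) + 1) / len(xs)
    quantiles = {q: float(np.quantile(outputs, q)) for q in quantile_levels}
    return UncertaintyResult(outputs, edges, density, xs, ys, quantiles)
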