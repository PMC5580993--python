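"""Long-only mean-variance efficient frontier and PI-indexed selection.

The Markowitz program: for a target expected yield t, minimise the
portfolio variance w' Sigma w subject to w >= 0, sum(w) = 1 and
w' mu = t. Sweeping t linearly from the minimum-variance portfolio's
return up to max(mu) traces the efficient frontier (default 100 points,
each Pareto-optimal: no feasible portfolio has higher yield at equal or
lower risk). Risk is the portfolio yield standard deviation
sqrt(w' Sigma w), in bu/ac.

The soil productivity index (PI, integer 0-19) acts as a risk-tolerance
proxy: the frontier's risk range is cut into 20 linearly spaced levels
indexed by PI, and a (possibly fractional) PI maps by linear
interpolation to a risk budget; the selected portfolio is the
highest-yield frontier point within budget.

The QP is solved with SLSQP and analytic gradients, warm-started along
the sweep; any solver meeting the 1e-8 tolerance would be conformant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import ConfigError, NumericalError

log = logging.getLogger(__name__)

N_RISK_LEVELS = 20


@dataclass
class Portfolio:
    varieties: list[str]
    weights: np.ndarray
    expected_yield: float
    risk: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.varieties)


@dataclass
class Frontier:
    """Pareto-optimal portfolios ordered by (non-decreasing) expected yield."""

    portfolios: list[Portfolio]

    @property
    def risks(self) -> np.ndarray:
        return np.array([p.risk for p in self.portfolios])

    @property
    def yields(self) -> np.ndarray:
        return np.array([p.expected_yield for p in self.portfolios])

    @property
    def min_risk(self) -> Portfolio:
        return self.portfolios[int(np.argmin(self.risks))]

    @property
    def max_return(self) -> Portfolio:
        return self.portfolios[-1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.portfolios):
            row = {"point": i, "risk": p.risk, "expected_yield":
                   p.expected_yield}
            row.update({f"w_{v}": w for v, w in zip(p.varieties, p.weights)})
            rows.append(row)
        return pd.DataFrame(rows)


def _solve_qp(sigma: np.ndarray, mu: np.ndarray, target: float | None,
              x0: np.ndarray, tol: float = 1e-10) -> np.ndarray | None:
    n = len(mu)
    # rescale the return constraint to the weights' O(1) scale; SLSQP's
    # linesearch is unreliable when constraint Jacobians differ by ~1e2
    scale = max(float(np.abs(mu).max()), 1.0)
    mu_s = mu / scale
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                    "jac": lambda w: np.ones(n)}]
    if target is not None:
        target_s = target / scale
        constraints.append({"type": "eq",
                            "fun": lambda w: w @ mu_s - target_s,
                            "jac": lambda w: mu_s})
    for ftol in (tol, 1e-9):
        res = minimize(
            lambda w: w @ sigma @ w, x0, jac=lambda w: 2.0 * sigma @ w,
            bounds=[(0.0, 1.0)] * n, constraints=constraints,
            method="SLSQP", options={"maxiter": 300, "ftol": ftol},
        )
        if res.success:
            w = np.clip(res.x, 0.0, None)
            return w / w.sum()
    return None


def efficient_frontier(mu: np.ndarray, sigma: np.ndarray,
                       varieties: list[str] | None = None,
                       n_points: int = 100) -> Frontier:
    """Trace the long-only efficient frontier with ``n_points`` targets.

    ``sigma`` must be PSD (run the covariance repair first); a negative
    eigenvalue beyond tolerance raises. A single variety yields a one-point
    frontier. Numerically infeasible targets are dropped with a warning.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = len(mu)
    if n == 0:
        raise ConfigError("need at least one variety")
    if sigma.shape != (n, n):
        raise ConfigError("mu / sigma dimensions disagree")
    if varieties is None:
        varieties = [f"V{i+1}" for i in range(n)]
    if n == 1:
        risk = float(np.sqrt(max(sigma[0, 0], 0.0)))
        return Frontier([Portfolio(list(varieties), np.array([1.0]),
                                   float(mu[0]), risk)])
    min_eig = float(np.linalg.eigvalsh(sigma)[0])
    if min_eig < -1e-6:
        raise NumericalError(
            f"covariance not PSD (min eigenvalue {min_eig:.3e}); "
            "repair it with nearest_psd first")

    def make(w: np.ndarray) -> Portfolio:
        return Portfolio(list(varieties), w, float(w @ mu),
                         float(np.sqrt(max(w @ sigma @ w, 0.0))))

    x0 = np.full(n, 1.0 / n)
    w_mvp = _solve_qp(sigma, mu, None, x0)
    if w_mvp is None:
        raise NumericalError("minimum-variance problem failed to converge")
    r_lo, r_hi = float(w_mvp @ mu), float(mu.max())
    if r_hi - r_lo < 1e-12:
        return Frontier([make(w_mvp)])

    targets = np.linspace(r_lo, r_hi, n_points)
    # the top target's solution is the corner portfolio: all weight on the
    # highest-mu variety (min variance among exact ties); SLSQP is unreliable
    # at this degenerate vertex, so construct it analytically
    tied = np.flatnonzero(mu >= r_hi - 1e-12)
    top = int(tied[np.argmin(np.diag(sigma)[tied])])
    w_top = np.zeros(n)
    w_top[top] = 1.0

    portfolios: list[Portfolio] = []
    w_prev = w_mvp
    dropped = 0
    for t in targets[:-1]:
        w = _solve_qp(sigma, mu, float(t), w_prev)
        if w is None:
            w = _solve_qp(sigma, mu, float(t), np.full(n, 1.0 / n))
        if w is None:
            dropped += 1
            continue
        w_prev = w
        portfolios.append(make(w))
    portfolios.append(make(w_top))
    if dropped:
        log.warning("efficient_frontier: dropped %d infeasible targets",
                    dropped)
    if not portfolios:
        raise NumericalError("no frontier point converged")
    portfolios.sort(key=lambda p: p.expected_yield)
    return Frontier(portfolios)


def risk_levels(frontier: Frontier) -> np.ndarray:
    """20 linearly spaced risk thresholds spanning the frontier's risk range
    (all equal for a degenerate one-point frontier), indexed by PI 0-19."""
    if not frontier.portfolios:
        raise ConfigError("empty frontier")
    risks = frontier.risks
    return np.linspace(float(risks.min()), float(risks.max()), N_RISK_LEVELS)


def select_by_pi(frontier: Frontier, levels: np.ndarray,
                 pi: float) -> Portfolio:
    """Highest-yield frontier portfolio whose risk fits the PI's budget.

    The budget interpolates the 20 thresholds linearly at the (possibly
    fractional) PI. If numerics leave no portfolio within budget, the
    minimum-risk portfolio is returned.
    """
    if not (0.0 <= pi <= 19.0):
        raise ConfigError(f"pi must be in [0, 19], got {pi}")
    budget = float(np.interp(pi, np.arange(N_RISK_LEVELS), levels))
    risks = frontier.risks
    ok = np.flatnonzero(risks <= budget + 1e-9)
    if ok.size == 0:
        return frontier.min_risk
    yields = frontier.yields[ok]
    return frontier.portfolios[int(ok[np.argmax(yields)])]
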