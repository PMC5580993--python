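# Methods

This note documents the models and procedures `seedfolio` implements,
the defaults it fixes, the numerical choices behind them, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

A seed retailer (or a region full of growers) must commit before the
season to at most five soybean varieties, each with a share of at least
10%. Yield depends on genotype, environment (weather, soil, location)
and their interaction; next season's weather is unknown. The package
treats each historical year's growing-season weather as one equiprobable
*scenario*, predicts every variety's yield in every subregion under
every scenario, and chooses variety portfolios that trade expected yield
against across-scenario standard deviation.

## Preprocessing

Trials carry both the test variety's yield and a commercial check
variety's yield grown alongside it. A variety is retained iff the
**mean** of its yield/check-yield ratios is at least the yield-difference
threshold (YDT), boundary inclusive. "Consistently worse than the check"
admits several formalisations (mean, median, every-year); the mean is
the only aggregate consistent with sweeping a single scalar threshold,
and it is what the brute-force YDT search (0.80–1.05, step 0.01)
optimises. Observations sharing (farm, planting date, variety, year) are
merged to their mean yield and mean check yield — the year is part of
the key so that identical dates in different years cannot collide — and
missing soil-productivity-index values are replaced by the mean of the
observed ones, kept fractional. The fixed order is filter → merge →
impute → feature assembly; the model sees 15 predictors (variety, year,
latitude, longitude, pH, CEC, organic matter, clay, silt, sand,
temperature, precipitation, solar radiation, area, PI).

## Yield regression

Four regressors share one `fit`/`predict` interface:

| method | encoding of variety | defaults |
|---|---|---|
| `mlr` | one-hot | — |
| `knn` | one-hot + standardized numerics | k = 5 |
| `rf`  | ordinal code (tree splits) | 100 trees, 5 features/split |
| `whr` | native label lookup | bandwidth h = 2.0 |

`whr` (weighted-histograms regression) estimates a query's yield as a
Gaussian-kernel weighted mean over the query variety's training rows:
w_j = exp(−‖z_j − z_q‖²/2h²) on standardized numeric features, estimate
Σ w_j y_j / Σ w_j. As h → ∞ this tends to the variety's plain mean; an
optional `n_bins` reinstates the explicit histogram discretization
(mass-weighted bin centres). A variety absent from training has no
histogram and raises; the other models fall back to the training-mean
prediction with a warning.

Validation is **leave-one-year-out**: observations within a year share
weather and are strongly correlated, so random k-fold splits leak the
test year's conditions and overstate accuracy. One fold per calendar
year; test rows whose variety never appears in the training years are
skipped and counted; fold metrics (RMSE, MAE, Pearson r, Spearman ρ —
the latter computed as Pearson of ranks, which equals the classical
1 − 6Σd²/(N(N²−1)) form on untied data) are averaged unweighted.

## Global sensitivity and uncertainty analysis

Factors are uniform on data-derived [min, max] bounds; the categorical
variety factor is sampled as a continuous uniform over its index range
and rounded to the nearest level at evaluation time.

**Morris screening** uses r randomized one-at-a-time trajectories on a
p = 4 level grid (step Δ = p/(2(p−1)) = 2/3) in the unit hypercube,
costing exactly r(k+1) model evaluations. Elementary effects are finite
differences in the rescaled coordinates; μ* (mean absolute effect)
measures direct influence, σ (their standard deviation, ddof = 1)
involvement in interactions. The screening cutoff (how many top-μ*
factors proceed to variance-based analysis) is a user parameter,
default 7.

**Sobol' indices** come from a Saltelli design of exactly M(2k+2) rows:
base blocks A and B are the halves of a scrambled 2k-dimensional Sobol'
sequence, followed by the k column-swapped blocks in each direction.
Estimators: S_i = mean(f_B (f_ABi − f_A))/V; S_Ti = ½ mean((f_A −
f_ABi)²)/V (Jansen); closed second order from the BA/AB cross blocks.
The interaction index is defined as S_Ii = S_Ti − S_i, so the identity
S_Ti = S_i + S_Ii is structural. Estimates are reported raw — small
negative values are sampling noise and are deliberately not clipped;
optional percentile-bootstrap intervals (resampling design rows)
quantify the noise. A power-of-two M keeps the sequence balanced; other
values are accepted with a warning. Correctness is tested against the
Ishigami function's closed-form variance decomposition and against
additive/pure-product models.

Uncertainty analysis summarises the same Monte-Carlo outputs: histogram
density (integrating to 1), empirical CDF, quantiles.

## Scenario covariance

The prediction cube holds model predictions for every (variety, site,
scenario-year) cell; in evaluation mode on trial data, only cells with a
measured yield are unmasked. Expected yield per (variety, site) is the
unweighted mean over unmasked scenarios (scenarios are equiprobable).
Covariance between two varieties: flatten each variety's site × scenario
layer, drop every position masked in either vector, and take the sample
covariance (denominator n − 1) of the survivors; on complete cubes this
reduces exactly to the ordinary covariance of the flattened layers. One
global Σ is estimated from the whole cube while μ is site-local — local
expected yields with a regionally pooled risk structure.

Pairwise deletion does not guarantee positive semidefiniteness, and
entries with fewer than two joint observations are undefined. Repair:
undefined entries are filled with 0, then negative eigenvalues are
clipped at zero and the matrix symmetrized (tolerance 1e−8). Eigenvalue
clipping was chosen over Higham-style alternating projections because
its contract is directly testable and its error is immaterial next to
the sampling error of the covariance itself.

## Portfolio optimisation

Long-only, fully-invested Markowitz: minimise wᵀΣw subject to w ≥ 0,
Σw = 1, wᵀμ = t for 100 targets t spaced linearly from the
minimum-variance portfolio's return to max μ (return-spacing is the
standard frontier sweep). The QP is solved with SLSQP, analytic
gradients, warm starts along the sweep, and the return constraint
rescaled to the weights' O(1) magnitude (unscaled bu/ac coefficients
destabilise the linesearch). The max-return point is constructed
analytically — all weight on the highest-μ variety, lowest variance
among exact ties — because SLSQP misreports infeasibility at that
degenerate vertex. Solver tolerance 1e−10 with a 1e−9 retry; any QP
method meeting 1e−8 is conformant.

The frontier's risk range is divided into 20 linearly spaced levels
indexed by PI 0–19 (PI's own range), and a possibly fractional PI —
the global grid searches PI in steps of 0.25 — maps to a risk budget by
linear interpolation of the thresholds. The selected portfolio is the
highest-yield frontier point with risk within budget ("budget"
semantics rather than nearest-risk, respecting risk aversion); if
numerics leave none, the minimum-risk portfolio.

## Selection strategies and the Q statistic

Three strategies are evaluated with leave-one-year-out folds:

* **best** — area-weighted predicted yield per variety
  (p_i = Σ areaⱼ ŷⱼ / Σ areaⱼ over the farms growing i); pick argmax,
  ties to the lowest variety index.
* **local_pi** — per farm: frontier over the varieties grown there
  (farm-local μ, global Σ restricted), portfolio at the farm's own PI;
  aggregate contribution rows across farms area-weighted; drop shares
  below 10%, keep at most 5, renormalise.
* **global_pi** — as local_pi with one fixed PI everywhere.

Because many variety pairs never co-occur historically, Σ comes from
the prediction cube over all years without validation (the model that
feeds it is trained on everything; only μ respects the held-out year).
Realized portfolio yield Y_l = Σ y_k x̂_k uses the area-weighted real
yields; the improvement statistic is

    Q = mean over years of Y_l / m_l,   reported as 100·(Q − 1) %

with m_l the mean realized yield of all varieties planted that year. A
literal sum of seven yearly ratios would be ≈ 7, not a small percentage,
so the summation is read as the mean its surrounding prose describes.
"Risk" of a strategy is the standard deviation of Y_l across years
(bu/ac). Brute-force grids — YDT 0.80–1.05 step 0.01 (26 values), PI
0–19 step 0.25 (77 values) — maximise Q, ties toward the smaller
parameter; infeasible grid points are recorded as missing.

The region-level `recommend` run mirrors local_pi at subregion
granularity: model trained on all (filtered) trials, cube over
subregions × scenario years, per-subregion frontier at the subregion's
PI, area-weighted aggregation, truncation.

## Synthetic data generator

The generative yield model is

    yield = max(50 + effect_v + f_env(weather, soil)
                − κ((T − opt_v)/300)² + g_{v,f} + ε,  0.1)   [bu/ac]

with variety effects ~ Normal(0, 5), per-variety temperature optima
uniform over the regional climate range (the quadratic optimum reorders
varieties across warm and cool scenarios — the G×E structure that makes
diversification meaningful), a smooth environment response f_env
(precipitation with a concave optimum, solar, pH penalty around 6.5,
organic matter, silt), a per-(variety, farm) random interaction g, and
observation noise ε ~ Normal(0, noise_sd). The floor at 0.1 bu/ac is
part of the mean function (crop failure saturates rather than going
negative), so the oracle `TruthModel` reproduces generated yields
exactly when noise and g are switched off — the basis of the
recoverability tests. The check variety is the same model with a +1
bu/ac offset and its optimum at the climate centre.

Weather is season-aggregated directly (temperature as a growing-season
°C sum around 3200 ± 300, precipitation mm around 600, solar W/m²
around 42000): each year's anomaly is a smooth planar field over
latitude/longitude plus small site noise, so nearby sites share weather
trajectories while years differ enough to act as distinct scenarios.
Soil covariates are static per site with clay + silt + sand = 100
exactly and integer PI 0–19. Coverage is unbalanced (each variety on a
random ~half of farms, observed in ~60% of years); a configurable
fraction of rows duplicate their key with independent noise, and a
fraction lose PI. Planting date and soil class are generated but carry
no signal — they exist so the preprocessing rules have work to do.
Defaults are desk-scale (50 varieties, 40 farms, 100 subregions, 7
experiment years 2009–2015, 15 scenario years 2001–2015, noise 3 bu/ac,
5% duplicates, 5% missing PI) and scale up by config. All tables are
byte-reproducible from the seed.

What the generator does **not** emulate: daily weather series (only
season sums), spatially autocorrelated soil, non-stationary climate,
measurement error in covariates, and any real genetic structure among
varieties. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under controlled G×E regimes, not
predictive skill on real trial networks.

## Observed phenomenology and limitations

* With clearly separated variety means, the single-best strategy
  attains the highest Q by construction — Q rewards concentrating on
  the argmax, and any hedge dilutes it. The portfolio strategies'
  advantage is in **risk**: under anticorrelated varieties the local-PI
  portfolio's across-year standard deviation drops to a fraction of the
  single variety's (≈ 0.3× in the seeded acceptance run) at a modest
  yield cost. A freely optimised global PI consistently matches or
  beats local PI in Q. Orderings between the best-variety benchmark and
  the portfolio strategies beyond that are data-dependent and are not
  asserted.
* Pairwise-complete covariance is consistent but not efficient; with
  very sparse cubes the PSD repair can move the matrix noticeably (the
  repair is flagged on the result).
* The WHR bandwidth is fixed, not tuned; the RF uses the stated 100
  trees / 5 features per split without hyperparameter search.
* Evaluation problem sizes in the tests and acceptance script are
  desk-scale by design (tens of varieties, tens of farms/subregions);
  the algorithms scale to the full problem (thousands of subregions) by
  configuration, at proportional cost in QP solves.
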