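# Methods

`tdcal` estimates *time-varying* cultivar parameters of a crop
simulation model from a multi-decade series of observed county yields.
Crop-model parameters encoding genotype traits (thermal-time phase
durations, radiation use efficiency, grain number and growth
potential, ...) are not constant over decades of plant breeding;
calibrating a single vector against 30+ years of yields therefore
confounds genetic change with model error. The framework has three
parts: an overlapping time-window scheme, a parallel Bayesian
optimizer for the per-window inverse problems, and an autoregressive
trend model that turns the per-year estimates into a test-year
forecast.

## Window scheme

For `Y` training years and a main-window length `n` (years), main
windows `W_i` cover years `i..i+n-1` for `i = 1..Y-n+1`, so successive
windows overlap by `n-1` years. Short auxiliary windows pad both
edges: head auxiliaries cover years `1..i-1` (`i = 2..n`), tail
auxiliaries cover `i+n..Y` (`i = Y-2n+2..Y-n`). This is the unique
edge-padding under which every year is covered by exactly `n` windows
and each window's combination weight equals its length. The year-`y`
parameter vector is

    P̄_y = Σ_{W ∋ y} len(W) · p_W / Σ_{W ∋ y} len(W),

which in the interior (`n ≤ y ≤ Y-n+1`) reduces to the unweighted mean
of the `n` covering main windows. The implementation evaluates the
three-branch edge/interior form explicitly; the test suite checks it
against a brute-force covering-window enumeration. `n` trades bias
(large `n`: parameters over-smoothed) against variance (small `n`:
single noisy years dominate); the default is `n = 5`, the value found
best in the corn-belt case study this framework targets, and the
configuration requires `Y ≥ 2n` because the tail-auxiliary index range
is ill-formed below that.

Each window's parameters are calibrated by minimizing the RMSE (kg/ha)
between simulated and observed county yields over the window's years,
with the candidate vector held constant within the window. Auxiliary
windows get the same optimizer budget as main windows.

## Parallel Bayesian optimization

Each per-window problem is a low-budget black-box minimization over a
9-dimensional box, the classic BO regime — but BO is sensitive to the
choice of acquisition function and GP kernel, neither of which can be
tuned when every objective evaluation is a full crop-model run. PBO
hedges that choice: `N` BO instances, each with its own acquisition
family (expected improvement, probability of improvement, lower
confidence bound) and kernel (Matérn-5/2, squared-exponential,
Matérn-3/2 available), propose one point each per iteration, and all
`N` evaluations are pooled into a single shared history that every
instance trains on at the next iteration. Sharing is synchronous —
the pool is extended once per iteration after all `N` proposals are
evaluated — and the total budget is `init + N·T` evaluations from a
Latin-hypercube initial design shared by all instances (they share
every evaluation anyway). Classic BO is the `N = 1` special case and
is implemented as exactly that.

Numerical choices:

- Inputs are scaled to `[0,1]^d` by the parameter bounds; objectives
  are standardized to zero mean / unit variance at every refit.
- GP hyperparameters start from each instance's specification and are
  refit by marginal likelihood (`tune_by_likelihood`, default on;
  scikit-learn's GP regressor does the fitting).
- Noise jitter starts at 1e-6 (standardized scale) and escalates by
  decades to 1e-2 on a Cholesky failure; coincident training inputs
  are merged (objective values averaged) with a logged warning.
- The acquisition is maximized by L-BFGS-B from `R = 10`
  uniform-random starts (5 in the desk-scale pipeline runs); the
  start points are retained as fallback candidates, so the proposal
  is never worse than the best start. Gradients are central finite
  differences evaluated in one batched posterior call.
- A proposal within 1e-8 (scaled) of an evaluated or pending point is
  replaced by a uniform random point. Acquisition defaults: ξ = 0.01
  (EI/PI), κ = 2.0 (LCB).
- Per-instance RNG streams are spawned from the master seed, so runs
  are bit-reproducible and composable in `N`.
- An objective that raises is retried once at the same point, then
  replaced by a random in-bounds point (logged).
- The stop rule is the iteration cap `T`; an optional
  improvement-threshold stop is available but off by default.

Wall-clock parallelism is not the contract — the semantics are the
synchronous shared pool; instances run sequentially within an
iteration.

## Trend model and forecasting

For each location and each parameter, the yearly series `P̄_y` is
modeled as an autoregression

    P̄_y = β₀ + Σ_{i=1..t} β_i P̄_{y-i} + ε_y.

The order `t` is the largest lag whose partial autocorrelation
(sequential-regression definition, statsmodels `pacf(method="ols")`)
exceeds the 95% band `1.96/√Y`, capped at `min(5, ⌊Y/6⌋)` and falling
back to `t = 1` when no lag is significant — the textbook PACF cutoff,
chosen because the framework itself prescribes PACF-based selection
without fixing a rule. Coefficients are fitted by conditional least
squares (OLS on the lagged design), which is exact on deterministic
recursions and degrades to an intercept-only fit, flagged, when the
design is singular (constant series). The Augmented Dickey–Fuller
test (constant term, AIC-chosen augmentation up to `(Y-1)/3` lags) is
reported as a diagnostic of trend autocorrelation only; it never gates
the AR fit, since near-unit-root behavior is expected of slowly
drifting traits. One-step forecasts are recursive substitutions,
clipped into the parameter's physiological bounds and flagged when
clipping occurs. A linear-regression-on-year fallback fitter is
provided for explicitly linear trends. Trends are fitted per location
(not on a cross-location average), matching the per-location
calibration; county-level reporting happens downstream.

County test-year predictions are the *median* of the county's
location-level predictions, which is robust to a single outlier
location.

## Synthetic crop simulator

`toycrop` stands in for a process-based crop model so the whole
pipeline can be exercised with known ground truth. It emulates the
shape of the motivating case study: 5 counties × 5 soil-distinct
locations, 34 years (1985–2018), county-level observed yields rising
≈1.5-fold. Yield is

    yield = base_potential × soil_factor × G(θ) × (1 + anomaly),

with `G(θ) = 1 + Σ_j w_j (u_j - 0.5)` on bound-scaled parameters
`u_j ∈ [0,1]` and fixed weights (rue 0.30, head_grain_no_max 0.20,
grain_gth_rate 0.20, tt_flower_to_maturity 0.15; −0.05 each for
tt_emerg_to_endjuv, tt_flower_to_start_grain, leaf_app_rate1; 0 for
n_conc_crit_grain and transp_eff_cf). The weight signs follow the
directions these traits have drifted under maize breeding; the two
zero weights mirror the traits reported as flat. Because `Σ|w_j| = 1`,
`G` ranges over `[0.5, 1.5]`, and because yield depends on `θ` only
through `G`, the simulator is *equifinal by construction*: recovery is
assessed on `G(P̄_y)`, never on individual components — the same
identifiability ceiling a real crop model imposes, where many
parameter combinations yield identical output.

The true trajectory moves positive-weight parameters linearly from
`u = 0.3` to `0.7` over the period (negative-weight ones 0.7 → 0.3),
so `G(θ*(y))` rises linearly 0.8 → 1.2 — a 1.5-fold yield ratio
matching the historical increase in magnitude. Generator defaults:
county base potential Uniform(9000, 11000) kg/ha, soil factor
Uniform(0.85, 1.10) per location, county-year season anomaly
Normal(0, 0.08) (≈ the year-to-year coefficient of variation of
county maize yields), observation noise 250 kg/ha (≈2.5% of mean
yield — small enough for trend recovery, large enough that window
RMSE never reaches zero). Anomalies are drawn for `Y + 1` years so a
held-out test year can be simulated with the same environments.

What the simulator does *not* emulate: weather and soil-water
dynamics, management (planting density, N fertilization), nonlinear
parameter interactions, and heteroscedastic or autocorrelated
observation error. Passing recovery tests therefore demonstrate that
the windowing → PBO → AR chain recovers a smooth effective-parameter
trend through an equifinal response under realistic noise — not that
it identifies individual cultivar traits in a real crop model.

## Desk-scale problem sizes

The shipped checks run on one CPU: per-window PBO at `N = 3`
(EI/PI/LCB on Matérn-5/2), `T = 15`, 18 initial points, 5 restarts;
end-to-end recovery calibrates 3 of the 25 locations (one per county
in three counties, ≈2 min each), which already averages three
independent calibrations per year. The optimizer comparison uses a
100-evaluation budget on a 2-D quadratic over 20 seeds, compared at
the median. The published five-county RMSE table is included as data
(`tdcal.benchmarks`) so the reported head-to-head percent reductions
are recomputed, not restated.

## Known limitations

- The external-simulator adapter is an interface contract
  (`CropModelInterface`), not a shipped integration; the toy simulator
  is the only built-in model.
- Only AR and linear-on-year trend fitters are implemented; no
  ARIMA/seasonal models.
- No treatment of heteroscedastic observation noise in the GP; no
  asynchronous evaluation sharing; no trust-region BO.
- Forecast clipping at the bounds means a genuinely out-of-range trend
  saturates rather than extrapolates — by design, since out-of-range
  cultivar parameters are not physiologically meaningful.
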