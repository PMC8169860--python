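# tdcal — time-dependent crop-model parameter calibration

Crop simulation models (APSIM, DSSAT, ...) encode genotype traits as
*cultivar parameters*: thermal time between phenological stages,
radiation use efficiency, potential grain number, grain growth rate.
Over decades of plant breeding these traits drift, so calibrating a
single constant parameter vector against 30+ years of observed county
yields confounds genetic change with model error. `tdcal` is for crop
modelers who want to estimate *how the parameters themselves moved*
— and to use that trend to predict the next season.

The framework:

1. **Overlapping time-windows.** `Y` training years are covered by
   main windows of `n` years (successive windows overlap by `n-1`)
   plus short auxiliary windows at both edges, so every year is
   covered by exactly `n` windows. Each window's parameters are
   calibrated by minimizing the RMSE between simulated and observed
   county yields over its years. The year-`y` vector is the
   length-weighted average over the windows covering `y`:
   `P̄_y = Σ_{W∋y} len(W)·p_W / Σ_{W∋y} len(W)`, the unweighted mean
   of `n` main windows in the interior.
2. **Parallel Bayesian optimization (PBO).** Each window is a
   low-budget black-box minimization over a bounded box. Instead of
   betting on one acquisition function and kernel, `N` BO instances
   with heterogeneous acquisitions (EI, PI, LCB) and kernels
   (Matérn-5/2, RBF) each propose one point per iteration; all `N`
   evaluations go into a shared pool every instance trains on.
   Classic BO is the `N = 1` special case.
3. **Autoregressive trend forecasting.** Per location and parameter,
   `P̄_y = β₀ + Σ β_i P̄_{y−i} + ε_y` with the order chosen from the
   PACF (largest lag outside the 95% band), fitted by conditional
   least squares; the Augmented Dickey–Fuller statistic is reported
   as a diagnostic. The one-step forecast, clipped to the parameter
   bounds, drives the test-year simulation; county predictions are
   the median over the county's locations.

A synthetic crop simulator (`tdcal.toycrop`) with known ground truth
— 5 counties × 5 soils × 34 years, yields rising ≈1.5-fold, nine
bounded maize cultivar parameters with breeding-consistent trends —
stands in for a process-based model so the whole chain can be tested
for parameter recovery. Any simulator implementing the one-call
`CropModelInterface` contract can be plugged in instead. See
`docs/methods.md` for the model details and limitations.

## Worked example

```python
import numpy as np
from tdcal import (
    WindowingConfig, PBOConfig, default_instances, generate_dataset,
    ToyCropModel, calibrate, default_parameter_space,
)
from tdcal.pipeline import predict_test_year, county_predictions

space = default_parameter_space()
observed, envs, truth = generate_dataset(
    n_counties=1, n_soils=2, n_years=12, noise_sd=100.0, seed=4, space=space
)
result = calibrate(
    observed, envs, ToyCropModel(space),
    WindowingConfig(Y=12, n=3, first_year=1985),
    PBOConfig(instances=default_instances(2), T=4, init_design_size=10, restarts=3),
    space=space, seed=4,
)
g_rec, g_true = result.mean_g_series(), truth.g_series()
print("windows calibrated per location:", len(result.estimates[envs[0].location]))
print("median window RMSE (kg/ha): %.1f" % np.median(
    [e.objective for loc in result.locations for e in result.estimates[loc]]))
print("corr(G_recovered, G_true):  %.3f" % np.corrcoef(g_rec, g_true)[0, 1])
frame = predict_test_year(result, ToyCropModel(space), envs)
print("county 1997 forecast (kg/ha): %.0f" % county_predictions(frame).iloc[0])
```

prints

```
windows calibrated per location: 14
median window RMSE (kg/ha): 324.6
corr(G_recovered, G_true):  0.998
county 1997 forecast (kg/ha): 13685
```

The 12-year / 3-year-window scheme has 10 main + 4 auxiliary = 14
windows. The median calibrated window RMSE (325 kg/ha, ≈2.5% of mean
yield) sits at the observation-noise floor. Because the toy simulator
is equifinal — many parameter vectors give the same yield — recovery
is measured on the growth multiplier `G(θ)` that yields actually
depend on: the recovered yearly `G(P̄_y)` tracks the true rising
trend at correlation 0.998. The forecast 1997 county yield (13,685
kg/ha) continues the upward trend of the final training year (13,563
kg/ha observed in 1996).

The same pipeline is scriptable from the shell:

```bash
tdcal simulate  --config cfg.yaml --out data/
tdcal calibrate --data data/ --config cfg.yaml --out results/
tdcal forecast  --results results/ --data data/ --test-year 2019 --out pred.csv
tdcal evaluate  --pred pred.csv --obs obs.csv
```

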