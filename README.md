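# costsim

Simulation toolkit for a practical question in health-services research:
**which regression strategy best predicts skewed episode-level healthcare
costs, and how robust is each to misspecification?**  Episode costs (for
example 6-month oncology care episodes under an episode-based payment
model) are strongly right-skewed, heteroscedastic and occasionally
extreme, and payment models built on them must both estimate average
expenditure and identify the high-cost episodes above the 90th percentile.

`costsim` provides, as one seeded and reproducible pipeline:

* a **calibrated episode-cost simulator** — ten covariates with fixed
  marginals, a nonlinear log-dollar predictor
  y′ = b₀ + 0.05x₁ − 0.08x₂ + … − 0.75z₁² + 0.15z₂³ − 0.35x₈²/(1+x₈²) + 0.2x₃x₅,
  and four conditional outcome families (Gamma, Weibull, heteroscedastic
  log-normal, heavy-tailed log-normal), with the intercept calibrated in
  closed form so the expected cost matches a $27,329 dollar target;
* a **model zoo** behind one fit/predict contract:
  * Gamma GLM with log link, E[y|x] = exp(Xβ), fit by IRLS,
  * PLAQR — partially linear additive quantile regression minimising the
    check loss ρ_τ(u) = u(τ − 1{u<0}) at τ = 0.5 on the dollar scale,
  * random forest — 1000 bagged full-grown regression trees with mtry
    tuned by out-of-bag error,
  each regression available "correct" (B-splines + interaction) or
  "main_effects" (misspecified: linear terms only);
* **metrics**: RMSE and MAPE in dollars and CA, the percentage of true
  high-cost dollars captured by episodes predicted above the 90th-percentile
  threshold;
* a **bootstrap harness**: B resamples per scenario, refit-and-score with
  convergence accounting, plus a train/test overfitting check;
* **reporting**: marginal summary tables, tidy long-format metric
  distributions, percentile-stratified error tables, boxplots, and a
  reproducibility manifest.

See `docs/methods.md` for the full model descriptions and design choices.

## Worked example

```python
import costsim as cs

# one dataset per outcome family, sharing the same covariate draw
datasets = [cs.simulate_dataset(4205, fam, seed=7) for fam in cs.FAMILIES]
print(cs.make_summary_table(datasets).round(1))
```

```
                  mean   median      p90  skewness  kurtosis
family
gamma          27064.9  19267.9  59096.3       1.4       2.2
weibull        28517.0  20574.6  62736.6       1.3       1.7
het_lognormal  28684.3  19935.0  63427.9       2.1       7.5
heavy_tail     41284.3  19635.2  97465.5       5.6      58.2
```

All four families share the same conditional mean structure but differ in
shape: the exponential-family outcomes (gamma, weibull) have moderate
skewness ≈ 1.5, the heteroscedastic log-normal is noticeably heavier, and
the heavy-tail family — log-normal noise with sd ≈ 0.92 — has extreme
skewness and kurtosis and a mean some 50% above its median.

```python
# fit the three models (correctly specified) and compare
data = datasets[2]                      # het_lognormal
for spec in cs.default_model_grid(rf_ntree=200)[::2]:   # glm, plaqr, rf
    res = cs.fit_model(data, spec)
    m = cs.evaluate(data.cost, res.predict(data.covariates))
    print(f"{spec.label:24s} rmse={m.rmse:8.0f}  mape={m.mape:8.0f}  ca={m.ca:6.1f}%")
```

```
gamma_glm/correct        rmse=   12979  mape=    7188  ca=  85.4%
plaqr/correct            rmse=   15628  mape=    8477  ca=  30.1%
rf/correct               rmse=   10012  mape=    5386  ca=  90.1%
```

The forest attains the lowest dollar errors and the cost accuracy nearest
100% under this non-exponential family; PLAQR's low CA reflects that a
conditional-median model rarely predicts above a 90th-percentile
threshold.  For operating characteristics rather than single fits, run the
bootstrap harness:

```python
cfg = cs.ScenarioConfig("het_lognormal", 500, B=100, seed=1,
                        specs=cs.default_model_grid(rf_ntree=200))
res = cs.run_bootstrap(cs.simulate_dataset(500, "het_lognormal", seed=1), cfg)
print(res.summary())
```

The same pipeline is scriptable from the shell:

```sh
costsim simulate --n 4205 --family heavy-tail --seed 1 --out episodes.csv
costsim fit --data episodes.csv --model rf --out model.json
costsim evaluate --observed model.predictions.csv --predicted model.predictions.csv --out metrics.json
costsim bootstrap --config scenario.yaml --out results/   # --full for B=1000
costsim report --results results/ --out report/ --plots
```

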