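"""Bootstrap operating-characteristics harness.

The experimental design of the simulation study: draw a dataset, then for
b = 1..B resample its rows with replacement, fit every model variant on the
resample, predict on a fixed evaluation set, and record RMSE / MAPE / CA per
iteration.  The spread of the per-iteration metrics describes the sampling
variability of each model's accuracy (the boxplot view).  Gamma GLM fits
that fail to converge are counted and excluded from aggregation, never
silently dropped.

Determinism: the scenario's master seed is split into one independent
sub-stream per iteration, so any execution order — or a resumed run —
yields bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng

from .metrics import cost_accuracy, mape, rmse
from .models import ModelSpec, fit_model
from .simulate import SimulatedDataset

__all__ = [
    "ScenarioConfig",
    "BootstrapResults",
    "default_model_grid",
    "run_bootstrap",
    "run_scenario_grid",
    "train_test_check",
]

logger = logging.getLogger(__name__)

EVAL_RULES = ("original", "oob", "insample")


def default_model_grid(
    rf_ntree: int = 1000, tau: float = 0.5, seed: int = 0, **kw
) -> list[ModelSpec]:
    """The five model variants of the study: GLM and PLAQR under correct and
    main-effects specifications, plus the (specification-invariant) forest."""
    return [
        ModelSpec("gamma_glm", "correct", seed=seed, **kw),
        ModelSpec("gamma_glm", "main_effects", seed=seed, **kw),
        ModelSpec("plaqr", "correct", tau=tau, seed=seed, **kw),
        ModelSpec("plaqr", "main_effects", tau=tau, seed=seed, **kw),
        ModelSpec("rf", "correct", rf_ntree=rf_ntree, seed=seed, **kw),
    ]


@dataclass
class ScenarioConfig:
    """One cell of the simulation design.

    ``eval_rule`` chooses what the bootstrap-fitted models predict on:
    "original" (default) — the full original dataset, fixed across
    iterations; "oob" — the rows left out of each resample; "insample" —
    the resample itself.  ``rf_tune_once`` tunes the forest's mtry once on
    the original dataset and reuses it for every resample fit, mirroring a
    single upfront tuning pass.
    """

    family: str
    n: int
    B: int = 1000
    specs: list[ModelSpec] = field(default_factory=default_model_grid)
    seed: int = 0
    eval_rule: str = "original"
    rf_tune_once: bool = True

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not self.specs:
            raise ValueError("model grid must be nonempty")
        if self.eval_rule not in EVAL_RULES:
            raise ValueError(f"eval_rule must be one of {EVAL_RULES}")

    @property
    def name(self) -> str:
        return f"{self.family}_n{self.n}"


@dataclass
class BootstrapResults:
    """Per-iteration metrics for every model plus convergence bookkeeping.

    ``table`` columns: model, specification, iteration, converged, rmse,
    mape, ca.  Non-converged iterations carry NaN metrics when no predictor
    was available.
    """

    table: pd.DataFrame
    config: ScenarioConfig
    rf_mtry: int | None = None

    def converged_counts(self) -> pd.Series:
        return self.table.groupby(["model", "specification"])["converged"].sum().astype(int)

    def aggregate(self, stat: str = "median") -> pd.DataFrame:
        """Per-model aggregate of the metric distributions over converged fits."""
        ok = self.table[self.table["converged"]]
        return ok.groupby(["model", "specification"])[["rmse", "mape", "ca"]].agg(stat)

    def summary(self) -> str:
        B = self.config.B
        lines = [f"Scenario {self.config.name}: B={B}, eval={self.config.eval_rule}"]
        for (model, spec), k in self.converged_counts().items():
            suffix = "" if k == B else f" (plotted based on the {k} converged models)"
            lines.append(f"  {model}/{spec}: {k}/{B} converged{suffix}")
        lines.append("")
        lines.append(self.aggregate().to_string(float_format=lambda v: f"{v:.1f}"))
        return "\n".join(lines)


def _prepare_specs(data: SimulatedDataset, cfg: ScenarioConfig) -> list[ModelSpec]:
    """Pin the forest's mtry by a single OOB tuning pass on the original data."""
    specs = []
    for spec in cfg.specs:
        if spec.family == "rf" and spec.rf_mtry is None and cfg.rf_tune_once:
            tuned = fit_model(data, spec)
            spec = replace(spec, rf_mtry=tuned.diagnostics["mtry"])
        specs.append(spec)
    return specs


def run_bootstrap(data: SimulatedDataset, cfg: ScenarioConfig) -> BootstrapResults:
    """Fit the model grid on B bootstrap resamples and measure accuracy.

    The CA threshold is computed once per scenario from the evaluation set's
    observed costs (for the "original" rule; per-iteration sets recompute it
    on their own observed costs).
    """
    n = data.n
    specs = _prepare_specs(data, cfg)
    rf_mtry = next((s.rf_mtry for s in specs if s.family == "rf"), None)
    eval_cov, eval_y = data.covariates, data.cost
    threshold = float(np.percentile(eval_y, 90))
    iter_seqs = SeedSequence(cfg.seed).spawn(cfg.B)
    rows = []
    for b, seq in enumerate(iter_seqs):
        rng = default_rng(seq)
        idx = rng.integers(0, n, n)
        boot = data.subset(idx)
        if cfg.eval_rule == "original":
            ev_cov, ev_y, ev_t = eval_cov, eval_y, threshold
        elif cfg.eval_rule == "insample":
            ev_cov, ev_y = boot.covariates, boot.cost
            ev_t = float(np.percentile(ev_y, 90))
        else:  # oob
            mask = np.ones(n, dtype=bool)
            mask[np.unique(idx)] = False
            ev_cov, ev_y = eval_cov[mask], eval_y[mask]
            ev_t = float(np.percentile(ev_y, 90)) if mask.any() else threshold
        model_seeds = seq.spawn(len(specs))
        for spec, mseq in zip(specs, model_seeds):
            if spec.family == "rf":
                spec = replace(spec, seed=int(mseq.generate_state(1)[0] % (2**31)))
            try:
                res = fit_model(boot, spec)
            except Exception as err:
                logger.warning("iteration %d %s: fit raised %r", b, spec.label, err)
                rows.append(_row(spec, b, False, np.nan, np.nan, np.nan))
                continue
            if res._predictor is None:
                rows.append(_row(spec, b, False, np.nan, np.nan, np.nan))
                continue
            pred = res.predict(ev_cov)
            rows.append(
                _row(
                    spec, b, res.converged,
                    rmse(ev_y, pred), mape(ev_y, pred),
                    cost_accuracy(ev_y, pred, threshold=ev_t),
                )
            )
    table = pd.DataFrame(rows)
    return BootstrapResults(table=table, config=cfg, rf_mtry=rf_mtry)


def _row(spec, b, converged, r, m, c):
    return {
        "model": spec.family,
        "specification": spec.specification,
        "iteration": b,
        "converged": bool(converged),
        "rmse": r,
        "mape": m,
        "ca": c,
    }


def run_scenario_grid(
    configs: list[ScenarioConfig],
    data_by_scenario: dict[str, SimulatedDataset] | None = None,
    out_dir=None,
) -> dict[str, BootstrapResults]:
    """Execute every scenario cell; a failing cell is logged and skipped.

    Datasets are generated from each scenario's (family, n, seed) unless
    supplied in ``data_by_scenario``.  With ``out_dir`` set, one CSV per
    (model, specification) cell is written as
    ``<family>_<n>_<model>_<specification>.csv``.
    """
    from .simulate import simulate_dataset

    if not configs:
        raise ValueError("no scenarios to run")
    results: dict[str, BootstrapResults] = {}
    for cfg in configs:
        try:
            if data_by_scenario and cfg.name in data_by_scenario:
                data = data_by_scenario[cfg.name]
            else:
                data = simulate_dataset(cfg.n, cfg.family, seed=cfg.seed)
            logger.info("running scenario %s (B=%d)", cfg.name, cfg.B)
            res = run_bootstrap(data, cfg)
            results[cfg.name] = res
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                for (model, spec), part in res.table.groupby(["model", "specification"]):
                    part = part[["iteration", "rmse", "mape", "ca", "converged"]]
                    part.to_csv(out_dir / f"{cfg.family}_{cfg.n}_{model}_{spec}.csv", index=False)
        except Exception as err:
            logger.error("scenario %s failed: %r", cfg.name, err)
    return results


def train_test_check(
    data: SimulatedDataset,
    specs: list[ModelSpec],
    test_fraction: float = 0.3,
    seed: int = 0,
    flag_ratio: float = 1.5,
) -> pd.DataFrame:
    """Single train/test split sanity check for overfitting.

    Fits each spec on the training part, reports train and test RMSE and
    flags models whose test error exceeds ``flag_ratio`` times their train
    error.  Columns: model, specification, train_rmse, test_rmse, overfit.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = data.n
    n_test = int(round(n * test_fraction))
    if min(n_test, n - n_test) < 10:
        raise ValueError("split leaves fewer than 10 rows on one side")
    perm = default_rng(seed).permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    train, test = data.subset(train_idx), data.subset(test_idx)
    rows = []
    for spec in specs:
        res = fit_model(train, spec)
        tr = rmse(train.cost, res.predict(train.covariates))
        te = rmse(test.cost, res.predict(test.covariates))
        rows.append(
            {
                "model": spec.family,
                "specification": spec.specification,
                "train_rmse": tr,
                "test_rmse": te,
                "overfit": bool(te > flag_ratio * tr),
            }
        )
    return pd.DataFrame(rows)
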