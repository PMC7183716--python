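"""Reporting surfaces: summary tables, metric-distribution exports, plots.

Aggregates simulator output and bootstrap results into the study's
presentation formats: a per-family marginal summary table, a tidy
long-format table of per-iteration metrics suitable for boxplotting, and a
percentile-stratified error table.  Plots are convenience output; the
tables are the tested surface.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import BootstrapResults
from .metrics import stratified_errors
from .simulate import SimulatedDataset, summarize_distribution

__all__ = [
    "make_summary_table",
    "export_metric_distributions",
    "make_stratified_table",
    "write_manifest",
]

SUMMARY_COLUMNS = ["mean", "median", "p90", "skewness", "kurtosis"]


def make_summary_table(datasets) -> pd.DataFrame:
    """Marginal cost summary per family (mean/median/p90/skewness/kurtosis).

    ``datasets`` is either a list of :class:`SimulatedDataset` (one row per
    family) or a mapping family -> list of replicate datasets, in which case
    each statistic is averaged over the replicates.
    """
    if not datasets:
        raise ValueError("no datasets to summarise")
    if isinstance(datasets, dict):
        items = datasets.items()
    else:
        items = [(d.family, [d]) for d in datasets]
    rows = {}
    for family, reps in items:
        if isinstance(reps, SimulatedDataset):
            reps = [reps]
        stats = [summarize_distribution(d.cost) for d in reps]
        rows[family] = {
            col: float(np.mean([getattr(s, col) for s in stats])) for col in SUMMARY_COLUMNS
        }
    table = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    table.index.name = "family"
    return table


def export_metric_distributions(
    results: dict[str, BootstrapResults],
    out_csv=None,
    plots: bool = False,
    plot_dir=None,
) -> pd.DataFrame:
    """Tidy long table of per-iteration metrics across scenarios.

    Columns: scenario, family, n, model, specification, iteration, metric,
    value.  Only converged iterations are exported (matching the boxplot
    convention of plotting converged fits and reporting their count).  With
    ``plots=True`` one boxplot per metric is written, faceted by family and
    specification.
    """
    if not results:
        raise ValueError("no bootstrap results to export")
    parts = []
    for name, res in results.items():
        tab = res.table[res.table["converged"]]
        long = tab.melt(
            id_vars=["model", "specification", "iteration"],
            value_vars=["rmse", "mape", "ca"],
            var_name="metric",
            value_name="value",
        )
        long.insert(0, "scenario", name)
        long.insert(1, "family", res.config.family)
        long.insert(2, "n", res.config.n)
        parts.append(long)
    table = pd.concat(parts, ignore_index=True)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if plots:
        _boxplots(table, Path(plot_dir or "."))
    return table


def _boxplots(table: pd.DataFrame, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for metric in ("rmse", "mape", "ca"):
        sub = table[table["metric"] == metric]
        families = sorted(sub["family"].unique())
        fig, axes = plt.subplots(
            1, len(families), figsize=(4 * len(families), 4), squeeze=False, sharey=False
        )
        for ax, family in zip(axes[0], families):
            fsub = sub[sub["family"] == family]
            labels, groups = [], []
            for (model, spec), g in fsub.groupby(["model", "specification"]):
                if model == "rf":
                    labels.append("rf")
                else:
                    labels.append(f"{model}\n{spec}")
                groups.append(g["value"].to_numpy())
            ax.boxplot(groups, tick_labels=labels, whis=1.5)
            ax.set_title(family)
            ax.tick_params(axis="x", labelsize=7)
        fig.suptitle(metric.upper())
        fig.tight_layout()
        fig.savefig(plot_dir / f"boxplot_{metric}.png", dpi=120)
        plt.close(fig)


def make_stratified_table(y, predictions: dict[str, np.ndarray]) -> pd.DataFrame:
    """Percentile-stratified RMSE/MAPE per model on one evaluation set.

    ``predictions`` maps a model label to its dollar predictions for the
    observed costs ``y``.  Returns a table with a (model, stratum) index.
    """
    parts = []
    for label, yhat in predictions.items():
        tab = stratified_errors(y, yhat)
        tab.insert(0, "model", label)
        parts.append(tab.reset_index())
    return pd.concat(parts, ignore_index=True).set_index(["model", "stratum"])


def write_manifest(path, configs, master_seed: int, extra: dict | None = None) -> dict:
    """Run manifest: seeds, scenario configs and a content hash, as JSON.

    Sufficient to re-run a scenario grid bit-identically: the harness is a
    pure function of (config, seed).
    """
    from dataclasses import asdict, is_dataclass

    def plain(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: plain(v) for k, v in obj.items()}
        return obj

    payload = {
        "master_seed": master_seed,
        "scenarios": [plain(c) for c in configs],
        **(extra or {}),
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
    return payload
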