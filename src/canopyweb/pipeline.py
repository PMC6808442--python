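"""End-to-end run: prune → pool → scheme resolution → simulation → comparison.

The default configuration mirrors the reference study design: a plot
baseline plus abundance-threshold schemes at q = 20/40/60/80% and a
family-representative scheme (families with ≥ 200 m² of sampled foliage),
each rarefied scheme replicated 100 times.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import PlotDataset, prune_dataset, read_plot_tables
from .simulation import (
    SimulationResult,
    compare_schemes,
    family_scheme,
    plot_baseline_metrics,
    pool_plots,
    simulate_scheme,
    threshold_scheme,
)
from .synthetic import SyntheticConfig, generate_forest

__all__ = ["RunConfig", "run_pipeline", "plot_comparison"]


@dataclass
class RunConfig:
    """Configuration of one full comparison run."""

    tree_path: str | None = None
    interaction_path: str | None = None
    synthetic: SyntheticConfig | None = None  # used when no input paths given
    thresholds: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8])
    min_family_foliage: float = 200.0
    include_family_scheme: bool = True
    include_baseline: bool = True
    n_reps: int = 100
    base_seed: int = 0
    ci_method: str = "percentile"
    baseline_ci_method: str = "t"
    out_dir: str = "results"
    make_figure: bool = False

    def validate(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not self.thresholds and not self.include_family_scheme and not self.include_baseline:
            raise ValueError("at least one scheme must be configured")
        for q in self.thresholds:
            if not 0 < q <= 1:
                raise ValueError(f"threshold {q} outside (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg


def _load_dataset(cfg: RunConfig) -> PlotDataset:
    if cfg.tree_path and cfg.interaction_path:
        return read_plot_tables(cfg.tree_path, cfg.interaction_path)
    syn = cfg.synthetic or SyntheticConfig()
    return generate_forest(syn)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full comparison and write its tables to ``cfg.out_dir``.

    Outputs: ``results.tsv`` (scheme × metric summaries), ``replicates.tsv``
    (per-replicate metric rows), ``comparison.tsv`` (summaries plus CI
    non-overlap flags against the plot baseline), ``run_log.jsonl`` and,
    optionally, a six-panel figure.  Deterministic for a fixed config.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")

    def log(stage: str, **kw) -> None:
        log_fh.write(json.dumps({"stage": stage, **kw}, sort_keys=True) + "\n")

    log("start", version=__version__, python=platform.python_version(),
        base_seed=cfg.base_seed, n_reps=cfg.n_reps)
    try:
        dataset = prune_dataset(_load_dataset(cfg))
        log("prune", n_trees=int(len(dataset.trees)),
            n_occurrences=int(len(dataset.occurrences)), n_plots=dataset.n_plots)
        pooled = pool_plots(dataset)
        log("pool", mean_plot_foliage=pooled.mean_plot_foliage, n_plots=pooled.n_plots)

        results: list[SimulationResult] = []
        if cfg.include_baseline:
            results.append(plot_baseline_metrics(dataset, cfg.baseline_ci_method))
            log("baseline", n_plots=dataset.n_plots)
        for q in cfg.thresholds:
            scheme = threshold_scheme(pooled, q)
            log("scheme", name=scheme.name, n_species=len(scheme.selected_species),
                f_thresh=scheme.f_thresh)
            results.append(
                simulate_scheme(pooled, scheme, cfg.n_reps, cfg.base_seed, cfg.ci_method)
            )
        if cfg.include_family_scheme:
            scheme = family_scheme(pooled, cfg.min_family_foliage)
            log("scheme", name=scheme.name, n_species=len(scheme.selected_species),
                f_thresh=scheme.f_thresh)
            results.append(
                simulate_scheme(pooled, scheme, cfg.n_reps, cfg.base_seed, cfg.ci_method)
            )

        summary = pd.concat([r.summary for r in results], ignore_index=True)
        reps = pd.concat(
            [r.replicates.assign(scheme=r.scheme, rep=range(len(r.replicates)))
             for r in results],
            ignore_index=True,
        )
        comparison = compare_schemes(results)

        paths = {
            "results": out / "results.tsv",
            "replicates": out / "replicates.tsv",
            "comparison": out / "comparison.tsv",
            "log": log_path,
        }
        summary.to_csv(paths["results"], sep="\t", index=False, na_rep="NA",
                       float_format="%.10g")
        cols = ["scheme", "rep"] + [c for c in reps.columns if c not in ("scheme", "rep")]
        reps[cols].to_csv(paths["replicates"], sep="\t", index=False, na_rep="NA",
                          float_format="%.10g")
        comparison.to_csv(paths["comparison"], sep="\t", index=False, na_rep="NA",
                          float_format="%.10g")
        if cfg.make_figure:
            paths["figure"] = plot_comparison(summary, out / "comparison.png")
        log("done", **{k: str(v) for k, v in paths.items()})
        return paths
    finally:
        log_fh.close()


def plot_comparison(summary: pd.DataFrame, path: str | Path) -> Path:
    """Six-panel mean ± 95%-CI figure, one panel per network metric."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = summary["metric"].unique()
    schemes = summary["scheme"].unique()
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True)
    for ax, metric in zip(axes.ravel(), metrics):
        sub = summary[summary["metric"] == metric].set_index("scheme").loc[schemes]
        x = range(len(sub))
        ax.errorbar(
            x, sub["mean"],
            yerr=[sub["mean"] - sub["ci_lo"], sub["ci_hi"] - sub["mean"]],
            fmt="o", capsize=3,
        )
        ax.set_title(metric.replace("_", " "))
        ax.set_xticks(list(x))
        ax.set_xticklabels(sub.index, rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
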