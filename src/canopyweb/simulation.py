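"""Simulated non-plot-based sampling of a censused forest patch.

The plot census is pooled into one patch, a set of focal tree species is
chosen — either the species whose cumulative foliage reaches an abundance
threshold q, or the most foliage-rich species of every sufficiently sampled
family — and each selected species is rarefied to an equal foliage quota
F_thresh (mean total foliage of one plot divided by the number of selected
species).  Rarefaction draws trees of a species in random order until the
quota is met; the final tree is included fractionally, contributing
round-half-up(f · C_f) of its C_f caterpillars so that included foliage
equals the quota exactly.  Replicated draws yield per-scheme metric
distributions that are compared, via 95% confidence intervals, against the
per-plot baseline webs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import EmptyNetworkError, InteractionMatrix, PlotDataset, build_matrix
from .metrics import METRIC_NAMES, network_summary

__all__ = [
    "PooledDataset",
    "SelectionScheme",
    "SpeciesDraw",
    "RarefactionDraw",
    "SimulationResult",
    "pool_plots",
    "select_threshold_species",
    "select_family_species",
    "compute_f_thresh",
    "threshold_scheme",
    "family_scheme",
    "round_half_up",
    "rarefy_species",
    "assemble_matrix",
    "simulate_scheme",
    "plot_baseline_metrics",
    "summarize_ci",
    "compare_schemes",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties at .5 going up (platform-fixed)."""
    return int(np.floor(x + 0.5))


@dataclass
class PooledDataset:
    """All plots combined into one patch, keeping the per-plot foliage mean."""

    data: PlotDataset
    n_plots: int
    mean_plot_foliage: float

    def species_foliage(self) -> pd.Series:
        """Total sampled foliage (m²) per tree species, descending."""
        s = self.data.trees.groupby("species")["foliage_m2"].sum()
        return s.sort_values(ascending=False, kind="stable")


def pool_plots(d: PlotDataset) -> PooledDataset:
    """Combine all plots into a single patch.

    Records the mean total foliage of one plot — the numerator of the
    F_thresh rarefaction quota.
    """
    if d.n_plots == 0:
        raise ValueError("cannot pool a dataset with no plots")
    per_plot = d.foliage_per_plot()
    return PooledDataset(data=d, n_plots=d.n_plots, mean_plot_foliage=float(per_plot.mean()))


# -- species selection ---------------------------------------------------------


def select_threshold_species(pooled: PooledDataset, q: float) -> list[str]:
    """Smallest prefix of the foliage-descending species ranking whose
    cumulative foliage share reaches ``q`` (ties in foliage broken by label)."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    foliage = pooled.species_foliage()
    if foliage.empty or foliage.sum() <= 0:
        raise ValueError("pooled dataset has no foliage to rank")
    # stable descending sort with label tie-break
    ranked = foliage.reset_index().sort_values(
        ["foliage_m2", "species"], ascending=[False, True], kind="stable"
    )
    shares = ranked["foliage_m2"].to_numpy() / foliage.sum()
    cum = np.cumsum(shares)
    k = int(np.searchsorted(cum, q - 1e-12) + 1)
    return ranked["species"].head(k).tolist()


def select_family_species(pooled: PooledDataset, min_family_foliage: float = 200.0) -> list[str]:
    """One species per qualifying family: for each family with at least
    ``min_family_foliage`` m² sampled, the species with the most foliage
    (ties by label).  Species without a family label are ineligible."""
    trees = pooled.data.trees
    known = trees[trees["family"].notna()]
    fam_tot = known.groupby("family")["foliage_m2"].sum()
    qualifying = fam_tot[fam_tot >= min_family_foliage].index
    if not len(qualifying):
        raise ValueError(
            f"no family reaches {min_family_foliage} m² of sampled foliage"
        )
    sp = (
        known[known["family"].isin(qualifying)]
        .groupby(["family", "species"])["foliage_m2"]
        .sum()
        .reset_index()
        .sort_values(["family", "foliage_m2", "species"],
                     ascending=[True, False, True], kind="stable")
    )
    top = sp.groupby("family", sort=True).head(1)
    return sorted(top["species"].tolist())


def compute_f_thresh(pooled: PooledDataset, n_selected: int) -> float:
    """Foliage quota per selected species: mean plot foliage / n_selected (m²)."""
    if n_selected < 1:
        raise ValueError("n_selected must be >= 1")
    return pooled.mean_plot_foliage / n_selected


@dataclass
class SelectionScheme:
    """A resolved sampling design: which species, and the foliage quota each."""

    kind: str  # abundance_threshold | family_representative | plot_baseline
    name: str
    selected_species: list[str]
    f_thresh: float
    q: float | None = None
    min_family_foliage: float | None = None

    def __post_init__(self) -> None:
        if self.kind != "plot_baseline":
            if self.f_thresh <= 0:
                raise ValueError("f_thresh must be > 0")
            if not self.selected_species:
                raise ValueError("scheme resolved to an empty species list")


def threshold_scheme(pooled: PooledDataset, q: float) -> SelectionScheme:
    """Abundance-threshold scheme: species covering fraction ``q`` of foliage."""
    species = select_threshold_species(pooled, q)
    return SelectionScheme(
        kind="abundance_threshold",
        name=f"{int(round(q * 100))}%",
        selected_species=species,
        f_thresh=compute_f_thresh(pooled, len(species)),
        q=q,
    )


def family_scheme(pooled: PooledDataset, min_family_foliage: float = 200.0) -> SelectionScheme:
    """Family-representative scheme: top species of each well-sampled family."""
    species = select_family_species(pooled, min_family_foliage)
    return SelectionScheme(
        kind="family_representative",
        name="families",
        selected_species=species,
        f_thresh=compute_f_thresh(pooled, len(species)),
        min_family_foliage=min_family_foliage,
    )


# -- rarefaction ---------------------------------------------------------------


@dataclass
class SpeciesDraw:
    """One species' share of a replicate: trees taken and herbivores kept."""

    species: str
    full_trees: list[str]
    partial_tree: str | None
    fraction: float  # f of the final tree's foliage counted, in (0, 1]
    included_foliage: float
    occurrences: pd.DataFrame  # tree_id, morphospecies_id, count (subsampled)
    shortfall: bool  # species total foliage < quota, taken whole


@dataclass
class RarefactionDraw:
    """All species' draws for one replicate plus the seed that produced them."""

    seed: int
    parts: list[SpeciesDraw] = field(default_factory=list)

    def total_herbivores(self) -> int:
        return int(sum(p.occurrences["count"].sum() for p in self.parts))


def _subsample_tree_occurrences(
    occ: pd.DataFrame, n_keep: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Keep ``n_keep`` individuals drawn uniformly without replacement from
    the tree's caterpillars, re-collapsed to per-morphospecies counts."""
    individuals = np.repeat(occ["morphospecies_id"].to_numpy(), occ["count"].to_numpy())
    if n_keep >= len(individuals):
        return occ.copy()
    if n_keep == 0:
        return occ.iloc[0:0].copy()
    kept = rng.choice(individuals, size=n_keep, replace=False)
    counts = pd.Series(kept).value_counts()
    out = pd.DataFrame(
        {
            "tree_id": occ["tree_id"].iloc[0],
            "morphospecies_id": counts.index,
            "count": counts.to_numpy(dtype=int),
        }
    )
    return out.sort_values("morphospecies_id").reset_index(drop=True)


def rarefy_species(
    pooled: PooledDataset,
    species: str,
    f_thresh: float,
    rng: np.random.Generator,
) -> SpeciesDraw:
    """Rarefy one species' foliage to the quota ``f_thresh``.

    Trees of the species are visited in uniformly random order.  Trees before
    the quota crossing are included whole; the crossing tree contributes a
    fraction f of its foliage — chosen so included foliage equals the quota
    exactly — and round-half-up(f · C_f) of its C_f caterpillars, drawn
    uniformly without replacement.  A species whose total foliage falls short
    of the quota is included in full and flagged.
    """
    trees = pooled.data.trees[pooled.data.trees["species"] == species]
    if not len(trees):
        raise ValueError(f"species {species!r} not present in pooled dataset")
    trees = trees.sort_values("tree_id").reset_index(drop=True)
    order = rng.permutation(len(trees))

    occ_by_tree = {
        tid: g
        for tid, g in pooled.data.occurrences[
            pooled.data.occurrences["tree_id"].isin(set(trees["tree_id"]))
        ].groupby("tree_id")
    }

    full: list[str] = []
    kept_occ: list[pd.DataFrame] = []
    acc = 0.0
    partial_tree = None
    fraction = 1.0
    crossed = False
    for idx in order:
        tree_id = trees["tree_id"].iloc[idx]
        w = float(trees["foliage_m2"].iloc[idx])
        occ = occ_by_tree.get(tree_id)
        if acc + w >= f_thresh - 1e-12 and w > 0:
            f = (f_thresh - acc) / w
            if f >= 1.0 - 1e-12:
                # quota lands exactly on this tree's edge: take it whole
                full.append(tree_id)
                if occ is not None:
                    kept_occ.append(occ[["tree_id", "morphospecies_id", "count"]].copy())
                acc += w
            else:
                partial_tree = tree_id
                fraction = f
                acc += f * w
                if occ is not None:
                    c_f = int(occ["count"].sum())
                    n_keep = round_half_up(f * c_f)
                    kept_occ.append(
                        _subsample_tree_occurrences(
                            occ[["tree_id", "morphospecies_id", "count"]], n_keep, rng
                        )
                    )
            crossed = True
            break
        full.append(tree_id)
        acc += w
        if occ is not None:
            kept_occ.append(occ[["tree_id", "morphospecies_id", "count"]].copy())

    occurrences = (
        pd.concat(kept_occ, ignore_index=True)
        if kept_occ
        else pd.DataFrame(columns=["tree_id", "morphospecies_id", "count"])
    )
    return SpeciesDraw(
        species=species,
        full_trees=full,
        partial_tree=partial_tree,
        fraction=fraction,
        included_foliage=acc,
        occurrences=occurrences,
        shortfall=not crossed,
    )


def assemble_matrix(draw: RarefactionDraw) -> InteractionMatrix:
    """Host-species × morphospecies matrix from one replicate's kept records."""
    frames = [
        p.occurrences.assign(species=p.species) for p in draw.parts if len(p.occurrences)
    ]
    if not frames:
        raise EmptyNetworkError("replicate retained no interactions")
    occ = pd.concat(frames, ignore_index=True)
    occ = occ[occ["count"] > 0]
    if not len(occ):
        raise EmptyNetworkError("replicate retained no interactions")
    table = occ.pivot_table(
        index="species", columns="morphospecies_id", values="count",
        aggfunc="sum", fill_value=0,
    ).sort_index(axis=0).sort_index(axis=1)
    return InteractionMatrix(table.to_numpy(dtype=float), list(table.index), list(table.columns))


# -- confidence intervals and replicated simulation ----------------------------


def summarize_ci(values, method: str = "percentile") -> tuple[float, float, float]:
    """Mean and 95% interval of replicate metric values.

    ``percentile`` uses the 2.5/97.5 empirical percentiles (distribution-free,
    suited to 100 simulation replicates); ``t`` uses the Student-t interval
    (suited to the handful of plot baselines).  Fewer than two non-missing
    values leave the interval undefined (NaN bounds).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 2:
        mean = float(v[0]) if len(v) == 1 else float("nan")
        return mean, float("nan"), float("nan")
    mean = float(v.mean())
    if method == "percentile":
        lo, hi = np.percentile(v, [2.5, 97.5])
    elif method == "t":
        sem = v.std(ddof=1) / np.sqrt(len(v))
        half = stats.t.ppf(0.975, len(v) - 1) * sem
        lo, hi = mean - half, mean + half
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return mean, float(lo), float(hi)


@dataclass
class SimulationResult:
    """Per-replicate metrics for one scheme plus mean / 95%-CI summaries."""

    scheme: str
    replicates: pd.DataFrame  # one row per replicate, columns = METRIC_NAMES
    summary: pd.DataFrame  # metric, mean, ci_lo, ci_hi, n_used, n_degenerate
    ci_method: str
    n_degenerate: int = 0


def _summarize_replicates(
    scheme: str, rows: pd.DataFrame, ci_method: str, n_degenerate: int
) -> SimulationResult:
    records = []
    for metric in METRIC_NAMES:
        vals = rows[metric].to_numpy(dtype=float)
        mean, lo, hi = summarize_ci(vals, ci_method)
        records.append(
            {
                "scheme": scheme,
                "metric": metric,
                "mean": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_used": int(np.sum(~np.isnan(vals))),
                "n_degenerate": int(np.sum(np.isnan(vals))),
            }
        )
    return SimulationResult(
        scheme=scheme,
        replicates=rows.reset_index(drop=True),
        summary=pd.DataFrame.from_records(records),
        ci_method=ci_method,
        n_degenerate=n_degenerate,
    )


def simulate_scheme(
    pooled: PooledDataset,
    scheme: SelectionScheme,
    n_reps: int = 100,
    base_seed: int = 0,
    ci_method: str = "percentile",
) -> SimulationResult:
    """Replicate the rarefied non-plot-based design and summarise its metrics.

    Replicate r uses its own RNG stream seeded ``base_seed + r``, so runs are
    reproducible and any prefix of replicates is stable when n_reps changes.
    Degenerate (empty-web) replicates are recorded as all-NaN rows and
    excluded per metric, never zero-filled.
    """
    rows = []
    n_degenerate = 0
    species = sorted(scheme.selected_species)
    for r in range(n_reps):
        rng = np.random.default_rng(base_seed + r)
        draw = RarefactionDraw(seed=base_seed + r)
        for sp in species:
            draw.parts.append(rarefy_species(pooled, sp, scheme.f_thresh, rng))
        try:
            matrix = assemble_matrix(draw)
        except EmptyNetworkError:
            n_degenerate += 1
            rows.append({m: float("nan") for m in METRIC_NAMES})
            continue
        rows.append(network_summary(matrix).as_dict())
    if n_degenerate == n_reps:
        raise EmptyNetworkError(
            f"all {n_reps} replicates of scheme {scheme.name!r} were degenerate"
        )
    reps = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return _summarize_replicates(scheme.name, reps, ci_method, n_degenerate)


def plot_baseline_metrics(
    d: PlotDataset, ci_method: str = "t", scheme_name: str = "plots"
) -> SimulationResult:
    """Network metrics of each plot's own web, summarised across plots.

    The baseline against which the simulated selective designs are compared:
    each 0.1 ha plot contributes one web, and the summary is the mean with a
    Student-t 95% interval across plots (plots are samples, not replicates of
    a randomised procedure).
    """
    rows = []
    n_degenerate = 0
    for plot in d.plot_ids:
        try:
            matrix = build_matrix(d, plots=[plot])
        except EmptyNetworkError:
            n_degenerate += 1
            rows.append({m: float("nan") for m in METRIC_NAMES})
            continue
        rows.append(network_summary(matrix).as_dict())
    reps = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return _summarize_replicates(scheme_name, reps, ci_method, n_degenerate)


def compare_schemes(
    results: list[SimulationResult], baseline: str = "plots"
) -> pd.DataFrame:
    """Long-format comparison table of all schemes against the plot baseline.

    One row per scheme × metric with mean and CI bounds plus
    ``nonoverlap_vs_baseline``: True when the scheme's 95% CI and the
    baseline's do not overlap (the paper-style significance call).
    """
    table = pd.concat([r.summary for r in results], ignore_index=True)
    base = table[table["scheme"] == baseline].set_index("metric")
    flags = []
    for _, row in table.iterrows():
        if row["scheme"] == baseline or row["metric"] not in base.index:
            flags.append(False)
            continue
        b = base.loc[row["metric"]]
        disjoint = (
            np.isfinite([row["ci_lo"], row["ci_hi"], b["ci_lo"], b["ci_hi"]]).all()
            and (row["ci_lo"] > b["ci_hi"] or row["ci_hi"] < b["ci_lo"])
        )
        flags.append(bool(disjoint))
    table["nonoverlap_vs_baseline"] = flags
    return table
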