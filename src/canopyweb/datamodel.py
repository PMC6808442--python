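"""Core data containers and table I/O for plot-census herbivory data.

A census consists of two tables: one row per tree (plot, species, family,
sampled foliage area in m², validity flags) and one row per host-use record
(tree, herbivore morphospecies, individual count, confirmation flag).
Interaction networks are built by aggregating occurrence counts to the host
*species* level: rows are host species (lower trophic level), columns are
herbivore morphospecies (higher trophic level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "HerbivoreOccurrence",
    "PlotDataset",
    "InteractionMatrix",
    "SchemaError",
    "IntegrityError",
    "EmptyNetworkError",
    "read_plot_tables",
    "write_plot_tables",
    "prune_dataset",
    "build_matrix",
]

TREE_COLUMNS = ["plot_id", "tree_id", "species", "family", "foliage_m2", "alive", "identified"]
OCC_COLUMNS = ["tree_id", "morphospecies_id", "count", "confirmed"]


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class IntegrityError(ValueError):
    """Cross-table referential integrity is violated."""


class EmptyNetworkError(ValueError):
    """Matrix construction was requested but no interactions are in scope."""


@dataclass(frozen=True)
class TreeRecord:
    """One censused stem (DBH ≥ 5 cm) with its sampled foliage area."""

    tree_id: str
    plot_id: str
    species: str
    family: str | None
    foliage_area: float
    alive: bool = True
    identified: bool = True

    def __post_init__(self) -> None:
        if self.foliage_area < 0:
            raise ValueError(f"tree {self.tree_id}: foliage_area must be >= 0")


@dataclass(frozen=True)
class HerbivoreOccurrence:
    """Count of one herbivore morphospecies collected from one tree."""

    tree_id: str
    morphospecies_id: str
    count: int
    confirmed: bool = True

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(
                f"occurrence {self.morphospecies_id}@{self.tree_id}: count must be >= 1"
            )


@dataclass
class PlotDataset:
    """A plot census: trees plus the herbivore occurrences found on them.

    ``trees`` and ``occurrences`` are DataFrames with the canonical columns
    (:data:`TREE_COLUMNS`, :data:`OCC_COLUMNS`); ``area_per_plot`` is the
    plot size in hectares (0.1 ha in the field protocol).
    """

    trees: pd.DataFrame
    occurrences: pd.DataFrame
    area_per_plot: float = 0.1

    def __post_init__(self) -> None:
        self.trees = self.trees.reset_index(drop=True)
        self.occurrences = self.occurrences.reset_index(drop=True)
        self.validate()

    @classmethod
    def from_records(
        cls,
        trees: Iterable[TreeRecord],
        occurrences: Iterable[HerbivoreOccurrence] = (),
        area_per_plot: float = 0.1,
    ) -> "PlotDataset":
        tdf = pd.DataFrame(
            [
                (t.plot_id, t.tree_id, t.species, t.family, t.foliage_area,
                 int(t.alive), int(t.identified))
                for t in trees
            ],
            columns=TREE_COLUMNS,
        )
        odf = pd.DataFrame(
            [(o.tree_id, o.morphospecies_id, int(o.count), int(o.confirmed)) for o in occurrences],
            columns=OCC_COLUMNS,
        )
        return cls(tdf, odf, area_per_plot)

    def validate(self) -> None:
        for col in TREE_COLUMNS:
            if col not in self.trees.columns:
                raise SchemaError(f"tree table missing column {col!r}")
        for col in OCC_COLUMNS:
            if col not in self.occurrences.columns:
                raise SchemaError(f"interaction table missing column {col!r}")
        if self.trees["tree_id"].duplicated().any():
            dup = self.trees.loc[self.trees["tree_id"].duplicated(), "tree_id"].iloc[0]
            raise IntegrityError(f"duplicate tree_id {dup!r}")
        if (self.trees["foliage_m2"] < 0).any():
            raise ValueError("foliage_m2 must be >= 0")
        if len(self.occurrences):
            if (self.occurrences["count"] < 1).any():
                raise ValueError("occurrence counts must be >= 1")
            known = set(self.trees["tree_id"])
            unknown = set(self.occurrences["tree_id"]) - known
            if unknown:
                raise IntegrityError(
                    f"occurrences reference unknown tree_id(s): {sorted(unknown)[:5]}"
                )

    # -- convenience aggregates ------------------------------------------------

    @property
    def plot_ids(self) -> list:
        return sorted(self.trees["plot_id"].unique())

    @property
    def n_plots(self) -> int:
        return self.trees["plot_id"].nunique()

    def foliage_per_plot(self) -> pd.Series:
        """Total sampled leaf area (m²) per plot."""
        return self.trees.groupby("plot_id")["foliage_m2"].sum()

    def stems_per_plot(self) -> pd.Series:
        return self.trees.groupby("plot_id")["tree_id"].count()

    def herbivores_per_plot(self) -> pd.Series:
        """Total herbivore individuals per plot (0 for herbivore-free plots)."""
        merged = self.occurrences.merge(
            self.trees[["tree_id", "plot_id"]], on="tree_id", how="left"
        )
        per = merged.groupby("plot_id")["count"].sum()
        return per.reindex(self.plot_ids, fill_value=0)

    def total_occurrence_count(self) -> int:
        return int(self.occurrences["count"].sum()) if len(self.occurrences) else 0

    def subset_plots(self, plots: Sequence) -> "PlotDataset":
        keep = self.trees["plot_id"].isin(set(plots))
        trees = self.trees.loc[keep]
        occ = self.occurrences[self.occurrences["tree_id"].isin(set(trees["tree_id"]))]
        return PlotDataset(trees.copy(), occ.copy(), self.area_per_plot)

    def equals(self, other: "PlotDataset") -> bool:
        key_t = ["plot_id", "tree_id"]
        a = self.trees.sort_values(key_t).reset_index(drop=True)
        b = other.trees.sort_values(key_t).reset_index(drop=True)
        key_o = ["tree_id", "morphospecies_id"]
        c = self.occurrences.sort_values(key_o).reset_index(drop=True)
        d = other.occurrences.sort_values(key_o).reset_index(drop=True)
        text_cols = [col for col in TREE_COLUMNS if col != "foliage_m2"]
        return (
            a[text_cols].astype(str).equals(b[text_cols].astype(str))
            and len(a) == len(b)
            and np.allclose(a["foliage_m2"], b["foliage_m2"])
            and c[OCC_COLUMNS].astype(str).equals(d[OCC_COLUMNS].astype(str))
            and self.area_per_plot == other.area_per_plot
        )


@dataclass
class InteractionMatrix:
    """Quantitative host-species × herbivore-morphospecies count matrix.

    Rows are host (tree) species — the lower trophic level; columns are
    herbivore morphospecies — the higher trophic level.  The orientation is
    fixed because every metric sign convention depends on it.
    """

    a: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 2:
            raise ValueError("interaction matrix must be 2-D")
        if self.a.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match matrix shape")
        if (self.a < 0).any():
            raise ValueError("interaction counts must be >= 0")

    @property
    def m(self) -> float:
        """Grand total of interaction counts."""
        return float(self.a.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    @property
    def n_hosts(self) -> int:
        return self.a.shape[0]

    @property
    def n_herbivores(self) -> int:
        return self.a.shape[1]

    def binary(self) -> np.ndarray:
        return (self.a > 0).astype(int)

    def transpose(self) -> "InteractionMatrix":
        return InteractionMatrix(self.a.T.copy(), list(self.col_labels), list(self.row_labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.a, index=self.row_labels, columns=self.col_labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().astype(int)
        df.index.name = "host_species"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="host_species")
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


# -- I/O -----------------------------------------------------------------------


def _read_table(path: str | Path, columns: Sequence[str], numeric: dict) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, validating schema and numerics."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = df[list(columns)].copy()
    for col, kind in numeric.items():
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(f"{path}: unparsable value {df[col][bad.idxmax()]!r} "
                              f"in column {col!r} at line {row}")
        df[col] = parsed.astype(kind)
    return df


def read_plot_tables(
    tree_path: str | Path,
    interaction_path: str | Path,
    area_per_plot: float = 0.1,
) -> PlotDataset:
    """Read the two census CSV/TSV tables into a validated :class:`PlotDataset`.

    ``trees``: plot_id, tree_id, species, family, foliage_m2, alive, identified.
    ``interactions``: tree_id, morphospecies_id, count, confirmed.
    Delimiter (comma/tab) is sniffed; flags are 0/1.
    """
    trees = _read_table(
        tree_path, TREE_COLUMNS, {"foliage_m2": float, "alive": int, "identified": int}
    )
    trees["family"] = trees["family"].where(trees["family"].notna() & (trees["family"] != ""), None)
    occ = _read_table(interaction_path, OCC_COLUMNS, {"count": int, "confirmed": int})
    return PlotDataset(trees, occ, area_per_plot)


def write_plot_tables(d: PlotDataset, tree_path: str | Path, interaction_path: str | Path) -> None:
    """Write the census back to delimited text (inverse of :func:`read_plot_tables`)."""
    t = d.trees.copy()
    t["family"] = t["family"].fillna("")
    # %.17g makes the float round-trip lossless
    t.to_csv(tree_path, index=False, float_format="%.17g")
    d.occurrences.to_csv(interaction_path, index=False)


# -- pruning and matrix construction ------------------------------------------


def prune_dataset(d: PlotDataset) -> PlotDataset:
    """Apply the inclusion rule: keep only living, species-identified trees and
    confirmed host associations on surviving trees.  Idempotent."""
    trees = d.trees[(d.trees["alive"] == 1) & (d.trees["identified"] == 1)]
    keep_ids = set(trees["tree_id"])
    occ = d.occurrences[
        (d.occurrences["confirmed"] == 1) & d.occurrences["tree_id"].isin(keep_ids)
    ]
    return PlotDataset(trees.copy(), occ.copy(), d.area_per_plot)


def build_matrix(
    d: PlotDataset,
    plots: Sequence | None = None,
    keep_empty_hosts: bool = False,
) -> InteractionMatrix:
    """Aggregate occurrence counts to a host-species × morphospecies matrix.

    Counts of each morphospecies are summed over all conspecific trees within
    the plot subset.  Host species without any herbivores are dropped unless
    ``keep_empty_hosts``; herbivore columns with zero total never occur by
    construction.  Raises :class:`EmptyNetworkError` when no interactions are
    in scope.
    """
    trees = d.trees if plots is None else d.trees[d.trees["plot_id"].isin(set(plots))]
    if not len(trees):
        raise EmptyNetworkError("no trees in the requested plot subset")
    occ = d.occurrences[d.occurrences["tree_id"].isin(set(trees["tree_id"]))]
    if not len(occ):
        raise EmptyNetworkError("no interactions in the requested plot subset")
    merged = occ.merge(trees[["tree_id", "species"]], on="tree_id")
    table = merged.pivot_table(
        index="species", columns="morphospecies_id", values="count",
        aggfunc="sum", fill_value=0,
    ).sort_index(axis=0).sort_index(axis=1)
    if keep_empty_hosts:
        all_sp = sorted(trees["species"].unique())
        table = table.reindex(all_sp, fill_value=0)
    return InteractionMatrix(table.to_numpy(dtype=float), list(table.index), list(table.columns))
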