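"""Field-protocol calculators: leaf-area estimation, gall extrapolation and
sampling-efficiency measures.

Leaf area of a tree is estimated either from total fresh foliage weight via
the area-to-weight ratio of a photographed leaf-frame sample (felled trees)
or from a visual leaf count times the mean leaf area of the frame (standing
trees accessed by crane/cherry picker).  Sampling efficiency is expressed
per unit area (ASE, person-hours per 0.1 ha), per unit resource (RSE,
person-hours per m² of foliage) and as foliage accessibility (%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LeafFrameSample",
    "EffortRecord",
    "leaf_area_from_biomass",
    "leaf_area_from_counts",
    "estimate_gall_abundance",
    "efficiency_measures",
    "arcsine_transform",
    "log_transform",
]


@dataclass(frozen=True)
class LeafFrameSample:
    """A photographed 50 × 50 cm leaf-frame sample from one tree.

    Exactly one of ``frame_weight`` (kg, felled-tree variant) or
    ``frame_leaf_count`` (standing-tree variant) accompanies the measured
    ``frame_leaf_area`` (m²).
    """

    frame_leaf_area: float
    frame_weight: float | None = None
    frame_leaf_count: int | None = None

    def __post_init__(self) -> None:
        if self.frame_leaf_area <= 0:
            raise ValueError("frame_leaf_area must be > 0")
        if (self.frame_weight is None) == (self.frame_leaf_count is None):
            raise ValueError("provide exactly one of frame_weight or frame_leaf_count")
        if self.frame_weight is not None and self.frame_weight <= 0:
            raise ValueError("frame_weight must be > 0")
        if self.frame_leaf_count is not None and self.frame_leaf_count <= 0:
            raise ValueError("frame_leaf_count must be > 0")


@dataclass(frozen=True)
class EffortRecord:
    """Collection + sorting effort spent on one plot."""

    person_hours: float
    plot_area: float  # ha
    sampled_foliage: float  # m²
    accessible_fraction: float  # in [0, 1]

    def __post_init__(self) -> None:
        if self.person_hours < 0:
            raise ValueError("person_hours must be >= 0")
        if not 0 <= self.accessible_fraction <= 1:
            raise ValueError("accessible_fraction must be in [0, 1]")
        if self.plot_area <= 0:
            raise ValueError("plot_area must be > 0")


def leaf_area_from_biomass(
    total_fresh_weight: float,
    frame: LeafFrameSample,
    defoliated_fraction: float = 1.0,
) -> float:
    """Tree leaf area (m²) from fresh foliage weight × area-to-weight ratio.

    ``defoliated_fraction`` extrapolates partial defoliation (e.g. 0.5 when
    only half the canopy was stripped and weighed) back to the whole crown.
    """
    if frame.frame_weight is None:
        raise ValueError("biomass variant requires a frame with frame_weight")
    if total_fresh_weight < 0:
        raise ValueError("total_fresh_weight must be >= 0")
    if not 0 < defoliated_fraction <= 1:
        raise ValueError("defoliated_fraction must be in (0, 1]")
    return (total_fresh_weight / defoliated_fraction) * (
        frame.frame_leaf_area / frame.frame_weight
    )


def leaf_area_from_counts(total_leaf_count_estimate: float, frame: LeafFrameSample) -> float:
    """Tree leaf area (m²) from an estimated leaf count × mean leaf area.

    The caller supplies the (already averaged) visual estimate of the total
    number of leaves; the result scales linearly in it.
    """
    if frame.frame_leaf_count is None:
        raise ValueError("count variant requires a frame with frame_leaf_count")
    if total_leaf_count_estimate < 0:
        raise ValueError("total_leaf_count_estimate must be >= 0")
    return total_leaf_count_estimate * (frame.frame_leaf_area / frame.frame_leaf_count)


def estimate_gall_abundance(per_branch_means, total_leaves: int) -> int:
    """Total galls on a tree from 3–5 per-branch galls-per-leaf means.

    The protocol inspects 3–5 branches of 100–500 leaves each; the tree-level
    estimate is the mean of the branch means times the tree's leaf count,
    rounded half-up.
    """
    means = np.asarray(list(per_branch_means), dtype=float)
    if not 3 <= len(means) <= 5:
        raise ValueError("protocol requires 3-5 branch means")
    if (means < 0).any():
        raise ValueError("branch means must be >= 0")
    if total_leaves <= 0:
        raise ValueError("total_leaves must be > 0")
    return int(np.floor(means.mean() * total_leaves + 0.5))


def efficiency_measures(e: EffortRecord) -> dict[str, float]:
    """ASE (person-hours per 0.1 ha), RSE (person-hours per m²) and
    accessibility (%) of one plot's sampling effort.

    RSE is NaN (undefined) when no foliage was sampled.
    """
    ase = e.person_hours * (0.1 / e.plot_area)
    rse = e.person_hours / e.sampled_foliage if e.sampled_foliage > 0 else float("nan")
    return {
        "ase_person_hours_per_0.1ha": ase,
        "rse_person_hours_per_m2": rse,
        "accessibility_pct": e.accessible_fraction * 100.0,
    }


def arcsine_transform(fraction) -> np.ndarray | float:
    """arcsin(sqrt(x)) variance-stabilising transform for proportions."""
    x = np.asarray(fraction, dtype=float)
    if ((x < 0) | (x > 1)).any():
        raise ValueError("proportions must be in [0, 1]")
    out = np.arcsin(np.sqrt(x))
    return float(out) if out.ndim == 0 else out


def log_transform(effort) -> np.ndarray | float:
    """Natural-log transform for strictly positive effort values."""
    x = np.asarray(effort, dtype=float)
    if (x <= 0).any():
        raise ValueError("effort must be > 0 for the log transform")
    out = np.log(x)
    return float(out) if out.ndim == 0 else out
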