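"""Bipartite network statistics for quantitative host–herbivore webs.

Six parameters characterise each web: connectance, web asymmetry,
nestedness temperature, herbivore species richness, and weighted
generality / vulnerability (marginal-weighted mean effective numbers of
partners, via exponentiated Shannon entropy of the interaction
proportions).  Connectance and temperature operate on the binarised web;
generality and vulnerability use the quantitative counts.

Undefined metrics (degenerate webs) are reported as NaN, never as silent
zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .datamodel import InteractionMatrix
from .nestedness import nestedness_temperature as _temperature

__all__ = [
    "NetworkMetrics",
    "METRIC_NAMES",
    "connectance",
    "web_asymmetry",
    "nestedness_temperature",
    "herbivore_richness",
    "weighted_generality",
    "weighted_vulnerability",
    "network_summary",
]

METRIC_NAMES = (
    "connectance",
    "web_asymmetry",
    "nestedness_temperature",
    "herbivore_richness",
    "weighted_generality",
    "weighted_vulnerability",
)


@dataclass(frozen=True)
class NetworkMetrics:
    """The six network parameters of one web; NaN marks undefined fields."""

    connectance: float
    web_asymmetry: float
    nestedness_temperature: float
    herbivore_richness: float
    weighted_generality: float
    weighted_vulnerability: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _require_nonempty(M: InteractionMatrix) -> None:
    if M.n_hosts == 0 or M.n_herbivores == 0:
        raise ValueError("metric undefined on an empty matrix")


def connectance(M: InteractionMatrix) -> float:
    """Realised proportion of possible links: positive cells / (rows × cols)."""
    _require_nonempty(M)
    return float((M.a > 0).sum() / M.a.size)


def web_asymmetry(M: InteractionMatrix) -> float:
    """(higher-level richness − lower-level richness) / total richness.

    Positive values mean more herbivore (higher trophic level) species than
    host species.
    """
    _require_nonempty(M)
    hi, lo = M.n_herbivores, M.n_hosts
    return float((hi - lo) / (hi + lo))


def nestedness_temperature(M: InteractionMatrix) -> float:
    """Packed matrix temperature in [0, 100]; NaN for single-row/column webs."""
    return _temperature(M.a, list(M.row_labels), list(M.col_labels))


def herbivore_richness(M: InteractionMatrix) -> int:
    """Number of herbivore species with at least one interaction."""
    if M.a.size == 0:
        return 0
    return int((M.a.sum(axis=0) > 0).sum())


def _effective_partner_number(a: np.ndarray) -> float:
    """Marginal-weighted mean exp(Shannon entropy) over the columns of ``a``.

    For each column j with total a_.j > 0, H_j = −Σ_i p_ij ln p_ij with
    p_ij = a_ij / a_.j (0·ln 0 := 0); the result is Σ_j (a_.j / m) exp(H_j).
    """
    totals = a.sum(axis=0)
    m = totals.sum()
    if m <= 0:
        return float("nan")
    out = 0.0
    for j in np.nonzero(totals > 0)[0]:
        p = a[:, j] / totals[j]
        p = p[p > 0]
        h = -float(np.sum(p * np.log(p)))
        out += (totals[j] / m) * np.exp(h)
    return float(out)


def weighted_generality(M: InteractionMatrix) -> float:
    """Mean effective number of host species per herbivore species."""
    _require_nonempty(M)
    return _effective_partner_number(M.a)


def weighted_vulnerability(M: InteractionMatrix) -> float:
    """Mean effective number of herbivore species per host species."""
    _require_nonempty(M)
    return _effective_partner_number(M.a.T)


def network_summary(M: InteractionMatrix) -> NetworkMetrics:
    """All six metrics of one web; degenerate metrics are NaN, not zero."""
    _require_nonempty(M)
    return NetworkMetrics(
        connectance=connectance(M),
        web_asymmetry=web_asymmetry(M),
        nestedness_temperature=nestedness_temperature(M),
        herbivore_richness=herbivore_richness(M),
        weighted_generality=weighted_generality(M),
        weighted_vulnerability=weighted_vulnerability(M),
    )
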