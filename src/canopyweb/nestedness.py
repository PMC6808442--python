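"""Matrix-temperature nestedness for binary bipartite webs.

Temperature quantifies the disorder of a presence–absence matrix after it
has been packed so that presences concentrate in the upper-left corner:
0 = perfectly nested, 100 = maximal disorder ("chaos").  The implementation
follows the isocline-of-perfect-order tradition: the matrix is mapped onto
the unit square, a fill-dependent isocline separates the region where
presences are expected from the region where absences are expected, and
every *unexpected* presence or absence is scored by its squared relative
distance from the isocline measured along the 45° diagonal through its
cell.  The mean unexpectedness is normalised so that the theoretical
maximum maps to 100.

Packing is deterministic and seed-free, replacing the stochastic
genetic-algorithm packers of the binmatnest lineage.  Because the
temperature is a sum of per-row (per-column) contributions that depend only
on a line's content and its position, the optimal ordering of one side
*given the other* is a linear assignment problem.  Small matrices (either
side ≤ 5 lines) are packed exactly: all orderings of the smaller side are
enumerated and the other side is solved by the Hungarian algorithm.  Larger
matrices start from a marginal-totals sort and alternate optimal row / column
assignments to a fixed point — a descent whose result never exceeds the
temperature of the seed ordering.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import brentq, linear_sum_assignment
from scipy.special import gammaln

__all__ = ["nestedness_temperature", "pack_matrix", "temperature_of_ordering"]

# Mean unexpectedness of the maximally disordered matrix; standard constant
# scaling temperature to [0, 100].
_U_MAX = 0.04145

# exact packing enumerates the smaller side up to this many lines (5! = 120)
_EXACT_SIDE = 5


def _isocline_exponent(fill: float) -> float:
    """Exponent p of the isocline x^p + y^p = 1 whose enclosed area equals fill.

    The area of {x^p + y^p <= 1} within the unit square is
    Gamma(1+1/p)^2 / Gamma(1+2/p), monotone increasing in p.
    """

    def area(p: float) -> float:
        return float(np.exp(2.0 * gammaln(1.0 + 1.0 / p) - gammaln(1.0 + 2.0 / p)))

    lo, hi = 1e-3, 1e4
    if fill <= area(lo):
        return lo
    if fill >= area(hi):
        return hi
    return brentq(lambda p: area(p) - fill, lo, hi, xtol=1e-12, rtol=1e-12)


def _unexpectedness_grid(n_rows: int, n_cols: int, fill: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell squared relative diagonal distance to the isocline.

    Returns ``(u, inside)``: ``u[i, j]`` is the unexpectedness charged to cell
    (i, j) when its state contradicts the isocline, and ``inside[i, j]`` is
    True where a presence is expected (cell centre inside the isocline).
    Depends only on shape and fill, so it is shared by all orderings of one
    matrix.
    """
    p = _isocline_exponent(fill)
    # cell centres in the unit square; row 0 / col 0 at the packed corner
    y = (np.arange(n_rows, dtype=float)[:, None] + 0.5) / n_rows
    x = (np.arange(n_cols, dtype=float)[None, :] + 0.5) / n_cols
    x, y = np.broadcast_arrays(x, y)
    inside = x**p + y**p < 1.0

    # diagonal through each cell: (x+t, y+t); square entry/exit parameters
    t_lo = -np.minimum(x, y)
    t_hi = np.minimum(1.0 - x, 1.0 - y)

    def h(t: np.ndarray) -> np.ndarray:
        return (x + t) ** p + (y + t) ** p - 1.0

    lo, hi = t_lo.copy(), t_hi.copy()
    # h is monotone in t on [t_lo, t_hi]; the isocline crossing may fall
    # outside the segment for extreme fills — clamp to the segment ends.
    sign_lo, sign_hi = h(lo) > 0, h(hi) < 0
    for _ in range(60):  # bisection to ~1e-18 of the segment
        mid = 0.5 * (lo + hi)
        gt = h(mid) > 0.0
        hi = np.where(gt, mid, hi)
        lo = np.where(gt, lo, mid)
    t_cross = 0.5 * (lo + hi)
    t_cross = np.where(sign_lo, t_lo, t_cross)
    t_cross = np.where(sign_hi, t_hi, t_cross)

    with np.errstate(invalid="ignore", divide="ignore"):
        u = (t_cross / (t_hi - t_lo)) ** 2
    return np.nan_to_num(u), inside


def _unexpectedness_sum(b: np.ndarray, u: np.ndarray, inside: np.ndarray) -> float:
    # a cell is unexpected exactly when its state differs from the isocline's
    return float(u[b ^ inside].sum())


def temperature_of_ordering(binary: np.ndarray) -> float:
    """Temperature of a presence–absence matrix in its *given* ordering."""
    b = np.asarray(binary) > 0
    n_rows, n_cols = b.shape
    fill = b.mean()
    if fill >= 1.0:
        return 0.0
    u, inside = _unexpectedness_grid(n_rows, n_cols, fill)
    t = 100.0 / _U_MAX * _unexpectedness_sum(b, u, inside) / (n_rows * n_cols)
    return float(min(t, 100.0))


def _line_costs(
    contents: np.ndarray, u: np.ndarray, inside: np.ndarray, axis: int
) -> np.ndarray:
    """Cost matrix C[pos, k]: unexpectedness charged to line-content k placed
    at line position ``pos``, for rows (axis 0) or columns (axis 1)."""
    u_presence = u * ~inside  # presence here is unexpected
    u_absence = u * inside  # absence here is unexpected
    B = contents.astype(float)
    if axis == 0:
        return u_presence @ B.T + u_absence @ (1.0 - B.T)
    return u_presence.T @ B + u_absence.T @ (1.0 - B)


def _marginal_order(b: np.ndarray, axis: int, labels: list | None) -> np.ndarray:
    totals = b.sum(axis=1 - axis)
    n = b.shape[axis]
    keys = labels if labels is not None else list(range(n))
    return np.array(sorted(range(n), key=lambda i: (-totals[i], keys[i])), dtype=int)


def _pack_exact(
    b: np.ndarray, u: np.ndarray, inside: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Global minimum: enumerate orderings of the smaller side, solve the
    other side by optimal assignment for each."""
    n_rows, n_cols = b.shape
    enumerate_rows = n_rows <= n_cols
    size = n_rows if enumerate_rows else n_cols
    best = (np.inf, None, None)
    for perm in itertools.permutations(range(size)):
        perm = np.array(perm, dtype=int)
        arranged = b[perm, :] if enumerate_rows else b[:, perm]
        axis = 1 if enumerate_rows else 0
        cost = _line_costs(arranged, u, inside, axis)
        pos, content = linear_sum_assignment(cost)
        total = float(cost[pos, content].sum())
        if total < best[0] - 1e-15:
            other = np.empty(len(content), dtype=int)
            other[pos] = content
            best = (total, perm, other)
    total, perm, other = best
    if enumerate_rows:
        return perm, other, total
    return other, perm, total


def _pack_descent(
    b: np.ndarray,
    u: np.ndarray,
    inside: np.ndarray,
    row_labels: list | None,
    col_labels: list | None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Deterministic descent: marginal-totals seed, then alternate optimal
    row and column assignments until no strict improvement."""
    row_order = _marginal_order(b, 0, row_labels)
    col_order = _marginal_order(b, 1, col_labels)
    cur = b[np.ix_(row_order, col_order)]
    cur_total = _unexpectedness_sum(cur, u, inside)
    eps = 1e-12
    improved = True
    while improved:
        improved = False
        for axis in (0, 1):
            cost = _line_costs(cur, u, inside, axis)
            pos, content = linear_sum_assignment(cost)
            total = float(cost[pos, content].sum())
            if total < cur_total - eps:
                perm = np.empty(len(content), dtype=int)
                perm[pos] = content
                if axis == 0:
                    row_order = row_order[perm]
                    cur = cur[perm, :]
                else:
                    col_order = col_order[perm]
                    cur = cur[:, perm]
                cur_total = total
                improved = True
    return row_order, col_order, cur_total


def pack_matrix(
    binary: np.ndarray,
    row_labels: list | None = None,
    col_labels: list | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Pack a binary matrix to (near-)minimal temperature, deterministically.

    Matrices whose smaller side has at most 5 lines are packed exactly
    (enumeration × optimal assignment); larger ones by alternating-assignment
    descent from a marginal-totals sort (ties broken by label order).
    Returns ``(row_order, col_order, temperature)``.
    """
    b = np.asarray(binary) > 0
    n_rows, n_cols = b.shape
    fill = b.mean()
    if fill >= 1.0:
        return np.arange(n_rows), np.arange(n_cols), 0.0
    u, inside = _unexpectedness_grid(n_rows, n_cols, fill)
    if min(n_rows, n_cols) <= _EXACT_SIDE:
        row_order, col_order, total = _pack_exact(b, u, inside)
    else:
        row_order, col_order, total = _pack_descent(b, u, inside, row_labels, col_labels)
    t = 100.0 / _U_MAX * total / (n_rows * n_cols)
    return row_order, col_order, float(min(t, 100.0))


def nestedness_temperature(
    a: np.ndarray,
    row_labels: list | None = None,
    col_labels: list | None = None,
) -> float:
    """Nestedness temperature in [0, 100] of a (quantitative) matrix.

    The matrix is binarised (presence = count > 0) and packed before scoring.
    A completely filled matrix returns exactly 0; a single-row or
    single-column matrix has no packing freedom and returns NaN (undefined).
    """
    b = np.asarray(a) > 0
    if b.ndim != 2 or min(b.shape) < 2:
        return float("nan")
    if b.all():
        return 0.0
    _, _, t = pack_matrix(b, row_labels, col_labels)
    return float(min(max(t, 0.0), 100.0))
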