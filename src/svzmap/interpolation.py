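"""Interpolation of heatmap columns for subsampled section series.

When only every N-th section of a homogeneous series is analyzed
(stereology-style 1/N subsampling) the wall matrix has measured columns at
``start_offset, start_offset + N, ...`` and background columns in between.
Missing columns are reconstructed in two passes:

* intersection interpolation — between two measured sections X (rostral) and
  Y (caudal), the n-th missing column is the convex combination
  ``v_n = (1 - n/N) * v_x + (n/N) * v_y`` of per-row "base values".  A base
  value is the vertical 3-neighbour average of the measured column
  (``(X' + X'' + X''') / 3``; at the first/last probe of a wall only one
  neighbour exists and ``(X' or X''' + X'') / 2`` is used).
* intrasection interpolation — one further vertical 3-neighbour smoothing
  pass applied to the interpolated columns only; measured columns are never
  modified.

Both passes operate row by row within one wall matrix and never mix walls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .mapping import BACKGROUND

MEASURED, INTERPOLATED, ABSENT = 1, 2, 0


@dataclass(frozen=True)
class SubsamplingScheme:
    """1-in-N subsampling with the first analyzed section at ``start_offset``."""

    n: int = 1
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("subsampling degree N must be >= 1")
        if not 0 <= self.start_offset < self.n:
            raise ValueError("start_offset must be in [0, N)")

    def analyzed_columns(self, n_sections: int) -> np.ndarray:
        return np.arange(self.start_offset, n_sections, self.n)


def column_base_values(column: np.ndarray) -> np.ndarray:
    """Vertical 3-neighbour average of one measured column.

    Interior rows average with both vertical neighbours; the wall's first and
    last rows average with their single neighbour; background rows stay
    background and never contribute.
    """
    col = np.asarray(column, dtype=float)
    out = np.full_like(col, BACKGROUND)
    valid = ~np.isnan(col)
    idx = np.flatnonzero(valid)
    for r in idx:
        neighbours = [col[r]]
        if r - 1 >= 0 and valid[r - 1]:
            neighbours.append(col[r - 1])
        if r + 1 < len(col) and valid[r + 1]:
            neighbours.append(col[r + 1])
        out[r] = float(np.mean(neighbours))
    return out


def base_value(column: np.ndarray, row: int) -> float:
    """Base value of a single row of a measured column."""
    col = np.asarray(column, dtype=float)
    if np.isnan(col[row]):
        raise DataError(f"row {row} is background; no base value defined")
    return float(column_base_values(col)[row])


def interpolate_intersections(
    matrix: np.ndarray, scheme: SubsamplingScheme
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing columns by row-wise linear weighting of base values.

    Between measured columns X and Y, missing column n (1-based from X) gets
    ``(1 - n/N) * v_x + (n/N) * v_y`` per row.  Rows measured in only one of
    the two flanking sections copy that section's base value; rows measured
    in neither stay background.  Missing columns before the first / after
    the last measured column copy the nearest measured column's base values.

    Returns the filled matrix and a provenance matrix (MEASURED /
    INTERPOLATED / ABSENT per cell).
    """
    values = np.asarray(matrix, dtype=float).copy()
    n_rows, n_cols = values.shape
    analyzed = scheme.analyzed_columns(n_cols)
    if analyzed.size < 1:
        raise DataError("need at least one analyzed column to interpolate")
    provenance = np.zeros((n_rows, n_cols), dtype=int)
    provenance[:, analyzed] = np.where(np.isnan(values[:, analyzed]), ABSENT, MEASURED)
    base = {int(c): column_base_values(values[:, c]) for c in analyzed}

    for c in range(n_cols):
        if c in base:
            continue
        left = analyzed[analyzed < c]
        right = analyzed[analyzed > c]
        if left.size and right.size:
            x, y = int(left[-1]), int(right[0])
            n = c - x
            span = y - x
            vx, vy = base[x], base[y]
            both = ~np.isnan(vx) & ~np.isnan(vy)
            only_x = ~np.isnan(vx) & np.isnan(vy)
            only_y = np.isnan(vx) & ~np.isnan(vy)
            col = np.full(n_rows, BACKGROUND)
            col[both] = (1 - n / span) * vx[both] + (n / span) * vy[both]
            col[only_x] = vx[only_x]
            col[only_y] = vy[only_y]
        else:
            nearest = int(left[-1]) if left.size else int(right[0])
            col = base[nearest].copy()
        values[:, c] = col
        provenance[:, c] = np.where(np.isnan(col), ABSENT, INTERPOLATED)
    return values, provenance


def interpolate_intrasections(
    matrix: np.ndarray, provenance: np.ndarray
) -> np.ndarray:
    """Vertical refinement pass over interpolated columns.

    Every interpolated cell is replaced by the 3-neighbour vertical average
    of its own column (same border rule as the base values), computed from
    the pre-pass values.  Columns containing any measured cell are returned
    bit-identical.
    """
    values = np.asarray(matrix, dtype=float).copy()
    for c in range(values.shape[1]):
        col_prov = provenance[:, c]
        if (col_prov == MEASURED).any() or not (col_prov == INTERPOLATED).any():
            continue
        values[:, c] = column_base_values(values[:, c])
    return values


def interpolate_matrix(
    matrix: np.ndarray, scheme: SubsamplingScheme, intrasection: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Intersection pass followed (optionally) by the intrasection pass."""
    if scheme.n == 1:
        provenance = np.where(np.isnan(matrix), ABSENT, MEASURED)
        return np.asarray(matrix, dtype=float).copy(), provenance
    filled, provenance = interpolate_intersections(matrix, scheme)
    if intrasection:
        filled = interpolate_intrasections(filled, provenance)
    return filled, provenance
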