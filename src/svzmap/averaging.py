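"""Averaging wall maps across animals.

Different animals yield different probe counts for the same wall and
section, so columns are first rebinned to a common probe count X before
elementwise averaging.  The rebinning follows a subvalue scheme: a column of
Y values is expanded to Y*X "subvalues" (each value divided by X and
repeated X times), the sequence is partitioned into X consecutive groups of
Y, and each group's mean times X is one "work value".  This is area-weighted
rebinning from Y to X equal bins and conserves the column mean exactly.

Averaging operates on raw (pre-normalization) values; the averaged maps are
normalized once at the end so every animal contributes on its own absolute
scale rather than relative to its own maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DataError, SectionCountMismatchError
from .mapping import BACKGROUND, normalize_maps


@dataclass
class AnimalDataset:
    """One animal's raw wall matrices for one quantity: {wall: 2D array}."""

    animal_id: str
    walls: dict[str, np.ndarray]


def common_probe_count(counts: list[int]) -> int:
    """Common probe count X: the mean of the animals' probe counts rounded to
    the nearest integer (halves away from zero), at least 1."""
    if not counts:
        raise DataError("no probe counts supplied")
    if any(c < 1 for c in counts):
        raise DataError("probe counts must be >= 1")
    mean = float(np.mean(counts))
    return max(1, int(math.floor(mean + 0.5)))


def rebin_column(values: np.ndarray, x: int) -> np.ndarray:
    """Rebin a column of Y probe values to X work values.

    Mean-conserving by construction: every original value spreads its mass
    uniformly over its stretch of the subvalue sequence.
    """
    values = np.asarray(values, dtype=float)
    y = len(values)
    if y < 1 or x < 1:
        raise DataError("need at least one value and x >= 1")
    subvalues = np.repeat(values / x, x)  # length y * x
    groups = subvalues.reshape(x, y)
    return groups.mean(axis=1) * x


def _column_values(column: np.ndarray) -> np.ndarray:
    """Non-background values of a column, in row order."""
    col = np.asarray(column, dtype=float)
    return col[~np.isnan(col)]


def average_animals(datasets: list[AnimalDataset]) -> dict[str, np.ndarray]:
    """Average several animals' raw wall matrices section by section.

    Per wall and section the contributing animals' columns are rebinned to
    the common probe count and averaged elementwise; animals with no probes
    in that section are skipped, and sections empty in every animal stay
    background.  Returns raw averaged matrices (normalize afterwards, e.g.
    via :func:`svzmap.mapping.normalize_maps`).
    """
    if len(datasets) < 2:
        raise DataError("averaging requires at least two animals")
    wall_sets = [set(d.walls) for d in datasets]
    if any(ws != wall_sets[0] for ws in wall_sets[1:]):
        raise DataError("animals do not share the same wall set")
    out: dict[str, np.ndarray] = {}
    for wall in wall_sets[0]:
        n_cols_set = {d.walls[wall].shape[1] for d in datasets}
        if len(n_cols_set) != 1:
            raise SectionCountMismatchError(
                f"wall {wall!r}: animals cover different section counts {sorted(n_cols_set)}"
            )
        n_cols = n_cols_set.pop()
        columns: list[np.ndarray] = []
        for c in range(n_cols):
            per_animal = [_column_values(d.walls[wall][:, c]) for d in datasets]
            per_animal = [v for v in per_animal if v.size]
            if not per_animal:
                columns.append(np.empty(0))
                continue
            x = common_probe_count([len(v) for v in per_animal])
            work = np.stack([rebin_column(v, x) for v in per_animal])
            columns.append(work.mean(axis=0))
        n_rows = max((len(col) for col in columns), default=1) or 1
        grid = np.full((n_rows, n_cols), BACKGROUND)
        for c, col in enumerate(columns):
            grid[: len(col), c] = col
        out[wall] = grid
    return out


def average_and_normalize(
    datasets: list[AnimalDataset],
) -> tuple[dict[str, np.ndarray], float]:
    """Average animals, then normalize the result jointly across walls."""
    averaged = average_animals(datasets)
    return normalize_maps(averaged)
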