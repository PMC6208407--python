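"""Optical-density measurement and heatmap assembly.

Each probe yields one optical density (OD) per channel: the arithmetic mean
grey value over the probe rectangle truncated at its detected height.  Per
wall and quantity the probe values are arranged into a rectangular matrix —
rows follow the trace order (row 0 = trace start, i.e. the dorsal end for
the lateral/medial walls), columns run rostral (left) to caudal (right)
across the section series.  Cells without a probe (short walls, unanalyzed
sections) carry a NaN background sentinel.

For display, values are normalized to [0, 1] by the joint non-background
maximum across the three walls, so one colour scale spans the whole figure,
and the three walls are stacked into a single "unfolded ventricle" panel:
medial on top, dorsal in the middle, lateral at the bottom (the ventricle is
cut open at its ventral tip).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ColumnCountMismatchError, DuplicateMeasurementError, ProbeOutsideImageError
from .geometry import ProbeFrame, probe_pixels

BACKGROUND = np.nan
DEFAULT_STACK_ORDER = ("medial", "dorsal", "lateral")


def is_background(values: np.ndarray) -> np.ndarray:
    return np.isnan(values)


@dataclass
class ProbeMeasurement:
    """Everything measured for one probe."""

    section_index: int
    wall: str
    probe_index: int
    height_px: int
    thickness_um: float
    od_per_channel: dict[str, float]
    manual_override: bool = False
    low_confidence: bool = False


@dataclass
class WallMatrix:
    """Grid of per-probe values for one wall: rows = probes (trace order),
    columns = sections (rostral to caudal).  NaN marks absent cells."""

    wall: str
    quantity: str
    values: np.ndarray

    @property
    def n_sections(self) -> int:
        return self.values.shape[1]


@dataclass
class HeatmapSet:
    """Normalized [0, 1] wall matrices for one quantity plus the scale."""

    quantity: str
    walls: dict[str, np.ndarray]
    max_raw_value: float
    colormap: str = "jet"
    stack_order: tuple[str, ...] = DEFAULT_STACK_ORDER
    panel: np.ndarray | None = field(default=None, repr=False)


def measure_probe_od(channel: np.ndarray, frame: ProbeFrame, height_px: int) -> float:
    """Mean grey value over the probe rectangle truncated at ``height_px``."""
    rows, cols = probe_pixels(frame, height_px, channel.shape)
    if rows.size == 0:
        raise ProbeOutsideImageError("probe mask is empty after clipping")
    return float(np.mean(channel[rows, cols]))


def assemble_wall_matrix(
    measurements: list[ProbeMeasurement], quantity: str, n_sections: int
) -> WallMatrix:
    """Arrange one wall's probe values into a probes x sections grid.

    ``quantity`` is ``"thickness"`` or a channel name.  Row count is the
    maximum probe count over sections; shorter columns are padded with the
    background sentinel at the bottom (away from the trace start), and
    sections without measurements stay all-background.
    """
    if not measurements:
        raise ValueError("no measurements to assemble")
    walls = {m.wall for m in measurements}
    if len(walls) != 1:
        raise ValueError(f"measurements mix walls: {sorted(walls)}")
    seen: set[tuple[int, int]] = set()
    for m in measurements:
        key = (m.section_index, m.probe_index)
        if key in seen:
            raise DuplicateMeasurementError(
                f"duplicate measurement for section {m.section_index}, probe {m.probe_index}"
            )
        seen.add(key)
    n_rows = max(m.probe_index for m in measurements) + 1
    grid = np.full((n_rows, n_sections), BACKGROUND)
    for m in measurements:
        if not 0 <= m.section_index < n_sections:
            raise ValueError(f"section index {m.section_index} outside series of {n_sections}")
        if quantity == "thickness":
            grid[m.probe_index, m.section_index] = m.thickness_um
        else:
            grid[m.probe_index, m.section_index] = m.od_per_channel[quantity]
    return WallMatrix(wall=walls.pop(), quantity=quantity, values=grid)


def normalize_maps(matrices: dict[str, np.ndarray]) -> tuple[dict[str, np.ndarray], float]:
    """Scale wall matrices of one quantity jointly to [0, 1].

    Every non-background value is divided by the single non-background
    maximum taken across all walls, so the three stacked walls share one
    colour scale.  Background cells are untouched.  Returns the normalized
    matrices and the raw maximum (the value that maps to 1).
    """
    finite = [m[~np.isnan(m)] for m in matrices.values()]
    all_vals = np.concatenate([f for f in finite if f.size] or [np.empty(0)])
    max_raw = float(all_vals.max()) if all_vals.size else 0.0
    if max_raw <= 0:
        warnings.warn("all map values are zero; heatmap is uniformly background-blue", stacklevel=2)
        return {w: m.copy() for w, m in matrices.items()}, 0.0
    return {w: m / max_raw for w, m in matrices.items()}, max_raw


def normalize_map(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    """Single-matrix convenience wrapper around :func:`normalize_maps`."""
    normed, max_raw = normalize_maps({"_": matrix})
    return normed["_"], max_raw


def stack_walls(
    walls: dict[str, np.ndarray],
    order: tuple[str, ...] = DEFAULT_STACK_ORDER,
) -> np.ndarray:
    """Stack wall matrices into one unfolded panel.

    Bands follow ``order`` top to bottom, separated by single all-background
    divider rows.  All matrices must share the column (section) count; a wall
    absent from ``walls`` contributes nothing.
    """
    bands = [walls[w] for w in order if w in walls]
    if not bands:
        raise ValueError("no wall matrices to stack")
    n_cols = {b.shape[1] for b in bands}
    if len(n_cols) != 1:
        raise ColumnCountMismatchError(f"walls have differing section counts: {sorted(n_cols)}")
    divider = np.full((1, n_cols.pop()), BACKGROUND)
    rows: list[np.ndarray] = []
    for i, band in enumerate(bands):
        if i:
            rows.append(divider)
        rows.append(band)
    return np.vstack(rows)


def split_walls(
    panel: np.ndarray,
    heights: dict[str, int],
    order: tuple[str, ...] = DEFAULT_STACK_ORDER,
) -> dict[str, np.ndarray]:
    """Inverse of :func:`stack_walls` given each band's row count."""
    out: dict[str, np.ndarray] = {}
    r = 0
    for i, wall in enumerate(w for w in order if w in heights):
        if i:
            r += 1  # divider row
        h = heights[wall]
        out[wall] = panel[r : r + h]
        r += h
    return out


def build_heatmap_set(
    matrices: dict[str, WallMatrix],
    colormap: str = "jet",
    stack_order: tuple[str, ...] = DEFAULT_STACK_ORDER,
) -> HeatmapSet:
    """Normalize one quantity's wall matrices jointly and stack the panel."""
    quantities = {m.quantity for m in matrices.values()}
    if len(quantities) != 1:
        raise ValueError(f"matrices mix quantities: {sorted(quantities)}")
    normed, max_raw = normalize_maps({w: m.values for w, m in matrices.items()})
    panel = stack_walls(normed, order=stack_order)
    return HeatmapSet(
        quantity=quantities.pop(),
        walls=normed,
        max_raw_value=max_raw,
        colormap=colormap,
        stack_order=stack_order,
        panel=panel,
    )
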