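"""Reading section images and traces; writing value tables and heatmaps.

Sections arrive as one multi-channel (or multi-page) TIFF per coronal
section; the wall traces and the parenchymal reference region come as a JSON
document per section::

    {"section_index": 0,
     "walls": [{"wall": "lateral", "hemisphere": "right",
                "start": [r, c], "end": [r, c],
                "polyline": [[r, c], ...], "flip_normal": false}],
     "reference_points": [[r, c], [r, c]]}

Raw per-probe values are exported as one CSV per (wall, quantity) — rows are
probe indices from the trace start, columns are section indices, background
cells are empty — and the export/import round trip is lossless.  Excel
export is available for interoperability.  Heatmap panels are rendered to
PNG/TIFF with one pixel per cell (optionally upscaled) through a matplotlib
colormap; background cells are drawn in a dedicated colour that is not part
of the colormap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import matplotlib
import numpy as np
import pandas as pd
import tifffile

from .config import StudyConfig
from .errors import (
    ChannelCountMismatchError,
    DataError,
    MissingFileError,
    TraceOutOfBoundsError,
)
from .geometry import WallTrace
from .mapping import WallMatrix


@dataclass
class ChannelImage:
    """One fluorescence channel of a section."""

    pixels: np.ndarray
    microns_per_pixel: float
    channel_name: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.microns_per_pixel <= 0:
            raise DataError("microns_per_pixel must be positive")
        if not np.isfinite(self.pixels).all() or (self.pixels < 0).any():
            raise DataError(f"channel {self.channel_name!r} has negative or non-finite pixels")


@dataclass
class SectionRecord:
    """All channels of one coronal section, sharing dimensions and scale."""

    section_index: int
    channels: dict[str, ChannelImage]
    section_thickness_um: float

    def __post_init__(self) -> None:
        shapes = {ch.pixels.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise DataError(f"channels differ in shape: {sorted(shapes)}")
        if self.section_thickness_um <= 0:
            raise DataError("section_thickness_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).pixels.shape


@dataclass
class TraceDocument:
    """Wall traces + reference region for one section."""

    section_index: int
    walls: list[WallTrace]
    reference_points: np.ndarray

    def __post_init__(self) -> None:
        self.reference_points = np.asarray(self.reference_points, dtype=float)
        if self.reference_points.shape != (2, 2):
            raise DataError("reference_points must be two (row, col) points")


def _validate_in_bounds(doc: TraceDocument, shape: tuple[int, int]) -> None:
    points = [doc.reference_points]
    for w in doc.walls:
        points += [w.polyline, w.start[None, :], w.end[None, :]]
    pts = np.vstack(points)
    if (pts < 0).any() or (pts[:, 0] > shape[0] - 1).any() or (pts[:, 1] > shape[1] - 1).any():
        raise TraceOutOfBoundsError(
            f"section {doc.section_index}: trace coordinates fall outside image of shape {shape}"
        )


def read_trace(trace_path: str | Path) -> TraceDocument:
    trace_path = Path(trace_path)
    if not trace_path.exists():
        raise MissingFileError(f"trace file not found: {trace_path}")
    data = json.loads(trace_path.read_text())
    walls = [
        WallTrace(
            wall=w["wall"],
            hemisphere=w["hemisphere"],
            start=np.asarray(w["start"], dtype=float),
            end=np.asarray(w["end"], dtype=float),
            polyline=np.asarray(w["polyline"], dtype=float),
            flip_normal=bool(w.get("flip_normal", False)),
        )
        for w in data["walls"]
    ]
    return TraceDocument(
        section_index=int(data["section_index"]),
        walls=walls,
        reference_points=np.asarray(data["reference_points"], dtype=float),
    )


def write_trace(doc: TraceDocument, trace_path: str | Path) -> None:
    data = {
        "section_index": doc.section_index,
        "walls": [
            {
                "wall": w.wall,
                "hemisphere": w.hemisphere,
                "start": w.start.tolist(),
                "end": w.end.tolist(),
                "polyline": w.polyline.tolist(),
                "flip_normal": w.flip_normal,
            }
            for w in doc.walls
        ],
        "reference_points": doc.reference_points.tolist(),
    }
    Path(trace_path).write_text(json.dumps(data))


def _channels_first(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr[None, :, :]
    if arr.ndim != 3:
        raise DataError(f"unsupported TIFF dimensionality {arr.ndim}")
    # channel axis is whichever of the first/last axes is smaller
    if arr.shape[0] <= arr.shape[2]:
        return arr
    return np.moveaxis(arr, -1, 0)


def load_section(
    image_path: str | Path, trace_path: str | Path, config: StudyConfig
) -> tuple[SectionRecord, TraceDocument]:
    """Read one section TIFF and its trace document, cross-validated.

    The TIFF channel count must match ``config.channels`` and every trace
    coordinate must fall inside the image.
    """
    image_path = Path(image_path)
    if not image_path.exists():
        raise MissingFileError(f"image file not found: {image_path}")
    arr = _channels_first(tifffile.imread(image_path))
    if arr.shape[0] != len(config.channels):
        raise ChannelCountMismatchError(
            f"{image_path.name}: {arr.shape[0]} channel(s) in TIFF, "
            f"config expects {len(config.channels)} ({config.channels})"
        )
    doc = read_trace(trace_path)
    _validate_in_bounds(doc, arr.shape[1:])
    channels = {
        name: ChannelImage(
            pixels=arr[i], microns_per_pixel=config.microns_per_pixel, channel_name=name
        )
        for i, name in enumerate(config.channels)
    }
    record = SectionRecord(
        section_index=doc.section_index,
        channels=channels,
        section_thickness_um=config.section_thickness_um,
    )
    return record, doc


def write_section_tiff(record: SectionRecord, image_path: str | Path) -> None:
    """Write a section as a channels-first multi-page TIFF (uint16)."""
    stack = np.stack(
        [np.clip(np.round(ch.pixels), 0, 65535).astype(np.uint16) for ch in record.channels.values()]
    )
    tifffile.imwrite(image_path, stack, photometric="minisblack")


def export_values(
    matrices: list[WallMatrix], out_dir: str | Path, fmt: str = "csv", prefix: str = "values"
) -> list[Path]:
    """Write one table per (wall, quantity): rows = probe index, columns =
    section index, background as empty cells.  Returns the written paths."""
    if fmt not in ("csv", "xlsx"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m in matrices:
        df = pd.DataFrame(
            m.values,
            index=pd.RangeIndex(m.values.shape[0], name="probe_index"),
            columns=[str(c) for c in range(m.values.shape[1])],
        )
        path = out_dir / f"{prefix}_{m.wall}_{m.quantity}.{fmt}"
        if fmt == "csv":
            df.to_csv(path, float_format="%.17g")
        else:
            df.to_excel(path)
        paths.append(path)
    return paths


def read_values(path: str | Path) -> np.ndarray:
    """Read a value table back into a matrix (empty cells become NaN)."""
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"value table not found: {path}")
    if path.suffix == ".xlsx":
        df = pd.read_excel(path, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float)


BACKGROUND_RGB = (255, 255, 255)


def export_heatmap_image(
    heatmap: np.ndarray,
    colormap: str,
    path: str | Path,
    scale: int = 1,
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB,
) -> Path:
    """Render a normalized heatmap to an image file.

    One pixel per cell (``scale`` upsamples by integer replication); values
    must lie in [0, 1]; background (NaN) cells are painted
    ``background_rgb`` and never pass through the colormap.
    """
    values = np.asarray(heatmap, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size and (finite.min() < 0 or finite.max() > 1 + 1e-12):
        raise DataError("heatmap values must lie in [0, 1]; normalize before export")
    cmap = matplotlib.colormaps[colormap]
    rgba = cmap(np.nan_to_num(values, nan=0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[np.isnan(values)] = np.asarray(background_rgb, dtype=np.uint8)
    if scale > 1:
        rgb = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, rgb)
    else:
        iio.imwrite(path, rgb)
    return path
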