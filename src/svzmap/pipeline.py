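"""End-to-end analysis: geometry -> thickness -> OD -> maps -> export.

The pipeline consumes an iterable of (SectionRecord, TraceDocument) pairs —
loaded from disk or generated by the phantom module — and produces, per
quantity (thickness plus one OD per channel), raw wall matrices, optionally
interpolated matrices with a provenance grid, and normalized stacked
heatmaps.  Sections are processed one at a time so a full series never has
to reside in memory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .config import StudyConfig
from .errors import DataError, UnknownProbeError
from .interpolation import SubsamplingScheme, interpolate_matrix
from .io import SectionRecord, TraceDocument, export_heatmap_image, export_values
from .mapping import (
    BACKGROUND,
    HeatmapSet,
    ProbeMeasurement,
    WallMatrix,
    assemble_wall_matrix,
    build_heatmap_set,
    measure_probe_od,
    normalize_map,
    stack_walls,
)
from .geometry import compute_frames, resample_contour
from .thickness import reference_histogram, estimate_height, section_bin_edges

OverrideKey = tuple[int, str, int]


@dataclass
class StudyResult:
    """Everything the analysis produced, quantity-major."""

    config: StudyConfig
    measurements: list[ProbeMeasurement]
    measured: dict[str, dict[str, WallMatrix]]
    matrices: dict[str, dict[str, WallMatrix]]
    provenance: dict[str, np.ndarray]
    heatmaps: dict[str, HeatmapSet]
    probe_log: list[dict] = field(default_factory=list)

    @property
    def quantities(self) -> list[str]:
        return list(self.matrices)


def analyze_section(
    record: SectionRecord,
    doc: TraceDocument,
    config: StudyConfig,
    overrides: dict[OverrideKey, int] | None = None,
) -> list[ProbeMeasurement]:
    """Measure every probe of one section: detect heights, then mean ODs."""
    if record.section_index != doc.section_index:
        raise DataError(
            f"image is section {record.section_index} but trace is {doc.section_index}"
        )
    overrides = overrides or {}
    dapi = record.channels[config.dapi_channel].pixels
    hs = config.height_search
    edges = section_bin_edges(dapi, hs.n_bins)
    ref = reference_histogram(dapi, doc.reference_points, edges)
    measurements: list[ProbeMeasurement] = []
    for trace in doc.walls:
        anchors = resample_contour(trace.polyline, config.probe_width_px)
        frames = compute_frames(
            anchors,
            trace.polyline,
            trace.wall,
            trace.hemisphere,
            config.probe_width_px,
            flip_normal=trace.flip_normal,
        )
        for frame in frames:
            result = estimate_height(dapi, frame, ref, hs, config.microns_per_pixel)
            key = (record.section_index, trace.wall, frame.index)
            if key in overrides:
                height = int(overrides[key])
                if height < 1:
                    raise ValueError(f"override height must be >= 1 px, got {height}")
                result.n_opt = height
                result.thickness_um = height * config.microns_per_pixel
                result.manual_override = True
                result.low_confidence = False
            ods = {
                name: measure_probe_od(ch.pixels, frame, result.n_opt)
                for name, ch in record.channels.items()
            }
            measurements.append(
                ProbeMeasurement(
                    section_index=record.section_index,
                    wall=trace.wall,
                    probe_index=frame.index,
                    height_px=result.n_opt,
                    thickness_um=result.thickness_um,
                    od_per_channel=ods,
                    manual_override=result.manual_override,
                    low_confidence=result.low_confidence,
                )
            )
    return measurements


def analyze_sections(
    sections,
    config: StudyConfig,
    overrides: dict[OverrideKey, int] | None = None,
) -> StudyResult:
    """Run the full workflow over an iterable of (record, trace) pairs."""
    overrides = dict(overrides or {})
    measurements: list[ProbeMeasurement] = []
    seen_sections: set[int] = set()
    for record, doc in sections:
        measurements.extend(analyze_section(record, doc, config, overrides))
        seen_sections.add(record.section_index)
    unused = {k for k in overrides if k[0] in seen_sections} - {
        (m.section_index, m.wall, m.probe_index) for m in measurements
    }
    unused |= {k for k in overrides if k[0] not in seen_sections}
    if unused:
        raise UnknownProbeError(f"overrides reference unknown probes: {sorted(unused)}")
    if not measurements:
        raise DataError("no sections were analyzed")
    return assemble_study(measurements, config)


def assemble_study(
    measurements: list[ProbeMeasurement], config: StudyConfig
) -> StudyResult:
    """Assemble matrices, interpolate subsampled series, build heatmaps."""
    walls = sorted({m.wall for m in measurements})
    quantities = ["thickness", *config.channels]
    scheme = SubsamplingScheme(n=config.subsample_n, start_offset=config.start_offset)

    measured: dict[str, dict[str, WallMatrix]] = {}
    final: dict[str, dict[str, WallMatrix]] = {}
    provenance: dict[str, np.ndarray] = {}
    for q in quantities:
        measured[q] = {}
        final[q] = {}
        for wall in walls:
            wall_ms = [m for m in measurements if m.wall == wall]
            matrix = assemble_wall_matrix(wall_ms, q, config.n_sections)
            measured[q][wall] = matrix
            filled, prov = interpolate_matrix(
                matrix.values, scheme, intrasection=config.intrasection
            )
            final[q][wall] = WallMatrix(wall=wall, quantity=q, values=filled)
            provenance[wall] = prov  # identical across quantities for one wall
    heatmaps = {
        q: _heatmap_for(final[q], config) for q in quantities
    }
    probe_log = [
        {
            "section_index": m.section_index,
            "wall": m.wall,
            "probe_index": m.probe_index,
            "n_opt_px": m.height_px,
            "thickness_um": m.thickness_um,
            "manual_override": m.manual_override,
            "low_confidence": m.low_confidence,
        }
        for m in measurements
    ]
    return StudyResult(
        config=config,
        measurements=measurements,
        measured=measured,
        matrices=final,
        provenance=provenance,
        heatmaps=heatmaps,
        probe_log=probe_log,
    )


def _heatmap_for(matrices: dict[str, WallMatrix], config: StudyConfig) -> HeatmapSet:
    if config.normalize_across_walls:
        return build_heatmap_set(matrices, colormap=config.colormap)
    normed: dict[str, np.ndarray] = {}
    max_raw = 0.0
    for wall, m in matrices.items():
        normed[wall], mr = normalize_map(m.values)
        max_raw = max(max_raw, mr)
    quantity = next(iter(matrices.values())).quantity
    panel = stack_walls(normed)
    return HeatmapSet(
        quantity=quantity,
        walls=normed,
        max_raw_value=max_raw,
        colormap=config.colormap,
        panel=panel,
    )


def config_hash(config: StudyConfig) -> str:
    blob = yaml.safe_dump(
        {**config.__dict__, "height_search": config.height_search.__dict__}, sort_keys=True
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def export_study(result: StudyResult, out_dir: str | Path, scale: int = 8) -> dict[str, list[str]]:
    """Write raw + interpolated tables, provenance, heatmaps and the log.

    Every heatmap has a sibling raw-value table and a provenance grid, so no
    figure exists without its underlying numbers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"tables": [], "heatmaps": [], "provenance": []}
    for q, wall_ms in result.measured.items():
        paths = export_values(list(wall_ms.values()), out_dir, prefix="raw")
        written["tables"] += [p.name for p in paths]
    for q, wall_ms in result.matrices.items():
        paths = export_values(list(wall_ms.values()), out_dir, prefix="values")
        written["tables"] += [p.name for p in paths]
    for wall, prov in result.provenance.items():
        path = out_dir / f"provenance_{wall}.csv"
        np.savetxt(path, prov, fmt="%d", delimiter=",")
        written["provenance"].append(path.name)
    for q, hm in result.heatmaps.items():
        path = out_dir / f"heatmap_{q}.png"
        export_heatmap_image(hm.panel, hm.colormap, path, scale=scale)
        written["heatmaps"].append(path.name)
        uv = out_dir / f"heatmap_{q}_uv.png"
        export_heatmap_image(hm.panel, hm.colormap, uv, scale=1)
        written["heatmaps"].append(uv.name)
    log = {
        "config_hash": config_hash(result.config),
        "max_raw_value": {q: hm.max_raw_value for q, hm in result.heatmaps.items()},
        "probes": result.probe_log,
    }
    (out_dir / "analysis_log.json").write_text(json.dumps(log, indent=1))
    return written
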