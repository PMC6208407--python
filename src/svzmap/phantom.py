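"""Synthetic serial-section phantoms with known SVZ geometry.

The phantom emulates the features of a counterstained coronal section that
the analysis relies on: a gently curved ventricular lumen with medial,
dorsal and lateral walls; a band of high nuclear density (the SVZ) of known,
smoothly varying thickness hugging each wall's apical face; sparser
nuclei-speckled parenchyma outside; a nearly empty lumen; and marker
channels whose expression inside the band follows prescribed spatial
gradients.  Nuclei are fixed-radius discs at Poisson-random centres plus
Gaussian read noise, which gives the band and the parenchyma grey-value
histograms of controllable contrast — the property the divergence-based
height detector keys on.

Every section comes with a matching trace document (the polyline follows
the true contour) and the series comes with analytic ground-truth maps of
thickness and marker expression sampled at the same probe anchors the
pipeline will use, so recovered maps are grid-aligned with truth.

The default series — 43 sections of 1024 x 1024 px at 0.64 um/px, 50 um
probes — mimics a complete postnatal mouse study: wall thickness 52-128 px
with a localized thickness "hotspot" on the lateral wall (the neuroblast
accumulation at the RMS entry), one marker ramping dorso-ventrally and one
anticorrelated with thickness (thick caudal walls of low density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .config import StudyConfig
from .geometry import resample_contour
from .io import ChannelImage, SectionRecord, TraceDocument, WallTrace


@dataclass
class PhantomSpec:
    """Parametric ground truth for a synthetic section series."""

    image_shape: tuple[int, int] = (1024, 1024)
    microns_per_pixel: float = 0.64
    section_thickness_um: float = 50.0
    n_sections: int = 43
    seed: int = 0

    # geometry, as fractions of the image shape
    wall_top: float = 0.26
    wall_bottom: float = 0.60
    lumen_left: float = 0.42
    lumen_right: float = 0.58
    curvature: float = 0.02
    # the dense band continues past the traced ROI (tissue does not stop at
    # the user's start/end clicks); probes near the ends still see band
    band_margin_px: float = 80.0

    # thickness profile t(wall, s, sec) in px
    base_thickness_px: float = 70.0
    thickness_amplitude_px: float = 18.0
    # smooth per-animal deviation from the cohort profile (seed-dependent):
    # individual brains differ, which is what cohort averaging evens out
    animal_variation_px: float = 4.0
    hotspot_amplitude_px: float = 40.0
    hotspot_s: float = 0.35
    hotspot_section: float = 0.4
    hotspot_sigma: float = 0.13

    # nuclei texture (centres per px^2) and intensities
    nucleus_radius_px: int = 3
    band_density: float = 0.04
    parenchyma_density: float = 0.006
    lumen_density: float = 0.0005
    background_level: float = 15.0
    # crowded somata and out-of-focus light lift the counterstain floor
    # inside the dense band, as in real germinal-zone sections
    band_background_boost: float = 25.0
    nucleus_level: float = 180.0
    noise_sd: float = 6.0
    # smooth multiplicative gain field emulating staining and illumination
    # inhomogeneity between sections and animals (fractional amplitude)
    illumination_amplitude: float = 0.03
    illumination_grid: int = 8

    # marker channels
    marker_channels: tuple[str, ...] = ("marker1", "marker2")
    marker_background: float = 8.0
    anticorrelated_marker: str = "marker2"

    # reference region (fractions); kept in far parenchyma
    reference_block: tuple[float, float, float, float] = (0.90, 0.98, 0.88, 0.98)

    walls: tuple[str, ...] = ("medial", "dorsal", "lateral")
    hemisphere: str = "right"
    trace_step_px: float = 4.0

    def __post_init__(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if self.base_thickness_px - self.thickness_amplitude_px <= 0:
            raise ValueError("thickness profile dips below zero")


@dataclass
class GroundTruth:
    """Analytic per-probe truth, grid-aligned with the pipeline output."""

    thickness: dict[str, np.ndarray]
    expression: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)


# ----------------------------------------------------------------- geometry


def _wall_rows(spec: PhantomSpec) -> tuple[float, float]:
    h = spec.image_shape[0]
    return spec.wall_top * h, spec.wall_bottom * h


def _lumen_cols(spec: PhantomSpec) -> tuple[float, float]:
    w = spec.image_shape[1]
    return spec.lumen_left * w, spec.lumen_right * w


def _bulge(spec: PhantomSpec, frac: np.ndarray) -> np.ndarray:
    return spec.curvature * spec.image_shape[1] * np.sin(np.pi * frac)


def contour_col(spec: PhantomSpec, wall: str, rows: np.ndarray) -> np.ndarray:
    """Column of the vertical (medial/lateral) wall contour at given rows."""
    r0, r1 = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    frac = np.clip((rows - r0) / (r1 - r0), 0.0, 1.0)  # straight beyond the ROI
    if wall == "lateral":
        return c_lat + _bulge(spec, frac)
    if wall == "medial":
        return c_med - _bulge(spec, frac)
    raise ValueError(wall)


def contour_row(spec: PhantomSpec, cols: np.ndarray) -> np.ndarray:
    """Row of the dorsal wall contour at given columns (arches upward)."""
    r0, _ = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    frac = np.clip((c_lat - cols) / (c_lat - c_med), 0.0, 1.0)
    return r0 - 0.75 * _bulge(spec, frac)


def thickness_px(spec: PhantomSpec, wall: str, s: np.ndarray, section_index: int) -> np.ndarray:
    """True SVZ thickness (px, along the local normal) at arc fraction s.

    The cohort-level profile (base sinusoid + lateral hotspot) is shared by
    every seed; on top of it each animal carries a smooth, seed-determined
    deviation of amplitude ``animal_variation_px``.
    """
    s = np.asarray(s, dtype=float)
    sec = section_index / max(1, spec.n_sections - 1)
    phase = {"medial": 0.15, "dorsal": 0.45, "lateral": 0.75}[wall]
    t = spec.base_thickness_px + spec.thickness_amplitude_px * np.sin(
        2 * np.pi * (0.5 * s + 0.3 * sec + phase)
    )
    if wall == "lateral" and spec.hotspot_amplitude_px:
        t = t + spec.hotspot_amplitude_px * np.exp(
            -(
                (s - spec.hotspot_s) ** 2 + (sec - spec.hotspot_section) ** 2
            )
            / (2 * spec.hotspot_sigma**2)
        )
    return t + _animal_deviation(spec, wall, s, sec)


def _animal_deviation(spec: PhantomSpec, wall: str, s: np.ndarray, sec: float) -> np.ndarray:
    """Seed-determined smooth deviation of one animal from the cohort profile.

    A short sum of low-frequency separable sinusoids (slow along both the
    wall and the series, so subsampled series still resolve it), scaled to
    ``animal_variation_px``.
    """
    if spec.animal_variation_px <= 0:
        return np.zeros_like(np.asarray(s, dtype=float))
    wall_idx = {"lateral": 0, "dorsal": 1, "medial": 2}[wall]
    gen = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7919, wall_idx]))
    out = np.zeros_like(np.asarray(s, dtype=float))
    for _ in range(3):
        fs, fsec = gen.uniform(0.3, 1.2, 2)
        ps, psec = gen.uniform(0, 1, 2)
        out = out + gen.normal(0, 1) * np.sin(2 * np.pi * (fs * s + ps)) * np.sin(
            2 * np.pi * (fsec * sec + psec)
        )
    # unit-variance deviation, clipped at 2 sigma so the band always stays
    # within the detectable thickness range
    return spec.animal_variation_px * np.clip(out / np.sqrt(0.75), -2.0, 2.0)


def marker_expression(
    spec: PhantomSpec, channel: str, wall: str, s: np.ndarray, section_index: int
) -> np.ndarray:
    """True marker level inside the band at arc fraction s.

    The default first marker ramps dorso-ventrally (monotone in s); the
    anticorrelated marker decreases linearly with local thickness.
    """
    s = np.asarray(s, dtype=float)
    if channel == spec.anticorrelated_marker:
        t = thickness_px(spec, wall, s, section_index)
        return 230.0 - 1.4 * t
    return 40.0 + 160.0 * s


# ----------------------------------------------------------------- rendering


def _disk_kernel(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    return (rr**2 + cc**2 <= radius**2).astype(float)


def _band_and_lumen_masks(
    spec: PhantomSpec, section_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean band mask and lumen mask.

    The band of a vertical wall at row r spans the perpendicular distance
    range [0, t) on the tissue side of the contour; the small contour slope
    is corrected with a cos factor so that the drawn width along the true
    normal equals the prescribed thickness.
    """
    h, w = spec.image_shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    r0, r1 = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    band = np.zeros(spec.image_shape, dtype=bool)
    m = spec.band_margin_px

    in_rows = (rows >= r0 - m) & (rows <= r1 + m)
    frac_v = np.clip((rows - r0) / (r1 - r0), 0, 1)
    dcol = np.where(
        (rows >= r0) & (rows <= r1), _bulge_slope(spec, frac_v), 0.0
    )  # d(col)/d(row) of the lateral contour; straight beyond the ROI
    cos_v = 1.0 / np.sqrt(1.0 + dcol**2)

    for wall in spec.walls:
        if wall in ("lateral", "medial"):
            c_wall = contour_col(spec, wall, rows)
            t = thickness_px(spec, wall, frac_v, section_index)
            signed = (cols - c_wall) if wall == "lateral" else (c_wall - cols)
            mask = in_rows & (signed >= 0) & (signed * cos_v < t)
        else:  # dorsal: band above the arched contour
            inside_c = (cols >= c_med - m) & (cols <= c_lat + m)
            frac_h = np.clip((c_lat - cols) / (c_lat - c_med), 0, 1)
            r_wall = contour_row(spec, cols)
            t = thickness_px(spec, wall, frac_h, section_index)
            drow = np.where(
                (cols >= c_med) & (cols <= c_lat), 0.75 * _bulge_slope_h(spec, frac_h), 0.0
            )
            cos_h = 1.0 / np.sqrt(1.0 + drow**2)
            signed = r_wall - rows
            mask = inside_c & (signed >= 0) & (signed * cos_h < t)
        band |= mask
    lumen = (
        (rows >= contour_row(spec, cols))
        & (rows <= r1)
        & (cols > contour_col(spec, "medial", rows))
        & (cols < contour_col(spec, "lateral", rows))
        & ~band
    )
    return band, lumen


def _bulge_slope(spec: PhantomSpec, frac: np.ndarray) -> np.ndarray:
    r0, r1 = _wall_rows(spec)
    return (
        spec.curvature * spec.image_shape[1] * np.pi * np.cos(np.pi * frac) / (r1 - r0)
    )


def _bulge_slope_h(spec: PhantomSpec, frac: np.ndarray) -> np.ndarray:
    c_med, c_lat = _lumen_cols(spec)
    return (
        spec.curvature * spec.image_shape[1] * np.pi * np.cos(np.pi * frac) / (c_lat - c_med)
    )


def _marker_field(spec: PhantomSpec, channel: str, section_index: int) -> np.ndarray:
    """Marker expression level for every pixel (evaluated on the arc fraction
    of the pixel's own wall; outside any band the value is irrelevant)."""
    h, w = spec.image_shape
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    r0, r1 = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    frac_v = np.clip((rows - r0) / (r1 - r0), 0, 1)
    frac_h = np.clip((c_lat - cols) / (c_lat - c_med), 0, 1)
    field_v = marker_expression(spec, channel, "lateral", frac_v, section_index)
    field_v_med = marker_expression(spec, channel, "medial", frac_v, section_index)
    field_h = marker_expression(spec, channel, "dorsal", frac_h, section_index)
    mid = (c_med + c_lat) / 2
    lateral_side = cols >= mid
    out = np.where(lateral_side, field_v, field_v_med)
    dorsal_zone = rows < (r0 + 1)
    return np.where(dorsal_zone, field_h, out)


def _illumination_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative gain field (mean ~1) over the section."""
    if spec.illumination_amplitude <= 0:
        return np.ones(spec.image_shape)
    from scipy.ndimage import zoom

    g = spec.illumination_grid
    coarse = rng.normal(0.0, 1.0, (g + 1, g + 1))
    field = zoom(coarse, (spec.image_shape[0] / (g + 1), spec.image_shape[1] / (g + 1)), order=3)
    field = field[: spec.image_shape[0], : spec.image_shape[1]]
    return 1.0 + spec.illumination_amplitude * (field - field.mean()) / max(field.std(), 1e-9)


def generate_section(spec: PhantomSpec, section_index: int) -> tuple[SectionRecord, TraceDocument]:
    """Render one synthetic section and its matching trace document.

    Deterministic for a fixed (seed, section_index); sections are mutually
    independent streams, so generating a subsampled series reproduces the
    exact pixels of the full series.
    """
    if not 0 <= section_index < spec.n_sections:
        raise ValueError(f"section_index {section_index} outside [0, {spec.n_sections})")
    h, w = spec.image_shape
    band, lumen = _band_and_lumen_masks(spec, section_index)
    if band[:, 0].any() or band[:, -1].any() or band[0, :].any() or band[-1, :].any():
        raise ValueError("SVZ band exits the image bounds; shrink geometry or thickness")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), int(section_index)]))
    gain = _illumination_field(spec, rng)

    density = np.full(spec.image_shape, spec.parenchyma_density)
    density[band] = spec.band_density
    density[lumen] = spec.lumen_density
    centres = rng.random(spec.image_shape) < density
    nuclei = fftconvolve(centres.astype(float), _disk_kernel(spec.nucleus_radius_px), mode="same")
    nuclei = nuclei > 0.5
    dapi = spec.background_level + spec.band_background_boost * band + spec.nucleus_level * nuclei
    dapi = dapi * gain + rng.normal(0.0, spec.noise_sd, spec.image_shape)
    channels = {
        "dapi": ChannelImage(
            pixels=np.clip(dapi, 0, None),
            microns_per_pixel=spec.microns_per_pixel,
            channel_name="dapi",
        )
    }
    for channel in spec.marker_channels:
        level = _marker_field(spec, channel, section_index)
        img = np.where(band, level, spec.marker_background) * gain + rng.normal(
            0.0, spec.noise_sd, spec.image_shape
        )
        channels[channel] = ChannelImage(
            pixels=np.clip(img, 0, None),
            microns_per_pixel=spec.microns_per_pixel,
            channel_name=channel,
        )
    record = SectionRecord(
        section_index=section_index,
        channels=channels,
        section_thickness_um=spec.section_thickness_um,
    )
    return record, make_trace(spec, section_index)


def make_trace(spec: PhantomSpec, section_index: int) -> TraceDocument:
    """Trace document whose polylines follow the true contours exactly."""
    r0, r1 = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    h, w = spec.image_shape
    walls = []
    rows = np.arange(r0, r1 + 1e-9, spec.trace_step_px)
    rows = np.append(rows, r1) if rows[-1] < r1 else rows
    for wall in spec.walls:
        if wall in ("lateral", "medial"):
            poly = np.column_stack([rows, contour_col(spec, wall, rows)])
        else:
            cols = np.arange(c_lat, c_med - 1e-9, -spec.trace_step_px)
            cols = np.append(cols, c_med) if cols[-1] > c_med else cols
            poly = np.column_stack([contour_row(spec, cols), cols])
        walls.append(
            WallTrace(
                wall=wall,
                hemisphere=spec.hemisphere,
                start=poly[0],
                end=poly[-1],
                polyline=poly,
            )
        )
    rb = spec.reference_block
    reference_points = np.array(
        [[rb[0] * h, rb[2] * w], [rb[1] * h, rb[3] * w]]
    )
    return TraceDocument(
        section_index=section_index, walls=walls, reference_points=reference_points
    )


def iter_sections(spec: PhantomSpec, section_indices=None):
    """Lazily yield (SectionRecord, TraceDocument) pairs."""
    indices = range(spec.n_sections) if section_indices is None else section_indices
    for i in indices:
        yield generate_section(spec, i)


def generate_series(spec: PhantomSpec, probe_width_px: float | None = None):
    """All sections of the series plus the analytic ground truth.

    Note the full default series holds ~500 MB of pixels; prefer
    :func:`iter_sections` plus :func:`ground_truth` for large studies.
    """
    sections = list(iter_sections(spec))
    width = probe_width_px if probe_width_px is not None else 50.0 / spec.microns_per_pixel
    return sections, ground_truth(spec, width)


def _anchor_fractions(spec: PhantomSpec, wall: str, probe_width_px: float) -> np.ndarray:
    """Arc fraction of each probe anchor along a wall's contour."""
    doc = make_trace(spec, 0)
    trace = next(t for t in doc.walls if t.wall == wall)
    anchors = resample_contour(trace.polyline, probe_width_px)
    r0, r1 = _wall_rows(spec)
    c_med, c_lat = _lumen_cols(spec)
    if wall in ("lateral", "medial"):
        return np.clip((anchors[:, 0] - r0) / (r1 - r0), 0, 1)
    return np.clip((c_lat - anchors[:, 1]) / (c_lat - c_med), 0, 1)


def ground_truth(spec: PhantomSpec, probe_width_px: float) -> GroundTruth:
    """Analytic thickness and expression maps at the pipeline's own anchors.

    Thickness is reported in micrometres (as the pipeline reports it);
    expression in raw grey levels.  The contour is identical across
    sections, so each wall's probe count is constant along the series.
    """
    thickness: dict[str, np.ndarray] = {}
    expression: dict[str, dict[str, np.ndarray]] = {c: {} for c in spec.marker_channels}
    for wall in spec.walls:
        s = _anchor_fractions(spec, wall, probe_width_px)
        t = np.empty((len(s), spec.n_sections))
        for sec in range(spec.n_sections):
            t[:, sec] = thickness_px(spec, wall, s, sec)
        thickness[wall] = t * spec.microns_per_pixel
        for channel in spec.marker_channels:
            g = np.empty((len(s), spec.n_sections))
            for sec in range(spec.n_sections):
                g[:, sec] = marker_expression(spec, channel, wall, s, sec)
            expression[channel][wall] = g
    return GroundTruth(thickness=thickness, expression=expression)


def study_config(spec: PhantomSpec, **overrides) -> StudyConfig:
    """StudyConfig matching a phantom spec's channels and calibration."""
    defaults = dict(
        channels=["dapi", *spec.marker_channels],
        dapi_channel="dapi",
        microns_per_pixel=spec.microns_per_pixel,
        section_thickness_um=spec.section_thickness_um,
        n_sections=spec.n_sections,
    )
    defaults.update(overrides)
    return StudyConfig(**defaults)
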