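"""Probe geometry along a traced apical (ventricular) contour.

The user traces the apical face of one SVZ wall as a polyline.  This module
resamples that contour into equally spaced probe anchors, attaches a local
orthonormal frame (tangent + inward normal) to each anchor, and rasterizes
the rectangular probe footprint used for histogram and optical-density
measurements.

Coordinate convention: pixel coordinates are 0-based ``(row, col)`` with rows
increasing downward (ventrally, for a coronal section displayed dorsal-side
up) and columns increasing to the right.  All geometry is carried in pixel
units; conversion to micrometres happens only at reporting time.

Tracing convention: the lateral and medial walls are traced from dorsal to
ventral, the dorsal wall from lateral to medial, regardless of hemisphere.
Together with the hemisphere this fixes on which side of the tangent the
tissue lies, which is how the inward (apical-to-basal) normal direction is
chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContourTooShortError, DegenerateTangentError, ProbeOutsideImageError

WALLS = ("lateral", "dorsal", "medial")
HEMISPHERES = ("left", "right")

# Sign of the perpendicular (-dc, dr) of the tangent (dr, dc) that points
# away from the ventricle lumen into the tissue, assuming the standard
# tracing directions and a coronal image with the right hemisphere on the
# right.  ``flip_normal`` on the trace overrides this for unusual anatomy.
_NORMAL_SIGN: dict[tuple[str, str], int] = {
    ("lateral", "right"): +1,
    ("lateral", "left"): -1,
    ("medial", "right"): -1,
    ("medial", "left"): +1,
    ("dorsal", "right"): -1,
    ("dorsal", "left"): +1,
}


@dataclass
class WallTrace:
    """Apical contour of one SVZ wall in one section.

    ``polyline`` is an ``(n, 2)`` array of ``(row, col)`` points ordered from
    ``start`` to ``end`` following the tracing convention above.
    """

    wall: str
    hemisphere: str
    start: np.ndarray
    end: np.ndarray
    polyline: np.ndarray
    flip_normal: bool = False

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.polyline = np.asarray(self.polyline, dtype=float)
        if self.wall not in WALLS:
            raise ValueError(f"unknown wall {self.wall!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")
        if self.polyline.ndim != 2 or self.polyline.shape[0] < 2 or self.polyline.shape[1] != 2:
            raise ValueError("polyline must be an (n>=2, 2) array of points")
        if np.linalg.norm(self.polyline[0] - self.start) > 1.0 + 1e-9:
            raise ValueError("polyline does not begin at the start point (within 1 px)")
        if np.linalg.norm(self.polyline[-1] - self.end) > 1.0 + 1e-9:
            raise ValueError("polyline does not end at the end point (within 1 px)")


@dataclass
class ProbeFrame:
    """One probe's local frame: anchor on the contour, unit tangent, and unit
    inward normal pointing apical -> basal (into the tissue)."""

    index: int
    anchor: np.ndarray
    tangent: np.ndarray
    inward_normal: np.ndarray
    width_px: float
    height_px: float | None = field(default=None)


def arc_length(polyline: np.ndarray) -> np.ndarray:
    """Cumulative arc length at each vertex (first entry 0)."""
    poly = np.asarray(polyline, dtype=float)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at(polyline: np.ndarray, s: np.ndarray | float) -> np.ndarray:
    """Point(s) on the polyline at arc-length position(s) ``s`` (clamped)."""
    poly = np.asarray(polyline, dtype=float)
    cum = arc_length(poly)
    s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, cum[-1])
    r = np.interp(s, cum, poly[:, 0])
    c = np.interp(s, cum, poly[:, 1])
    return np.column_stack([r, c])


def resample_contour(polyline: np.ndarray, spacing_px: float) -> np.ndarray:
    """Equally spaced probe anchors along the contour.

    Anchors sit at probe centres, i.e. at arc positions ``spacing/2,
    3*spacing/2, ...``; a contour of arc length ``L`` yields
    ``floor(L / spacing)`` anchors, so a trailing arc shorter than one probe
    is dropped.
    """
    if spacing_px <= 0:
        raise ValueError("spacing_px must be positive")
    total = arc_length(polyline)[-1]
    n = int(np.floor(total / spacing_px))
    if n < 1:
        raise ContourTooShortError(
            f"contour arc length {total:.1f} px is shorter than one probe ({spacing_px:.1f} px)"
        )
    centres = (np.arange(n) + 0.5) * spacing_px
    return point_at(polyline, centres)


def compute_frames(
    anchors: np.ndarray,
    polyline: np.ndarray,
    wall: str,
    hemisphere: str,
    width_px: float,
    flip_normal: bool = False,
) -> list[ProbeFrame]:
    """Attach tangent and inward-normal unit vectors to each anchor.

    The tangent is a central difference of the arc-length parameterized
    contour; the inward normal is the tangent rotated +-90 deg with the sign
    given by the (wall, hemisphere) lookup so that it points from the apical
    face into the tissue.
    """
    poly = np.asarray(polyline, dtype=float)
    cum = arc_length(poly)
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    # recover the arc position of each anchor by projection onto the contour
    s_anchor = _arc_position(poly, cum, anchors)
    delta = max(1.0, float(np.min(np.diff(cum)[np.diff(cum) > 0], initial=1.0)))
    ahead = point_at(poly, s_anchor + delta)
    behind = point_at(poly, s_anchor - delta)
    sign = _NORMAL_SIGN[(wall, hemisphere)] * (-1 if flip_normal else 1)
    frames: list[ProbeFrame] = []
    for i, anchor in enumerate(anchors):
        d = ahead[i] - behind[i]
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise DegenerateTangentError(f"zero-length tangent at anchor {i}")
        t = d / norm
        n = sign * np.array([-t[1], t[0]])
        frames.append(
            ProbeFrame(index=i, anchor=anchor, tangent=t, inward_normal=n, width_px=float(width_px))
        )
    return frames


def _arc_position(poly: np.ndarray, cum: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Arc-length position of each point, assumed to lie on the polyline."""
    out = np.empty(len(points))
    for k, p in enumerate(points):
        a, b = poly[:-1], poly[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        j = int(np.argmin(d))
        out[k] = cum[j] + t[j] * (cum[j + 1] - cum[j])
    return out


def probe_pixels(
    frame: ProbeFrame, height_px: int, image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices covered by the probe rectangle, clipped to the image.

    The rectangle spans ``[-width/2, width/2)`` along the tangent (centred on
    the anchor) and ``[0, height)`` along the inward normal.  A pixel belongs
    to the probe when its centre (integer coordinate) satisfies both
    half-open interval tests, which makes the mask identical to a brute-force
    point-in-rotated-rectangle scan and gives exactly ``width * height``
    pixels for integer-anchored axis-aligned frames.

    Returns ``(rows, cols)`` index arrays.
    """
    if height_px < 1:
        raise ValueError("height_px must be >= 1")
    a = frame.anchor
    t = frame.tangent
    n = frame.inward_normal
    w = frame.width_px
    corners = np.array(
        [
            a - (w / 2) * t,
            a + (w / 2) * t,
            a + (w / 2) * t + height_px * n,
            a - (w / 2) * t + height_px * n,
        ]
    )
    r0 = max(0, int(np.floor(corners[:, 0].min())) - 1)
    r1 = min(image_shape[0] - 1, int(np.ceil(corners[:, 0].max())) + 1)
    c0 = max(0, int(np.floor(corners[:, 1].min())) - 1)
    c1 = min(image_shape[1] - 1, int(np.ceil(corners[:, 1].max())) + 1)
    if r1 < r0 or c1 < c0:
        raise ProbeOutsideImageError("probe rectangle lies entirely outside the image")
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    dr = rr - a[0]
    dc = cc - a[1]
    u = dr * t[0] + dc * t[1]
    v = dr * n[0] + dc * n[1]
    inside = (u >= -w / 2) & (u < w / 2) & (v >= 0) & (v < height_px)
    if not inside.any():
        raise ProbeOutsideImageError("probe rectangle lies entirely outside the image")
    return rr[inside], cc[inside]


def probe_band_index(
    frame: ProbeFrame, max_height_px: int, image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Probe pixels up to ``max_height_px`` plus each pixel's integer depth.

    The depth of a pixel is ``floor`` of its signed distance along the inward
    normal; the pixels with depth ``< N`` are exactly ``probe_pixels(frame,
    N, ...)``.  This supports incremental histograms over growing probe
    heights without re-rasterizing.
    """
    rows, cols = probe_pixels(frame, max_height_px, image_shape)
    v = (rows - frame.anchor[0]) * frame.inward_normal[0] + (
        cols - frame.anchor[1]
    ) * frame.inward_normal[1]
    depth = np.floor(v).astype(int)
    return rows, cols, depth
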