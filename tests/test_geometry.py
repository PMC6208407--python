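"""Probe geometry: contour resampling, frames, rectangle rasterization."""

import numpy as np
import pytest

from svzmap.errors import ContourTooShortError, ProbeOutsideImageError
from svzmap.geometry import (
    ProbeFrame,
    WallTrace,
    compute_frames,
    probe_pixels,
    resample_contour,
)


def brute_force_rectangle(frame, height, shape):
    """Oracle: test every pixel centre against the rotated rectangle."""
    hits = []
    a, t, n, w = frame.anchor, frame.tangent, frame.inward_normal, frame.width_px
    for r in range(shape[0]):
        for c in range(shape[1]):
            u = (r - a[0]) * t[0] + (c - a[1]) * t[1]
            v = (r - a[0]) * n[0] + (c - a[1]) * n[1]
            if -w / 2 <= u < w / 2 and 0 <= v < height:
                hits.append((r, c))
    return set(hits)


class TestResampleContour:
    def test_anchor_positions_on_straight_segment(self):
        poly = np.array([[0.0, 0.0], [0.0, 150.0]])
        anchors = resample_contour(poly, 50.0)
        assert anchors.shape == (3, 2)
        np.testing.assert_allclose(anchors[:, 1], [25.0, 75.0, 125.0])

    def test_floor_rule_drops_trailing_arc(self):
        poly = np.array([[0.0, 0.0], [0.0, 149.0]])
        assert len(resample_contour(poly, 50.0)) == 2

    def test_doubling_back_follows_cumulative_arc(self):
        # out 100 px and back 100 px: arc length 200, anchors at 25/75/125/175
        poly = np.array([[0.0, 0.0], [0.0, 100.0], [0.0, 0.0]])
        anchors = resample_contour(poly, 50.0)
        np.testing.assert_allclose(anchors[:, 1], [25.0, 75.0, 75.0, 25.0])

    def test_short_contour_raises(self):
        with pytest.raises(ContourTooShortError):
            resample_contour(np.array([[0.0, 0.0], [0.0, 30.0]]), 50.0)


class TestComputeFrames:
    def test_dorsal_wall_normals_point_dorsally(self):
        # dorsal wall traced lateral -> medial on the right hemisphere:
        # columns decreasing, tissue above (normal = -row direction)
        poly = np.array([[100.0, 300.0], [100.0, 100.0]])
        anchors = resample_contour(poly, 50.0)
        frames = compute_frames(anchors, poly, "dorsal", "right", 50.0)
        for f in frames:
            np.testing.assert_allclose(f.inward_normal, [-1.0, 0.0], atol=1e-12)
            assert abs(np.dot(f.tangent, f.inward_normal)) < 1e-12

    def test_reversed_trace_flips_normals(self):
        poly = np.array([[100.0, 100.0], [100.0, 300.0]])
        anchors = resample_contour(poly, 50.0)
        frames = compute_frames(anchors, poly, "dorsal", "right", 50.0)
        for f in frames:
            np.testing.assert_allclose(f.inward_normal, [1.0, 0.0], atol=1e-12)

    def test_flip_normal_override(self):
        poly = np.array([[100.0, 300.0], [100.0, 100.0]])
        anchors = resample_contour(poly, 50.0)
        frames = compute_frames(anchors, poly, "dorsal", "right", 50.0, flip_normal=True)
        np.testing.assert_allclose(frames[0].inward_normal, [1.0, 0.0], atol=1e-12)

    def test_semicircle_normals_are_radial(self):
        # lateral wall of the right hemisphere bulging rightward: normals
        # must match the analytic outward radii within 2 degrees
        radius = 200.0
        theta = np.linspace(-np.pi / 2, np.pi / 2, 400)
        centre = np.array([300.0, 300.0])
        poly = np.column_stack(
            [centre[0] + radius * np.sin(theta), centre[1] + radius * np.cos(theta)]
        )
        anchors = resample_contour(poly, 40.0)
        frames = compute_frames(anchors, poly, "lateral", "right", 40.0)
        for f in frames:
            radial = (f.anchor - centre) / np.linalg.norm(f.anchor - centre)
            angle = np.degrees(np.arccos(np.clip(np.dot(f.inward_normal, radial), -1, 1)))
            assert angle < 2.0

    def test_normals_invariant_to_collinear_subdivision(self):
        poly = np.array([[0.0, 0.0], [400.0, 0.0]])
        fine = np.column_stack([np.linspace(0, 400, 81), np.zeros(81)])
        a1 = resample_contour(poly, 60.0)
        f1 = compute_frames(a1, poly, "lateral", "right", 60.0)
        f2 = compute_frames(a1, fine, "lateral", "right", 60.0)
        for u, v in zip(f1, f2):
            np.testing.assert_allclose(u.inward_normal, v.inward_normal, atol=1e-9)


class TestProbePixels:
    def test_axis_aligned_count_is_exact(self):
        frame = ProbeFrame(
            index=0,
            anchor=np.array([50.0, 100.0]),
            tangent=np.array([0.0, 1.0]),
            inward_normal=np.array([1.0, 0.0]),
            width_px=50.0,
        )
        rows, cols = probe_pixels(frame, 100, (300, 300))
        assert len(rows) == 50 * 100

    @pytest.mark.parametrize("angle_deg", [45.0, 30.0, 73.0])
    def test_rotated_rectangle_matches_brute_force(self, angle_deg):
        a = np.radians(angle_deg)
        t = np.array([np.sin(a), np.cos(a)])
        n = np.array([-t[1], t[0]])
        frame = ProbeFrame(
            index=0, anchor=np.array([120.0, 80.0]), tangent=t, inward_normal=n, width_px=50.0
        )
        rows, cols = probe_pixels(frame, 100, (300, 300))
        got = set(zip(rows.tolist(), cols.tolist()))
        assert got == brute_force_rectangle(frame, 100, (300, 300))
        assert abs(len(got) - 50 * 100) / (50 * 100) < 0.03

    def test_clipping_at_image_edge(self):
        frame = ProbeFrame(
            index=0,
            anchor=np.array([2.0, 10.0]),
            tangent=np.array([0.0, 1.0]),
            inward_normal=np.array([-1.0, 0.0]),  # points off the top edge
            width_px=20.0,
        )
        rows, cols = probe_pixels(frame, 50, (100, 100))
        assert rows.min() >= 0 and cols.min() >= 0
        assert len(rows) < 20 * 50

    def test_fully_outside_raises(self):
        frame = ProbeFrame(
            index=0,
            anchor=np.array([-2.0, 10.0]),
            tangent=np.array([0.0, 1.0]),
            inward_normal=np.array([-1.0, 0.0]),
            width_px=20.0,
        )
        with pytest.raises(ProbeOutsideImageError):
            probe_pixels(frame, 50, (100, 100))

    def test_probe_count_per_wall_is_arc_length_floor(self, rng):
        pts = np.cumsum(rng.uniform(1, 5, size=(40, 2)), axis=0) + 100
        arc = np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))
        anchors = resample_contour(pts, 13.0)
        assert len(anchors) == int(arc // 13.0)


class TestWallTrace:
    def test_polyline_must_join_endpoints(self):
        with pytest.raises(ValueError, match="start point"):
            WallTrace(
                wall="lateral",
                hemisphere="right",
                start=np.array([0.0, 0.0]),
                end=np.array([10.0, 0.0]),
                polyline=np.array([[5.0, 0.0], [10.0, 0.0]]),
            )

    def test_unknown_wall_rejected(self):
        with pytest.raises(ValueError, match="wall"):
            WallTrace(
                wall="ventral",
                hemisphere="right",
                start=np.array([0.0, 0.0]),
                end=np.array([10.0, 0.0]),
                polyline=np.array([[0.0, 0.0], [10.0, 0.0]]),
            )
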