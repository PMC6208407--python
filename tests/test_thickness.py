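"""Jensen-Shannon divergence and plateau-exit height detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svzmap.errors import HistogramMismatchError, UnknownProbeError
from svzmap.geometry import compute_frames, resample_contour
from svzmap.phantom import generate_section, ground_truth, study_config
from svzmap.thickness import (
    LN2,
    GreyHistogram,
    HeightSearchConfig,
    ProbeHeightResult,
    apply_height_overrides,
    estimate_height,
    histogram,
    js_divergence,
    reference_histogram,
    section_bin_edges,
)


def js_oracle(p, r):
    """Independent scalar evaluation of the divergence formula."""
    import math

    total = 0.0
    for pi, ri in zip(p, r):
        mi = 0.5 * (pi + ri)
        if pi > 0:
            total += 0.5 * pi * (math.log(pi) - math.log(mi))
        if ri > 0:
            total += 0.5 * ri * (math.log(ri) - math.log(mi))
    return total


def _hist(probs, edges=None):
    probs = np.asarray(probs, dtype=float)
    if edges is None:
        edges = np.arange(len(probs) + 1, dtype=float)
    return GreyHistogram(bin_edges=np.asarray(edges, dtype=float), probabilities=probs)


class TestJsDivergence:
    def test_identical_histograms_give_zero(self):
        h = _hist([0.2, 0.3, 0.5])
        assert js_divergence(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_reach_ln2(self):
        assert js_divergence(_hist([1.0, 0.0]), _hist([0.0, 1.0])) == pytest.approx(LN2)

    def test_half_half_versus_point_mass(self):
        # independent hand evaluation of the formula gives 0.2157615...
        p, r = [0.5, 0.5], [1.0, 0.0]
        expected = js_oracle(p, r)
        assert js_divergence(_hist(p), _hist(r)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.21576, abs=5e-6)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(HistogramMismatchError):
            js_divergence(_hist([1.0, 0.0]), _hist([1.0, 0.0], edges=[0, 2, 4]))

    def test_unnormalized_rejected(self):
        with pytest.raises(HistogramMismatchError):
            _hist([0.5, 0.4])

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_bounds_and_oracle_agreement(self, seed):
        gen = np.random.default_rng(seed)
        k = int(gen.integers(2, 32))
        p = gen.dirichlet(np.ones(k) * gen.uniform(0.2, 3.0))
        r = gen.dirichlet(np.ones(k) * gen.uniform(0.2, 3.0))
        # exact zeroes exercise the 0 log 0 convention
        p[gen.random(k) < 0.3] = 0.0
        p = p / p.sum() if p.sum() else np.ones(k) / k
        edges = np.arange(k + 1, dtype=float)
        d1 = js_divergence(_hist(p, edges), _hist(r, edges))
        d2 = js_divergence(_hist(r, edges), _hist(p, edges))
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= LN2 + 1e-12
        assert d1 == pytest.approx(js_oracle(p, r), abs=1e-10)


class TestReferenceHistogram:
    def test_uniform_rectangle_occupies_single_bin(self):
        img = np.full((50, 50), 7.0)
        edges = np.linspace(0.0, 10.0, 11)
        h = reference_histogram(img, [[5, 5], [30, 30]], edges)
        assert h.probabilities.max() == pytest.approx(1.0)
        assert (h.probabilities > 0).sum() == 1

    def test_corner_order_irrelevant(self, rng):
        img = rng.uniform(0, 255, (80, 80))
        edges = section_bin_edges(img, 64)
        h1 = reference_histogram(img, [[10, 10], [60, 70]], edges)
        h2 = reference_histogram(img, [[60, 70], [10, 10]], edges)
        np.testing.assert_array_equal(h1.probabilities, h2.probabilities)

    def test_tiny_rectangle_warns_but_computes(self):
        img = np.ones((20, 20))
        edges = np.linspace(0, 2, 5)
        with pytest.warns(UserWarning, match="px"):
            h = reference_histogram(img, [[0, 0], [4, 4]], edges)
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_two_parenchymal_rectangles_nearly_identical(self, small_section):
        # same tissue elsewhere in the section: divergence stays small
        record, doc = small_section
        dapi = record.channels["dapi"].pixels
        edges = section_bin_edges(dapi, 64)
        h1 = reference_histogram(dapi, [[440, 420], [500, 500]], edges)
        h2 = reference_histogram(dapi, [[20, 20], [80, 100]], edges)
        assert js_divergence(h1, h2) < 0.05


class TestEstimateHeight:
    def test_recovers_band_thickness_on_phantom(self, small_spec, small_section):
        # oracle: the probe's true mean band depth, read off the phantom's
        # own band mask (band pixel count / probe width)
        from svzmap.geometry import probe_band_index
        from svzmap.phantom import _band_and_lumen_masks

        record, doc = small_section
        band, _ = _band_and_lumen_masks(small_spec, 2)
        config = study_config(small_spec)
        dapi = record.channels["dapi"].pixels
        edges = section_bin_edges(dapi, config.height_search.n_bins)
        ref = reference_histogram(dapi, doc.reference_points, edges)
        for trace in doc.walls:
            anchors = resample_contour(trace.polyline, config.probe_width_px)
            frames = compute_frames(
                anchors, trace.polyline, trace.wall, trace.hemisphere, config.probe_width_px
            )
            for f in frames:
                res = estimate_height(dapi, f, ref, config.height_search)
                rows, cols, _ = probe_band_index(f, config.height_search.n_max, dapi.shape)
                true_px = band[rows, cols].sum() / config.probe_width_px
                assert abs(res.n_opt - true_px) / true_px < 0.15

    def test_flat_profile_flags_low_confidence(self):
        # constant image: probe and reference share one histogram bin
        img = np.full((400, 400), 50.0)
        cfg = HeightSearchConfig(n_max=120)
        edges = section_bin_edges(img, cfg.n_bins)
        ref = reference_histogram(img, [[300, 300], [380, 380]], edges)
        poly = np.array([[50.0, 100.0], [250.0, 100.0]])
        frames = compute_frames(
            resample_contour(poly, 60.0), poly, "lateral", "right", 60.0
        )
        res = estimate_height(img, frames[0], ref, cfg)
        assert res.low_confidence
        assert res.n_opt == cfg.n0

    def test_thicker_band_gives_larger_height(self, small_spec):
        # paired phantoms: doubling the band thickness raises N_opt
        from dataclasses import replace

        thin = replace(small_spec, base_thickness_px=45.0, thickness_amplitude_px=0.0,
                       hotspot_amplitude_px=0.0, seed=7)
        thick = replace(thin, base_thickness_px=90.0)
        heights = {}
        for name, spec in [("thin", thin), ("thick", thick)]:
            record, doc = generate_section(spec, 2)
            config = study_config(spec)
            dapi = record.channels["dapi"].pixels
            edges = section_bin_edges(dapi, config.height_search.n_bins)
            ref = reference_histogram(dapi, doc.reference_points, edges)
            trace = next(t for t in doc.walls if t.wall == "lateral")
            frames = compute_frames(
                resample_contour(trace.polyline, config.probe_width_px),
                trace.polyline, trace.wall, trace.hemisphere, config.probe_width_px,
            )
            heights[name] = estimate_height(dapi, frames[0], ref, config.height_search).n_opt
        assert heights["thick"] > heights["thin"]

    def test_reference_placement_robustness(self, small_spec, small_section):
        # several parenchymal reference placements: stdev(N_opt) <= 5 px
        record, doc = small_section
        config = study_config(small_spec)
        dapi = record.channels["dapi"].pixels
        edges = section_bin_edges(dapi, config.height_search.n_bins)
        trace = next(t for t in doc.walls if t.wall == "lateral")
        frames = compute_frames(
            resample_contour(trace.polyline, config.probe_width_px),
            trace.polyline, trace.wall, trace.hemisphere, config.probe_width_px,
        )
        blocks = [
            [[460, 450], [500, 500]],
            [[430, 400], [480, 470]],
            [[20, 20], [70, 90]],
            [[20, 420], [80, 500]],
            [[450, 20], [500, 100]],
        ]
        n_opts = [
            estimate_height(
                dapi, frames[0], reference_histogram(dapi, b, edges), config.height_search
            ).n_opt
            for b in blocks
        ]
        assert np.std(n_opts) <= 5.0

    def test_thickness_um_conversion_exact(self):
        res = ProbeHeightResult(n_opt=100, thickness_um=64.0)
        assert res.thickness_um == res.n_opt * 0.64


class TestOverrides:
    def _results(self):
        return {
            (0, "lateral", i): ProbeHeightResult(n_opt=80, thickness_um=80.0) for i in range(4)
        }

    def test_only_targeted_probe_changes(self):
        out = apply_height_overrides(self._results(), {(0, "lateral", 3): 120})
        assert out[(0, "lateral", 3)].n_opt == 120
        assert out[(0, "lateral", 3)].manual_override
        for i in range(3):
            assert out[(0, "lateral", i)].n_opt == 80
            assert not out[(0, "lateral", i)].manual_override

    def test_empty_override_set_is_identity(self):
        results = self._results()
        assert apply_height_overrides(results, {}) == results

    def test_unknown_probe_rejected(self):
        with pytest.raises(UnknownProbeError):
            apply_height_overrides(self._results(), {(1, "dorsal", 0): 50})

    def test_sub_pixel_override_rejected(self):
        with pytest.raises(ValueError):
            apply_height_overrides(self._results(), {(0, "lateral", 0): 0})
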