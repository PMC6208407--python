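"""Automatic probe-height (SVZ thickness) detection.

The SVZ is a band of high nuclear density lining the ventricle; beyond its
basal border the tissue looks like ordinary parenchyma.  For every probe the
detector grows an apical slab of candidate height N and compares the
grey-value histogram of the nuclear counterstain inside the slab against the
histogram of a user-placed parenchymal reference rectangle, using the
Jensen-Shannon divergence.  While the slab sits inside the dense band the
two distributions differ and the divergence is high; once the slab grows
past the basal border the mixed histogram converges toward the reference and
the divergence drops and keeps dropping.  The detected height N_opt is the
exit point of the high-divergence plateau.

Because a probe only a few pixels tall holds too few pixels for a stable
histogram, the search starts at N_0 = 30 px rather than at the apical face,
where the divergence shows spurious variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import HistogramMismatchError, TraceOutOfBoundsError, UnknownProbeError
from .geometry import ProbeFrame, probe_band_index

LN2 = float(np.log(2.0))


@dataclass
class GreyHistogram:
    """Normalized grey-value histogram over shared section-wide bin edges."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.min(initial=0.0) < 0:
            raise HistogramMismatchError("histogram probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise HistogramMismatchError("histogram probabilities must sum to 1")


@dataclass
class HeightSearchConfig:
    """Tunables of the plateau-exit height search.

    n0/n_max bound the search in pixels; tau is the plateau threshold as a
    fraction of the peak smoothed divergence; drop_window is how many
    consecutive non-increasing smoothed samples must follow the plateau exit
    before it is accepted.
    """

    n0: int = 30
    n_max: int = 250
    n_bins: int = 64
    smooth_window: int = 5
    plateau_fraction: float = 0.9
    drop_window: int = 15

    def __post_init__(self) -> None:
        if not 1 <= self.n0 < self.n_max:
            raise ValueError("need 1 <= n0 < n_max")
        if not 0 < self.plateau_fraction <= 1:
            raise ValueError("plateau_fraction must be in (0, 1]")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class JSProfile:
    heights: np.ndarray
    js_values: np.ndarray
    smoothed_js: np.ndarray


@dataclass
class ProbeHeightResult:
    n_opt: int
    thickness_um: float
    manual_override: bool = False
    low_confidence: bool = False
    js_profile: JSProfile | None = field(default=None, repr=False)


def section_bin_edges(pixels: np.ndarray, n_bins: int = 64) -> np.ndarray:
    """Equal-width bin edges spanning the section-wide grey-value range.

    Probe and reference histograms must share edges for the divergence to be
    meaningful, so edges are computed once per section from the counterstain
    channel.
    """
    lo = float(np.min(pixels))
    hi = float(np.max(pixels))
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_bins + 1)


def histogram(values: np.ndarray, bin_edges: np.ndarray) -> GreyHistogram:
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("cannot build a histogram from zero pixels")
    counts, _ = np.histogram(values, bins=bin_edges)
    return GreyHistogram(bin_edges=bin_edges, probabilities=counts / counts.sum())


def js_divergence(p: GreyHistogram, r: GreyHistogram) -> float:
    """Jensen-Shannon divergence (natural log) between two histograms.

    JS(P, R) = 1/2 sum_i P_i [log P_i - log M_i] + 1/2 sum_i R_i [log R_i - log M_i]
    with M = (P + R) / 2 and the 0 log 0 = 0 convention.  Symmetric,
    bounded by [0, ln 2], and 0 iff P = R.
    """
    if p.bin_edges.shape != r.bin_edges.shape or not np.allclose(p.bin_edges, r.bin_edges):
        raise HistogramMismatchError("histograms do not share bin edges")
    return float(_js_rows(p.probabilities[None, :], r.probabilities)[0])


def _js_rows(p_rows: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-wise JS divergence of a stack of distributions against one."""
    m = 0.5 * (p_rows + r)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_p = np.where(p_rows > 0, p_rows * (np.log(p_rows) - np.log(m)), 0.0)
        term_r = np.where(r > 0, r * (np.log(r) - np.log(m)), 0.0)
    return 0.5 * term_p.sum(axis=1) + 0.5 * term_r.sum(axis=1)


def reference_histogram(
    dapi: np.ndarray, reference_points: np.ndarray, bin_edges: np.ndarray
) -> GreyHistogram:
    """Histogram of the axis-aligned rectangle spanned by two corner points.

    The rectangle is the parenchymal "reference region"; the two points may
    be given in either order.  A rectangle under 100 px^2 still yields a
    histogram but triggers a warning because it is statistically fragile.
    """
    pts = np.asarray(reference_points, dtype=float)
    if pts.shape != (2, 2):
        raise ValueError("reference_points must be two (row, col) points")
    r0, r1 = sorted((int(round(pts[0, 0])), int(round(pts[1, 0]))))
    c0, c1 = sorted((int(round(pts[0, 1])), int(round(pts[1, 1]))))
    if r0 < 0 or c0 < 0 or r1 >= dapi.shape[0] or c1 >= dapi.shape[1]:
        raise TraceOutOfBoundsError("reference points lie outside the image")
    area = (r1 - r0 + 1) * (c1 - c0 + 1)
    if area < 100:
        warnings.warn(
            f"reference rectangle has only {area} px; histogram may be unstable",
            stacklevel=2,
        )
    return histogram(dapi[r0 : r1 + 1, c0 : c1 + 1], bin_edges)


def _truncated_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window is truncated at the array edges."""
    if window <= 1:
        return x.astype(float)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    n = len(x)
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (csum[hi] - csum[lo]) / (hi - lo)


def js_profile(
    dapi: np.ndarray,
    frame: ProbeFrame,
    ref: GreyHistogram,
    config: HeightSearchConfig,
) -> JSProfile:
    """Divergence between the growing probe slab and the reference, for every
    candidate height in [n0, n_max].

    Implemented incrementally: each probe pixel is binned once by grey value
    and integer depth along the inward normal; cumulative sums over depth
    then give the histogram of every slab at once.
    """
    n_max = config.n_max
    rows, cols, depth = probe_band_index(frame, n_max, dapi.shape)
    values = dapi[rows, cols].astype(float)
    edges = ref.bin_edges
    bins = np.clip(np.digitize(values, edges) - 1, 0, len(edges) - 2)
    counts = np.zeros((n_max, len(edges) - 1))
    np.add.at(counts, (depth, bins), 1.0)
    cum = np.cumsum(counts, axis=0)  # cum[h] = histogram of slab [0, h+1)
    heights = np.arange(config.n0, n_max + 1)
    slab = cum[heights - 1]
    totals = slab.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    p_rows = slab / totals
    js = _js_rows(p_rows, ref.probabilities)
    smoothed = _truncated_moving_average(js, config.smooth_window)
    return JSProfile(heights=heights, js_values=js, smoothed_js=smoothed)


def estimate_height(
    dapi: np.ndarray,
    frame: ProbeFrame,
    ref: GreyHistogram,
    config: HeightSearchConfig,
    microns_per_pixel: float = 1.0,
) -> ProbeHeightResult:
    """Detect the probe's basal height N_opt from the divergence profile.

    While the growing slab stays inside the dense band the smoothed
    divergence sits on a plateau near its peak; past the basal border it
    decays toward zero and never recovers.  N_opt is therefore the last
    height whose smoothed divergence is still on the plateau (>= tau *
    peak): every later sample sits below the threshold, which is the point
    where the divergence "consistently drops".  Judging the drop against
    the plateau threshold rather than sample-to-sample keeps brief noise
    dips from cutting the estimate short.  The drop counts as confirmed
    when at least ``drop_window`` below-threshold samples follow; a plateau
    that runs into N_max cannot be confirmed and is flagged low-confidence
    (the band may be thicker than the search range).  A flat profile (probe
    indistinguishable from the reference everywhere) returns N_0 flagged
    low-confidence.
    """
    profile = js_profile(dapi, frame, ref, config)
    s = profile.smoothed_js
    peak = float(s.max())
    if peak < 1e-6:
        return ProbeHeightResult(
            n_opt=config.n0,
            thickness_um=config.n0 * microns_per_pixel,
            low_confidence=True,
            js_profile=profile,
        )
    # robust plateau level: median of the top-decile smoothed samples, so a
    # single spurious spike (small slabs are noisy) cannot inflate it
    top = np.sort(s)[-max(3, len(s) // 10) :]
    plateau = float(np.median(top))
    thresh = config.plateau_fraction * plateau
    # exit = last sample still on the plateau; everything after it stays
    # below the threshold, so mid-plateau dips shorter than the remaining
    # profile never cut the estimate short
    i_last = int(np.flatnonzero(s >= thresh)[-1])
    # the drop is confirmed when at least drop_window below-threshold
    # samples follow; a plateau running into n_max cannot be confirmed
    drop_confirmed = (len(s) - 1 - i_last) >= config.drop_window
    n_opt = int(profile.heights[i_last])
    return ProbeHeightResult(
        n_opt=n_opt,
        thickness_um=n_opt * microns_per_pixel,
        low_confidence=not drop_confirmed,
        js_profile=profile,
    )


def apply_height_overrides(
    results: dict[tuple[int, str, int], ProbeHeightResult],
    overrides: dict[tuple[int, str, int], int],
    microns_per_pixel: float = 1.0,
) -> dict[tuple[int, str, int], ProbeHeightResult]:
    """Replace detected heights with manual corrections.

    ``results`` and ``overrides`` are keyed by (section_index, wall,
    probe_index).  Overridden entries keep their divergence profile for
    audit but are flagged ``manual_override``.
    """
    out = dict(results)
    for key, height in overrides.items():
        if key not in out:
            raise UnknownProbeError(f"override references unknown probe {key}")
        if height < 1:
            raise ValueError(f"override height must be >= 1 px, got {height}")
        prev = out[key]
        out[key] = replace(
            prev,
            n_opt=int(height),
            thickness_um=int(height) * microns_per_pixel,
            manual_override=True,
            low_confidence=False,
        )
    return out
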