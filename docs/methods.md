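# Methods

This note documents the models, parameter choices and numerical decisions
behind `svzmap`, and what the synthetic phantom does and does not emulate.

## Coordinate and tracing conventions

Pixel coordinates are 0-based `(row, col)`, rows increasing downward
(ventrally for a coronal section displayed dorsal side up), columns to the
right; all geometry is computed in pixels and converted to micrometres only
for reporting. Lateral and medial walls are traced dorsal → ventral, the
dorsal wall lateral → medial, on either hemisphere. These conventions fix
the side of the contour on which tissue lies, so the inward (apical →
basal) probe normal is chosen from a `(wall, hemisphere)` lookup; a
`flip_normal` flag per trace covers unusual anatomy. Probe anchors sit at
probe *centres* (arc positions w/2, 3w/2, …), giving ⌊L/w⌋ probes for arc
length L — symmetric coverage with the trailing remainder dropped. Probes
are rigid rectangles; on concave contours neighbouring probes may overlap
and are measured independently, since any de-overlapping scheme would be
arbitrary.

Probe rectangles are rasterized by a half-open pixel-centre test
(tangential offset in [−w/2, w/2), normal offset in [0, N)), which makes
the mask identical to a brute-force point-in-rotated-rectangle scan and
gives exactly w·N pixels for integer-anchored axis-aligned frames.

## Thickness detection

For each probe, the grey-value histogram of the counterstain inside the
growing apical slab [0, N] is compared with a parenchymal reference
histogram by the Jensen–Shannon divergence (natural logarithm, 0·log 0 = 0;
maximum ln 2). The slab is grown rather than slid because its histogram
then converges monotonically toward the reference once the band has been
crossed, giving a one-way plateau-then-decay profile.

Numerical choices:

* **Bins.** 64 equal-width bins spanning the counterstain's section-wide
  [min, max]; probe and reference share edges (required for the
  divergence to be meaningful). 64 balances resolution against
  small-sample noise at the smallest slab (~w·N₀ pixels).
* **Search range.** N₀ = 30 px to N_max = 250 px. Slabs shorter than ~30 px
  hold too few pixels for a stable histogram and show spurious divergence
  fluctuations; 250 px comfortably exceeds any plausible band thickness at
  the default calibration (0.64 µm/px) and is configurable.
* **Smoothing.** Centred moving average, window 5, truncated at the edges —
  enough to damp sample jitter without displacing the plateau edge.
* **Plateau exit.** The plateau level is the median of the top decile of
  smoothed samples (robust to a single spurious spike from the noisy small
  slabs); N_opt is the *last* height whose smoothed divergence is ≥ τ times
  that level (τ = 0.9). Judging the drop against the plateau threshold
  rather than sample-to-sample monotonicity matters: on any sampled
  profile, literal monotone runs essentially never occur, while the
  "last sample on the plateau" rule tolerates brief dips and cannot be
  fooled by re-rises below the threshold. A drop is *confirmed* when at
  least `drop_window` (15) below-threshold samples follow; a plateau that
  runs into N_max cannot be confirmed and is flagged low-confidence, as is
  a flat profile (max < 10⁻⁶, e.g. a probe lying in reference-like
  tissue, which returns N₀).
* **Ties.** All comparisons resolve toward the smaller height.

The threshold-exit estimator lags the true basal border slightly (the
divergence must fall 10 % below the plateau before the exit registers);
on phantoms this bias is below ~1 px and is dwarfed by tissue-level
variability. Detected heights convert to µm exactly as N_opt times the
pixel size. Manual overrides replace N_opt, set a flag, and retain the
divergence profile for audit.

## Optical density and heatmaps

OD is the arithmetic *mean* grey value in the probe (not sum or median):
with acquisition settings held constant it is comparable across probes of
different heights. Wall matrices are normalized per quantity by the joint
non-background maximum across the three walls, so a figure has one colour
scale; per-wall normalization is available behind a switch
(`normalize_across_walls=False`) since either convention is defensible.
Background cells are NaN throughout, never enter normalization, and render
in a colour outside the colormap (white). Raw values are always exported
next to every heatmap — relative colour maps show spatial pattern, not
amplitude.

## Series interpolation

For a 1-in-N series, base values are vertical 3-neighbour averages of each
measured column ((X′ + X″ + X‴)/3 inside the wall, (X′ or X‴ + X″)/2 at the
first/last probe); the n-th missing column between measured X and Y is the
convex combination (1 − n/N)·vₓ + (n/N)·v_y row by row. Three edge policies
the formula itself does not cover:

* rows present in only one flanking section copy that single base value
  (keeps maps hole-free wherever there is evidence, in the spirit of the
  single-neighbour border rule);
* missing columns before the first / after the last measured section copy
  the nearest measured column's base values;
* the intrasection refinement pass is one further vertical 3-neighbour
  average applied to interpolated columns only, computed from the
  pre-pass values; measured columns are returned bit-identical. This pass
  is a minimal reconstruction of a refinement that is usually shown only
  graphically, and is flagged as such to users.

A provenance grid (measured / interpolated / absent per cell) is exported
beside every interpolated table.

## Cohort averaging

Probe counts differ between animals, so per (wall, section) each animal's
column of Y values is rebinned to the common count X = round(mean counts)
(half away from zero — the symmetric choice; the printed example {1, 4, 5}
→ 3 does not discriminate floor from nearest): every value becomes X
subvalues of v/X, the Y·X sequence is cut into X groups of Y, and each
group's mean times X is a work value. This is area-weighted rebinning and
conserves the column mean to floating-point precision. Averaging operates
on raw values and normalizes once at the end; averaging normalized maps
would weight each animal by its own maximum.

## The phantom

`PhantomSpec` renders serial coronal sections with a curved ventricular
lumen (medial/lateral walls as gently bulging verticals, an arched dorsal
wall), a dense band hugging each wall's apical face, sparse parenchyma, a
near-empty lumen, and marker channels expressed inside the band. Nuclei
are fixed-radius discs (3 px) at Poisson-random centres — band 0.04,
parenchyma 0.006 centres/px² — over backgrounds of 15 (parenchyma) and 40
(band: crowded somata and out-of-focus light lift the counterstain floor
in real germinal zones) with nuclear level 180, Gaussian read noise
(σ = 6), and a smooth ±3 % multiplicative illumination field per section.
The band is drawn to the prescribed thickness along the local contour
normal (a cos-slope correction on the horizontal offset) and continues
past the traced ROI ends, as tissue does beyond the user's start/end
points. Reference points are placed in far parenchyma, at least twice the
maximal band thickness from any band pixel.

The default series is 43 sections of 1024 × 1024 px at 0.64 µm/px with
50 µm sections and 50 µm probes. The cohort-level thickness profile is a
smooth sinusoid (70 ± 18 px) over arc position and series position, plus a
Gaussian "hotspot" on the lateral wall (amplitude 40 px, σ = 0.13 in both
normalized coordinates, centred at arc fraction 0.35, series fraction 0.4)
— the analogue of the neuroblast accumulation where the migratory stream
leaves the ventricle. Each seed additionally carries a smooth
animal-specific profile deviation (amplitude 4 px, clipped at 2σ; low
frequencies only, so subsampled series still resolve it): replicate
"animals" share the cohort profile but differ individually, which is what
cohort averaging is meant to even out. Marker 1 ramps dorso-ventrally
inside the band; marker 2 decreases linearly with local thickness
(thick ⇔ sparse, mimicking the caudal thickening with falling cell
density). Ground truth (thickness in µm, expression in grey levels) is
evaluated analytically at the same probe anchors the pipeline uses, so
comparisons are free of regridding artefacts.

What the phantom does *not* emulate: real nuclear morphology and intensity
variation, anisotropic tissue texture, staining bleed-through between
channels, section-to-section registration errors, tissue tears, and true
anatomy (no migratory stream or olfactory bulb). Passing the phantom
suites therefore demonstrates the correctness and calibration of the
*pipeline* under controlled contrast, not performance on any particular
real dataset — on real tissue the manual height-override path exists
precisely because automatic detection can fail locally.

Problem sizes in the test suite follow the default study (43 sections at
1024 px for the end-to-end suites; 6 sections at 512 px for unit-level
checks), chosen to exercise full-scale behaviour while keeping the suite
quick to run.

## Known limitations

* The plateau-exit rule assumes the band is denser (histogram-distinct)
  from parenchyma throughout its depth; a band with an internal cavity
  or gradual density taper will read short.
* Probes are straight; on strongly curved contours the rectangle deviates
  from the true normal corridor at depth (the phantom's curvature keeps
  this below ~2 %).
* Intrasection interpolation is a declared approximation (see above).
* The CLI's file layout (`section_###.tif` / `trace_###.json`) is fixed;
  the library API accepts any iterable of section/trace pairs.
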