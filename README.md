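# svzmap

Thickness and optical-density flat-maps of the subventricular zone (SVZ)
from traced serial sections.

The postnatal SVZ is a thin, tortuous germinal layer lining the lateral
ventricles, organised into lateral, dorsal and medial walls of distinct
developmental origin. Its thickness, cell density and marker expression vary
strongly along both the dorso-ventral and rostro-caudal axes, so
histological quantification needs a spatial map rather than a handful of
counting frames. `svzmap` turns a series of counterstained, immunostained
coronal sections plus user-supplied traces of each wall's ventricular
(apical) face into 2D "unfolded" heatmaps: one column per section
(rostral to caudal), one row per sampling probe along the traced wall
(trace start at the top), with the three walls stacked into a single panel
as if the ventricle were cut open at its ventral tip.

## Method

* **Probe sampling.** Each traced wall contour is resampled into rectangular
  probes of fixed width *w* (default 50 µm) placed perpendicular to the
  contour, apical edge on the trace.
* **Automatic thickness detection.** The SVZ is denser in nuclei than the
  adjacent parenchyma. For candidate heights *N* ∈ [*N*₀, *N*ₘₐₓ] (defaults
  30–250 px) the grey-value histogram *P* of the counterstain inside the
  growing probe slab is compared with the histogram *R* of a user-defined
  parenchymal reference region via the Jensen–Shannon divergence

  JS(P, R) = ½ Σᵢ Pᵢ [log Pᵢ − log Mᵢ] + ½ Σᵢ Rᵢ [log Rᵢ − log Mᵢ],
  M = (P + R)/2,

  which is symmetric and bounded by [0, ln 2]. While the slab lies inside
  the dense band JS stays on a high plateau; past the basal border the slab
  histogram converges to the reference and JS drops for good. The detected
  height *N*ₒₚₜ (the local SVZ thickness) is the plateau-exit point of the
  smoothed profile. Heights can be overridden manually per probe.
* **Optical density.** Each marker's OD is the mean grey value inside the
  probe truncated at *N*ₒₚₜ; acquisition settings are assumed constant
  across the series.
* **Heatmaps.** Per quantity (thickness + one OD per channel) the per-probe
  values form a probes × sections matrix per wall; matrices are normalized
  jointly to [0, 1] (one colour scale per quantity across all three walls)
  and rendered through a colormap (default "jet"), background cells in a
  colour outside the map. Raw values are always exported alongside.
* **Subsampled series.** Analysing every *N*-th section (stereology-style),
  the missing columns are reconstructed by intersection interpolation,
  vₙ = (1 − n/N)·vₓ + (n/N)·v_y for the *n*-th missing column between
  measured sections X and Y (base values vₓ, v_y are vertical 3-neighbour
  averages), followed by an optional intrasection smoothing pass.
* **Cohort averaging.** Per wall and section, animals with different probe
  counts are rebinned to a common count X (mean count, rounded) through a
  mean-conserving subvalue scheme, then averaged elementwise on raw values
  and normalized once.

A synthetic phantom generator (`svzmap.phantom`) produces full studies —
curved ventricle walls, a nuclei-speckled dense band of known thickness
with a localized "hotspot", marker gradients, illumination inhomogeneity,
per-animal profile variation — together with matching trace files and
analytic ground-truth maps, so the whole pipeline is testable end to end
without any microscope.

## Worked example

```python
import numpy as np
from svzmap import analyze_sections
from svzmap.phantom import PhantomSpec, iter_sections, ground_truth, study_config

spec = PhantomSpec(image_shape=(512, 512), n_sections=6, seed=0)
config = study_config(spec)
result = analyze_sections(iter_sections(spec), config)

truth = ground_truth(spec, config.probe_width_px)
print(np.round(result.matrices["thickness"]["lateral"].values, 1))
print(np.round(truth.thickness["lateral"], 1))
```

prints the measured lateral-wall thickness map (µm; 2 probe rows × 6
section columns) next to the phantom's analytic truth:

```
[[33.3 42.2 49.9 46.1 45.4 55.7]
 [49.9 51.8 57.  59.5 57.  53.8]]
[[32.6 47.  61.8 49.9 49.8 58.8]
 [49.7 49.1 54.1 61.8 60.2 53.1]]
```

Each entry is one probe's detected height times the pixel size; the map
tracks the true thickness profile to a few micrometres, and
`result.heatmaps["thickness"].max_raw_value` (59.5 µm here) is the value
that maps to 1.0 on the colour scale.

The same workflow from the shell:

```bash
svzmap simulate --out study/ --seed 0 --n-sections 43
svzmap analyze --config study/study.yaml --images study/ --traces study/ --out out/
svzmap average --inputs out_a/ --inputs out_b/ --inputs out_c/ \
    --quantity thickness --out averaged/
```

`analyze` writes per-wall raw and interpolated value tables (CSV), a
provenance grid marking measured vs interpolated cells, the stacked heatmap
PNGs (plus a UV-ready panel for texturing 3D ventricle meshes), and a JSON
log with every probe's *N*ₒₚₜ.

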