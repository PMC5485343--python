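# Methods

This note records the models, defaults and numerical choices behind
`corneaheal`, and what the synthetic-data experiments do and do not
demonstrate.

## Geometry

The anterior cornea is a spherical cap of radius *R*, apex at lateral offset
(*x*₀, *y*₀) and depth *z*₀ below the top of the scan volume:
*z*(*x*, *y*) = *z*₀ + *R* − √(*R*² − ρ²), ρ² = (*x*−*x*₀)² + (*y*−*y*₀)²,
defined for ρ < *R*. Defaults: *R* = 7.5 mm (typical rabbit anterior cornea —
the value is configurable and every curvature-dependent output records the
radius actually used), *z*₀ = 0.1 mm, epithelium 40 µm. Axial distances are
assumed already geometrically corrected (`refractive_scaling = 1`); refraction
of the beam at the anterior surface is not modelled.

The 6-mm trephine diameter is interpreted as the planar chord diameter of the
wound footprint: a rigid trephine contacts the spherical cornea on a planar
circle. The true planar area is then π(*d*/2)² and the true surface area the
spherical-cap area 2π*R*²(1 − √(1 − (*d*/2*R*)²)). An optional irregular
boundary (low-order harmonic perturbation) emulates manual debridement but is
not calibrated to any measured wound shape.

A geometric consequence worth knowing: with *R* = 7.5 mm and the standard
1-mm scan depth, the anterior surface leaves the volume at ρ ≈ 3.6 mm, so only
the central ~70% of the 7.5 × 7.5 mm field contains the surface. A centred
6-mm wound is fully measurable; wounds decentred by more than ~0.5 mm are
physically clipped regardless of the pipeline (translation robustness is
therefore demonstrated on a deeper synthetic scan).

## Synthetic OCT volumes

The default scan is 7.5 × 7.5 × 1 mm sampled at 1024 × 512 × 1024 voxels;
pixel centres sit at (i + 0.5)·pitch with the en face origin at the volume
corner and depth increasing away from the instrument. The phantom renders,
per A-scan: background (0.03), a bright specular interface at the surface
(1.0, width max(4 µm, 1.5 Δz) — resolution-limited, as a real point-spread
floor would be), then 40 µm of low-scattering epithelium (0.12) outside the
wound, and stroma (0.45) below; inside the wound footprint stromal
reflectivity begins directly at the surface (the wound floor carries no
40-µm step, which keeps the analytic sphere the ground truth for surface
detection everywhere; stromal damage is modelled separately as an explicit
crater of configurable depth and radius). Speckle is multiplicative,
unit-mean, exponential-law with configurable contrast (default 0.35).
Deterministic for a fixed seed; generation is chunked along x so full-size
volumes stay within ordinary memory.

The test suite and the reproduction script run the imaging chain at reduced
resolution (96³–256³ over the same physical extent, chosen so the whole suite
completes in well under a minute of imaging time); full-resolution generation
is supported but not exercised by the tests.

## Synthetic photographs

Cobalt-blue photographs render a dark bluish cornea, a green fluorescein pool
of projected diameter *d*·√(bias) with a soft 1.5-px edge, Gaussian pixel
noise (σ = 4 DN), and a ruler band at the image bottom with dark ticks every
`ruler_tick_mm`. The scale default is 0.043 mm/px. Ground truth (scale, wound
geometry, biased area) is stored in metadata and in the PNG's JSON sidecar.

## Healing and measurement-noise model

Per animal, linear radial closure *r*(*t*) = max(0, *r*₀ − *v t*) with
*v* ~ Normal(μ, σ) truncated at 0; defaults μ = 35 µm/h (placebo) vs 55 µm/h
(treated), σ = 5 µm/h between animals, chosen so the treated arm approaches
closure by 72 h while the placebo arm does not. Series-level measurement
noise is multiplicative lognormal with the σ parametrized so the sample CV
equals the nominal value (σ² = log(1 + cv²)): OCT cv 0.03, fluorescein
cv 0.05 with a systematic ×1.25 overestimation. A closed wound (truth 0)
reads 0 under both methods. The fluorescein bias magnitude is anchored on the
ratio of baseline group means the two methods report on the same wounds
(≈ 31/25); its direction — fluorescein larger — is the empirically observed
one.

What the generator does **not** emulate: tear-film and motion artifacts,
speckle correlation, illumination gradients in photographs, perspective/
keystone distortion, irregular healing fronts, or any biology beyond the
linear closure rate. Passing tests therefore demonstrate that the measurement
chain is correct and well-calibrated *for data of this structure*, not that
it is robust to every artifact of real acquisitions.

## OCT pipeline choices

- **Surface detection**: per A-scan, first axial sample exceeding the global
  intensity quantile (default 0.70 — roughly two thirds of the volume is
  background or sub-threshold, so this lands between the background and
  tissue modes of both noise-free and speckled volumes). Axial Gaussian
  smoothing is available but off by default: the first-crossing rule is
  already robust to multiplicative speckle (background essentially never
  crosses a tissue-level threshold), while smoothing dilutes the thin
  specular interface and can push it below the threshold. Columns without a
  crossing are invalid; a robust quadric fit (3-MAD outlier rejection,
  3 iterations) fills them and supplies a fitted radius/apex. More than 50%
  invalid columns raises `NoSurfaceFound`.
- **En face projection**: mean intensity over an index-based window below the
  detected surface voxel, default 10–40 µm, clamped to start at least
  2 voxels down so the specular interface never leaks into the band at coarse
  axial sampling (interface inclusion is a rounding-phase artifact that
  otherwise creates spurious bimodality). The window deliberately ends at the
  epithelial base: reaching deeper dilutes the epithelium/stroma contrast
  with stroma on both sides of the wound border.
- **Segmentation**: 3×3 median filter → Otsu threshold within the
  valid-surface region → opening (disc radius 3 px) → largest 4-connected
  component → hole fill. Guards declare the wound closed: effectively uniform
  image, foreground/background contrast below 1.2, or area below
  `min_area_mm2` (default 0.2 mm² — the "closed" call is a property of the
  pipeline, not of raw pixels).
- **Curvature correction**: corrected area = Σ_fg Δx Δy / √(1 − ρ²/R²). By
  default ρ and R come from the configured cornea model; `fit_radius=True`
  instead uses the sphere least-squares-fitted to the detected surface (the
  quadric's x²+y² curvature), and both radii are always reported. Projected
  (planar) area is the primary endpoint and the corrected area is reported
  alongside, since either convention is defensible for an instrument that
  "corrects curvature distortion" without stating a formula.

Accuracy at reduced resolution, measured by the tests: the 6-mm wound's
equivalent planar diameter is recovered within 0.01 mm (noise-free) and
within ~0.05 mm (speckled) at 96²–256² lateral sampling; areas within a few
percent. Near closure the relative error necessarily blows up — a 0.5 mm²
wound spans ~6 pixels at 128² sampling — which is why the fast-vs-images
consistency check compares areas only above 0.5 mm² and requires both modes
to agree on "effectively closed" below it.

## Photo pipeline choices

Fluorescein score F = G − (R+B)/2 on [0, 1] channels; Otsu within the ROI
(ruler band excluded); the same morphology chain as the OCT branch. The
ruler scale is the least-squares slope of tick position against tick index
(a median of integer pixel gaps inherits a ±1 px quantization bias that can
exceed 1%); a periodicity guard (worst gap deviation > max(25%, 1.5 px) of
the spacing) rejects pseudo-peaks in tickless regions. "Semi-automatic"
operator input is replaced by the fully automatic chain with an optional ROI
restriction. No curvature correction is applied to photographs.

## Statistics

`RepeatedMeasuresAnova` implements the classical balanced split-plot
decomposition (treatment tested against subjects-within-arms; time and
time × treatment against the time × subject residual) with exact
F-distribution p-values; sums of squares are validated against an
independent projection-matrix least-squares oracle and against
`pingouin.mixed_anova`. Missing cells abort with the cells named — no
imputation. An effect with zero sum of squares has F defined as 0 even when
the error term is also 0.

Sphericity: the default report is the uncorrected univariate F, with a
Greenhouse–Geisser option (`correction="gg"`, ε from the pooled
within-group covariance, floored at 1/(t−1)). This matters for calibration:
the generator's between-animal speed heterogeneity is a random-slope
covariance structure, under which the uncorrected interaction F is
anti-conservative (measured type-I ≈ 0.11 at α = 0.05 under the simulated
null), while the GG-adjusted test holds its nominal size (≈ 0.057). The
calibration test asserts the band for the adjusted test and separately
documents the uncorrected inflation. The headline effect under the default
arm separation is p ≪ 0.01 under either test. ANOVA uses raw areas (no
variance-stabilizing transform), matching how such measurements are normally
summarized in mm².

Method agreement pairs each animal-timepoint's OCT and fluorescein areas;
pairs where both read 0 (closed wound) are excluded from the correlation by
default (they are uninformative constants) but kept in the ANOVA (they carry
the healing signal). Closure-speed recovery fits a per-animal line to the
equivalent radius √(area/π) over open-wound timepoints and negates the slope.

## Study runner

Two execution modes: `fast` applies the series-level noise model directly
(statistics in milliseconds; used for Monte-Carlo type-I/power work via a
batched ANOVA over replicates), `images` renders and measures an OCT volume
and a photograph per animal-timepoint through the full pipelines. Stromal
damage at baseline excludes an animal when the detected surface dips more
than 20 µm (an invented but recorded criterion) below the robust sphere fit
over at least 0.05 mm² of contiguous area; an epithelium-only wound is not
flagged. Every run writes its exact configuration (YAML) and a manifest with
the derived seeds, so outputs are byte-reproducible from config + seed.
Designs too small for the ANOVA (< 2 animals/arm) complete with the ANOVA
skipped and marked null in the manifest.

## Known limitations

- The spherical-cap model ignores corneal asphericity and the epithelial
  thickness profile; the curvature correction assumes the configured (or
  fitted) sphere over the whole wound.
- Ruler calibration assumes the ruler plane is at the eye's depth and
  parallel to the sensor (no perspective correction).
- The en face window must fit inside the epithelial band; axial sampling
  coarser than ~⅓ of the epithelial thickness leaves no usable window.
- `fast`-mode noise is an aggregate stand-in for the image pipelines'
  error; the two agree a few percent for resolved wounds but `fast` mode
  cannot reproduce resolution-dependent small-wound behaviour.
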