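# Methods

`rpcsvoct` re-creates, end to end and at desk scale, a label-free
angiography workflow for the radial peripapillary capillaries (RPCs):
speckle-variance optical coherence tomography (svOCT) flow contrast,
retinal-layer segmentation, en-face capillary morphometry, and the
mixed-effects analyses that relate capillary spacing to retinal nerve
fibre layer (RNFL) thickness. Because no live-subject volumes or donor
flat-mounts can ship with a software package, every stage is validated
against a synthetic phantom whose ground truth is known exactly. This
note documents the models, the defaults and their units, and what the
phantom does and does not emulate.

## Coordinate and array conventions

x = fast scan axis, y = slow axis, z = depth increasing posteriorly;
all physical quantities in μm unless stated. Volumes are indexed
`[repeat, y, z, x]`, en-face images `[y, x]`. In-plane angles are
degrees in [0, 180), measured from +x toward +y.

## Beam optics and scan geometry

Closed forms convert device parameters to physical scale:

* coherence length (axial resolution) `l_c = (2 ln 2 / π) λ0² / (Δλ n)`
  — with the 1060 nm / 61.5 nm source and n = 1.33 this is 6.06 μm;
* lateral spot FWHM `= √(2 ln 2) · ω0` — 8.59 μm for ω0 = 7.3 μm.
  (The factor is sometimes misprinted as `2 ln 2`, which would give
  10.1 μm and is inconsistent with the ~8.6 μm value the 7.3 μm waist
  implies; the square-root form is the correct Gaussian relation.)
* focal waist `ω0 = (λ0/n) f / (π w_pupil)`, with the Gullstrand–Le
  Grand theoretical-eye constants f = 22.29 mm (n'/P = 1.336/59.94 D)
  and n = 1.336 as documented defaults. A 1.5 mm pupil beam gives
  7.51 μm, within 3% of the 7.3 μm device estimate; which wavelength
  (in air or in medium) and which focal length the original estimate
  used is not stated, so agreement is checked to 10%.
* lateral scan extent on a reduced (single refracting surface) eye:
  the external half-angle θ refracts to θ' = asin(sin θ / n) and the
  spot traces an arc of radius equal to the axial eye length,
  `fov = 2 L θ'`. This deliberately follows the circle-of-radius-eye-
  length simplification rather than an anatomically centered globe.

## Phantom

**Networks.** Each peripapillary region (Sup, ST, Temp, IT, Inf, N) is
assigned a radial orientation (90°, 45°, 0°, 135°, 90°, 0°); a network
is a set of parallel polylines at constant perpendicular spacing,
centered in a square FOV (default 636.5 μm, matching the confocal
field), at mid-RNFL depth. `waviness` adds a per-capillary sinusoidal
perpendicular displacement of amplitude `waviness × spacing`. Defaults
— 5 μm diameter, 30–42 μm spacing by region (arcuate sectors denser) —
sit inside the ranges reported for human RPC beds. Hairpin loops and
anastomoses are not modelled; networks are strictly parallel, which is
the configuration the density/ICD protocol assumes.

**Speckle.** OCT speckle is fully developed: the rendered intensity is
the magnitude of a circular complex Gaussian field low-pass filtered at
the point-spread function scale (lateral FWHM 8.59 μm, axial 6.06 μm),
normalised to unit mean, and multiplied by a layer reflectivity map
(vitreous 0.05, RNFL 1.0, inner retina 0.4, RPE band 1.6, below 0.1,
arbitrary units) that is blurred by the same PSF. Static tissue reuses
one speckle realization across the N = 3 repeats; voxels inside flowing
capillaries mix in a fresh realization with weight
`flow_decorrelation × (tube volume fraction)`, so the across-repeat
variance carries the flow contrast. An earlier variant that drew
voxel-independent speckle and blurred the intensity afterwards was
rejected: blurring averages ~60 independent voxels and collapses the
across-repeat variance to ~1.5× background, whereas physical speckle
has PSF-sized grains at full contrast. Additive Gaussian detector
noise (σ = 0.02 by default, against a tissue mean of ~1) is applied
per repeat after rendering. Optional bulk motion shifts whole B-scans
of single repeats laterally (default off; probability and shift are
configurable), which saturates sv across the affected row — the streak
artifact.

**Tube rasterization.** En-face (histology-style) renders use
anti-aliased coverage so that foreground area matches the analytic
tube area to well under 3%; the 3-D flow fraction is estimated on a
3×3×3 subvoxel grid, making the rasterized tube volume match
`Σ π r² L` to ~1%.

**Study tables.** `generate_study_table` simulates per-(subject, eye,
region, technique) records: ICD = region mean + slope × (RNFL − grand
mean RNFL) + subject intercept + eye intercept + noise, with RNFL drawn
around a region-typical double-hump profile (sd 12 μm within region).
Defaults: slope −0.065 μm/μm (the published estimate), noise sd 2 μm,
intercept sd 1.5 μm, 9 subjects contributing 16 eyes; simulations at
"study scale" use 15 eyes so each region has 15 observations, matching
the original cohort. Density is 100/ICD by construction.

## Angiography

Speckle variance is the per-voxel population variance across repeats,
computed on first-repeat-shifted values so identical repeats give an
exact zero: `sv = (1/N) Σ (I_t − Ī)²`. The 1/N normalisation is a
documented convention; no downstream quantity depends on N vs N−1.
Background suppression zeroes values strictly below a percentile of the
nonzero sv (default 75th; the original display-time brightness/contrast
adjustment is not reproducible, so a percentile rule is used). Streak
rows — row medians more than 3 MAD above the global row median — are
replaced by interpolation between the nearest clean rows: a
motion-corrupted B-scan's sv is saturated across the whole row, so
attenuation cannot recover its vessels, while interpolation continues
the capillaries through the gap (validated by the paired-run recall
check). The en-face image reduces sv (mean by default, max available)
over the slab between two named layer boundaries, then a centered
floor-aligned crop to 636.5 μm matches the histology field.

## Layer segmentation

Boundaries are minimum-cost connected paths (|Δz| ≤ 5 px per lateral
step) found by dynamic programming on each repeat-averaged B-scan —
the standard shortest-path realization of single-boundary graph
segmentation; a joint multi-boundary graph is unnecessary at phantom
complexity. B-scans are pre-smoothed (σ = 1 px in depth, 4 px
laterally) so speckle grains do not capture the paths. The RPE/BM is
traced first on negative intensity (brightest band), then refined per
column to the strongest dark-to-bright edge within 10 px above the
bright path (the bright path runs inside the band; the refinement
recovers its anterior edge). The ILM is the strongest-edge path
restricted anterior to the RPE. All costs are normalised per B-scan,
making segmentation intensity-scale invariant. The RNFL/GCL boundary
is the RPE line shifted anteriorly by a configurable offset (the
original delineation was manual; `fit_rnfl_offset` calibrates the
offset against phantom truth as the median of rpe − truth). RNFL
thickness is the lateral mean of (RNFL/GCL − ILM) averaged over 10
evenly spaced B-scans; both the selection rule and the lateral mean
are declared defaults, as the source protocol states neither.

## Morphometry

The estimators are algorithmic surrogates for a manual protocol and
are validated against phantom truth, not against per-region human
means:

* **binarize** — ISODATA (midpoint-between-class-means) threshold on
  the nonzero values of a 1 px smoothed copy, applied to the smoothed
  image; nonzero-only so zeroed backgrounds do not bias the split, and
  midpoint-form so a clean two-level image is recovered exactly at its
  half-amplitude edges (Otsu pulls below the window once smoothing
  creates faint edge tails). A disk(1) closing removes pinholes; a
  foreground fraction > 0.5 raises an inverted-contrast warning.
* **dominant orientation** — image-averaged structure tensor; the
  principal gradient direction is perpendicular to the vessels. The
  tensor coherence (λ1−λ2)/(λ1+λ2) must exceed 0.2, otherwise the
  image is declared isotropic and a manual angle is required.
  Accuracy on parallel-bar inputs is ~1.5°.
* **sampling line** — through the image center, perpendicular to the
  dominant orientation, length capped at the image width so oblique
  lines do not overhang into sparsely vascularised corners.
* **crossings** — the mask is first closed along the vessel axis with
  a 60 μm line element: with only 3 repeats the sv of a capillary has
  deep nulls along its length (the "beaded" appearance), and a reader
  counting crossings bridges those gaps visually; the directional
  closing is the algorithmic equivalent and cannot merge parallel
  neighbours. The line is then sampled bilinearly at 0.25 px steps and
  each maximal foreground run ≥ 1 px counts as one crossing.
* **density and ICD** — density = 100 n / L per 100 μm and
  ICD = L / n, so density × ICD ≡ 100; zero crossings flag ICD as
  undefined.
* **diameter** — per connected component, intensity profiles are taken
  perpendicular to the local skeleton tangent at up to 7 points; the
  vessel diameter is the largest full-width-at-half-maximum among its
  unimodal profiles ("maximum chord" read as the widest perpendicular
  profile — the operational definition is not stated in the source).
  FWHM is measured on the grayscale image (amplitude scale — the
  square root — when the pixels are sv values), so the value reflects
  the PSF-convolved apparent width; this reproduces the svOCT >
  histology diameter bias for every paired render.

## Statistics

All regressions are linear mixed models (statsmodels MixedLM) with
random intercepts for eye nested in subject, REML estimation. ICD
responses are log-transformed in technique comparisons (the source's
normality transform); the ICD–RNFL model defaults to the raw scale
with the log branch available, since the scale of the published slope
is ambiguous. P-values default to Wald z-tests on the REML fit;
likelihood-ratio tests from ML refits are available (`p_method="lrt"`).
In a 500-replicate null simulation at study scale the Wald test
rejected at 6.0% (LRT 7.0%) for α = 0.05, which is why Wald is the
default. Degenerate zero-residual fits (noise-free constructions)
report p = 1 for vanishing estimates. `zero_random_effects=True` pins
both intercept variances at 1e-8 (an exact zero makes the profiled
covariance solver singular), which reproduces OLS to ~1e-9. The age
comparison is a Welch two-sample t-test; no multiple-testing
correction is applied anywhere, matching the raw per-region reporting
convention, and a flag is available in the comparison tables.

## Pipeline

`run_pipeline` executes simulate → angiogram → segment → quantify →
stats per (subject, eye, region) from a schema-validated YAML/dict
config (unknown keys rejected). Default problem sizes are chosen for
desk-scale runs: a 120×120×3 grid over 700 μm with 150 depth pixels of
2 μm (the clinical grid was 300×300×3 over ~1×1 mm; depth sampling is
not stated in the source and any grid covering the layers is valid).
Per-eye RNFL truth is linked to capillary spacing through the default
slope so the downstream regression has signal. The streak filter runs
only when bulk motion is simulated. Every artifact embeds the seed
and a config hash; identical config + seed reproduce byte-identical
CSVs (sub-seeds are drawn from one master generator in a fixed order).

## What the phantom does and does not show

Passing tests demonstrate that the estimators recover known truth
under fully developed speckle, PSF blur, detector noise, layered
anatomy and bulk-motion artifacts. They do not demonstrate robustness
to eye-motion warping between repeats (gate alignment is assumed
perfect), pulsatile or heterogeneous flow, capillary branching and
hairpin topology, pathology, or media opacity — real-data performance
on those axes is out of scope. Accuracy figures (e.g. ICD within ±10%)
are specific to the default grid resolution (4.67 μm lateral pixels);
coarser grids degrade crossing detection well before the optics
justify it.

## Numerical choices

Population (1/N) variance; percentile threshold keeps exact ties;
crop uses a centered floor-aligned window (idempotent); DP paths break
cost ties toward smaller depth via argmin; orientation ties resolve
toward 0°; degenerate numeric slabs select the nearest depth plane,
while equal named boundaries are an error; sub-seeds for batch runs
are drawn below 2³¹.
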