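# rpcsvoct

Label-free angiography and morphometry of the radial peripapillary
capillaries (RPCs) — the parallel, radially oriented capillary beds in
the retinal nerve fibre layer (RNFL) around the optic disc — built
around **speckle-variance optical coherence tomography (svOCT)** and
validated end to end on a synthetic retina phantom.

svOCT acquires N repeat B-scans at each slow-axis location; moving
blood cells decorrelate the speckle between repeats, so the per-voxel
intensity variance

    sv(y, z, x) = (1/N) Σ_t ( I_t(y, z, x) − Ī(y, z, x) )²

is high inside perfused capillaries and low in static tissue. Mean sv
over the RNFL slab (between the internal limiting membrane, ILM, and
the RNFL/GCL boundary) yields an en-face angiogram on which capillary
beds are quantified the way flat-mount histology is read: a line of
length L perpendicular to the capillaries crossing n vessels gives a
density of 100·n/L per 100 μm and an inter-capillary distance
ICD = L/n; capillary diameter is the FWHM of the perpendicular
intensity profile at the vessel's widest point. ICD is then related to
RNFL thickness with a linear mixed model (random intercepts for eye
nested in subject):

    ICD ~ RNFL + region + (1 | subject/eye)

The package is a library first: `import rpcsvoct` and compose the
stages, or use the thin `rpcsvoct` CLI / `run_pipeline` orchestrator
for configured end-to-end runs. Because live-subject volumes cannot
ship with software, a first-class phantom module generates
ground-truth capillary networks and renders them both as repeat-
resolved svOCT volumes (fully developed speckle with PSF-sized grains,
flow decorrelation, layered retina, optional bulk-motion streaks) and
as histology-style en-face images of the same truth, so every stage is
tested against known answers. See `docs/methods.md` for the models and
defaults.

## Worked example

```python
import rpcsvoct as r

# device scale from the source and beam parameters
print(round(r.coherence_length(1060, 61.5, 1.33), 2))  # 6.06 (μm, axial)
print(round(r.lateral_fwhm(7.3), 2))                   # 8.6  (μm, lateral)

# phantom: parallel capillaries, 35 μm apart, in a layered retina
geom = r.ScanGeometry(n_fast=150, n_slow=150, fov_um=700,
                      n_depth=120, depth_pixel_um=2.0)
layers = r.generate_layers(geom, ilm_um=40, rnfl_um=60, rpe_um=200)
net = r.generate_network("ST", spacing_um=35, diameter_um=5,
                         n_capillaries=27, waviness=0.0, seed=1,
                         fov_um=700)
vol, truth = r.render_oct_volume(net, layers, geom, r.SpeckleParams(seed=1))

# angiography + segmentation + morphometry
ilm, rpe = r.segment_boundaries(vol.mean_intensity(), depth_pixel_um=2.0)
offset = r.fit_rnfl_offset(rpe, layers.rnfl_gcl_depth)
model = r.segmentation.build_layer_model(ilm, rpe, offset)
ef = r.enface_project(r.speckle_variance(vol), model,
                      slab=("ILM", "RNFL/GCL"))
ef = r.crop_enface(r.threshold_sv(ef, 75), 636.5)
res = r.measure_enface(ef, angle_deg=(net.dominant_angle + 90) % 180,
                       measure_diameters=False)
print(f"ICD {res.icd_um:.1f} μm, density {res.density_per_100um:.2f}/100 μm")
# ICD 33.4 μm, density 2.99/100 μm   (truth: 35 μm, 2.86/100 μm)
```

The recovered ICD sits within 5% of the generated 35 μm spacing; the
density is its exact reciprocal (×100) by construction. Narrative
scripts in `examples/` walk through each capability — optics
calibration, phantom rendering and recovery, the diameter PSF bias,
and the mixed-model study analysis — each printing the numbers it
computes and what they mean.

## CLI

```bash
rpcsvoct simulate --region ST --spacing-um 35 --seed 1 --out out/
rpcsvoct segment --volume out/volume.tif --offset-um 120 --out out/layers.json
rpcsvoct angiogram --volume out/volume.tif --layers out/layers.json --out out/enface.tif
rpcsvoct quantify --enface out/enface.tif --region ST --out out/morphometry.csv
rpcsvoct stats --records records.csv --out stats.json
rpcsvoct all --config cfg.yaml --seed 1 --out run/
```
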