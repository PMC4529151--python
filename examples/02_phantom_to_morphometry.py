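"""Full chain on one phantom eye: simulate, project, segment, measure.

Generates a capillary network with known 35 μm spacing, renders the
repeat-resolved svOCT volume, computes the speckle-variance angiogram,
segments the layers, and measures density / ICD — then compares every
estimate with the generating truth.
"""

import warnings

import numpy as np

import rpcsvoct as r
from rpcsvoct.phantom import max_capillaries

warnings.filterwarnings("ignore")

SPACING = 35.0
geom = r.ScanGeometry(n_fast=150, n_slow=150, fov_um=700.0,
                      n_depth=120, depth_pixel_um=2.0)
layers = r.generate_layers(geom, ilm_um=40, rnfl_um=60, rpe_um=200,
                           tilt_x_um=15, tilt_y_um=10)
net = r.generate_network("ST", SPACING, diameter_um=5,
                         n_capillaries=max_capillaries("ST", SPACING, 5, 700),
                         waviness=0.0, seed=7, fov_um=700)
volume, truth = r.render_oct_volume(net, layers, geom, r.SpeckleParams(seed=7))
print(f"rendered volume {volume.intensity.shape} [repeat, slow, depth, fast]")

sv = r.speckle_variance(volume)
flow = truth["flow_mask"]
print(f"sv inside capillaries {sv.sv[flow].mean():.4f} vs static "
      f"{sv.sv[~flow].mean():.6f} "
      f"({sv.sv[flow].mean() / sv.sv[~flow].mean():.0f}x flow contrast)")

ilm, rpe = r.segment_boundaries(volume.mean_intensity(), depth_pixel_um=2.0)
print(f"ILM boundary error {np.abs(ilm - layers.ilm_depth).mean() / 2:.2f} px,"
      f" RPE {np.abs(rpe - layers.rpe_depth).mean() / 2:.2f} px")

offset = r.fit_rnfl_offset(rpe, layers.rnfl_gcl_depth)
model = r.segmentation.build_layer_model(ilm, rpe, offset)
th = r.rnfl_thickness(model)
print(f"RNFL thickness {th.mean_um:.1f} μm over {th.n_bscans} B-scans "
      f"(truth 60 μm)")

enface = r.enface_project(sv, model, slab=("ILM", "RNFL/GCL"))
enface = r.crop_enface(r.threshold_sv(enface, 75), 636.5)
res = r.measure_enface(enface, region_label="ST", technique="svOCT",
                       angle_deg=(net.dominant_angle + 90) % 180,
                       diameter_scale="sqrt")
print(f"{res.n_crossings} capillaries cross the sampling line")
print(f"ICD {res.icd_um:.1f} μm (truth {SPACING}), density "
      f"{res.density_per_100um:.2f}/100 μm (truth {100 / SPACING:.2f})")
print(f"mean apparent diameter {res.mean_diameter_um:.1f} μm "
      f"(5 μm tubes widened by the 8.6 μm PSF)")
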