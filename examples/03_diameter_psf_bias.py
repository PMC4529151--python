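"""Why svOCT overstates capillary diameter relative to histology.

Renders the same ground-truth network twice — at confocal resolution
(0.5 μm PSF) and at OCT resolution (8.6 μm PSF) — and measures FWHM
diameters on both. The imaging beam convolves the capillary with the
spot, so the lower-resolution render is systematically wider.
"""

import warnings

import numpy as np

import rpcsvoct as r

warnings.filterwarnings("ignore")

print("seed  histology-PSF(μm)  OCT-PSF(μm)")
for seed in range(5):
    net = r.generate_network("ST", 35.0, diameter_um=5.0, n_capillaries=12,
                             waviness=0.2, seed=seed)
    hist = r.render_histology(net, pixel_um=1.0, psf_fwhm_um=0.5)
    svo = r.render_histology(net, pixel_um=1.0, psf_fwhm_um=8.59)
    d_h = np.mean(r.capillary_diameter(hist.pixels, pixel_um=1.0))
    d_s = np.mean(r.capillary_diameter(svo.pixels, pixel_um=1.0))
    print(f"  {seed}        {d_h:5.2f}            {d_s:5.2f}")

print("\nTrue tube diameter is 5 μm in every case: the histology-"
      "resolution value recovers it, while the OCT-resolution value is "
      "inflated to roughly the convolution of a 5 μm rect with the "
      "8.6 μm spot (~9.3 μm). The bias direction holds for every seed — "
      "the same asymmetry seen when in-vivo angiograms are compared "
      "with flat-mount microscopy of the same beds.")
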