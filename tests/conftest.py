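import numpy as np
import pytest

import rpcsvoct as r
from rpcsvoct.phantom import max_capillaries


@pytest.fixture(scope="session")
def small_geometry():
    """Scan grid used by most phantom-based tests (700 μm FOV,
    4.67 μm lateral pitch, 240 μm depth)."""
    return r.ScanGeometry(n_fast=150, n_slow=150, fov_um=700.0,
                          n_depth=120, depth_pixel_um=2.0)


@pytest.fixture(scope="session")
def sloped_layers(small_geometry):
    return r.generate_layers(small_geometry, ilm_um=40.0, rnfl_um=60.0,
                             rpe_um=200.0, tilt_x_um=15.0, tilt_y_um=10.0)


@pytest.fixture(scope="session")
def flat_layers(small_geometry):
    return r.generate_layers(small_geometry, ilm_um=40.0, rnfl_um=60.0,
                             rpe_um=200.0)


@pytest.fixture(scope="session")
def st_network():
    n = max_capillaries("ST", 35.0, 5.0, 700.0)
    return r.generate_network("ST", 35.0, 5.0, n, 0.0, seed=0, fov_um=700.0)


@pytest.fixture(scope="session")
def default_render(st_network, flat_layers, small_geometry):
    """One default-parameter svOCT render shared across tests."""
    volume, truth = r.render_oct_volume(
        st_network, flat_layers, small_geometry, r.SpeckleParams(seed=0))
    return volume, truth


def run_enface_chain(volume, layer_model, percentile=75.0, crop_um=636.5):
    """Standard sv → project → threshold → crop chain."""
    sv = r.speckle_variance(volume)
    ef = r.enface_project(sv, layer_model, slab=("ILM", "RNFL/GCL"))
    ef = r.threshold_sv(ef, percentile=percentile)
    return r.crop_enface(ef, crop_um=crop_um)


@pytest.fixture(scope="session")
def enface_chain():
    return run_enface_chain
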