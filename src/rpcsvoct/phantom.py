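"""Synthetic retina phantom.

Generates ground-truth radial peripapillary capillary (RPC) networks —
approximately parallel capillaries confined to the retinal nerve fibre
layer (RNFL) of one peripapillary region — and renders them two ways:

* ``render_histology``: a high-resolution en-face image of the tubes at
  their true diameters, emulating a confocal flat-mount projection;
* ``render_oct_volume``: a repeat-resolved OCT intensity volume with a
  layered retina, static-tissue speckle that repeats across acquisitions
  and flow-decorrelated speckle inside perfused capillaries, lateral and
  axial PSF blur, optional bulk-motion streaks, and a voxel-level truth
  sidecar.

It also generates synthetic study tables (per subject/eye/region
measurements with subject- and eye-level random intercepts) for the
mixed-model analyses. All generators are deterministic per seed.

Coordinates: x = fast axis, y = slow axis, z = depth increasing
posteriorly; physical units μm throughout; volumes are indexed
``[repeat, y, z, x]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .angiography import EnFaceImage, OCTVolume
from .optics import ScanGeometry

__all__ = [
    "REGIONS",
    "REGION_ANGLES",
    "ARCUATE_REGIONS",
    "CapillaryNetwork",
    "RetinaLayersTruth",
    "SpeckleParams",
    "generate_network",
    "generate_layers",
    "render_histology",
    "render_oct_volume",
    "generate_study_table",
    "STUDY_COLUMNS",
    "DEFAULT_ICD_MEANS_UM",
    "DEFAULT_RNFL_MEANS_UM",
]

REGIONS = ("Sup", "ST", "Temp", "IT", "Inf", "N")
ARCUATE_REGIONS = ("ST", "IT")

# Radial direction of the capillaries within each peripapillary sector,
# degrees from the +x (fast) axis toward +y (slow), mod 180. Temporal and
# nasal sectors run horizontally, superior/inferior vertically, the
# arcuate sectors obliquely.
REGION_ANGLES = {
    "Sup": 90.0, "ST": 45.0, "Temp": 0.0, "IT": 135.0, "Inf": 90.0, "N": 0.0,
}

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class CapillaryNetwork:
    """Ground-truth capillary geometry for one region.

    ``capillaries`` is a list of (m, 3) float arrays of polyline points
    in μm (columns x, y, z); ``diameters`` and ``flow`` are per
    capillary. ``dominant_angle`` is the intended common orientation in
    degrees [0, 180).
    """

    capillaries: list[np.ndarray]
    diameters: np.ndarray
    flow: np.ndarray
    region_label: str
    dominant_angle: float
    fov_um: float = 636.5

    def __post_init__(self) -> None:
        self.capillaries = [np.asarray(c, dtype=float) for c in self.capillaries]
        self.diameters = np.asarray(self.diameters, dtype=float)
        self.flow = np.asarray(self.flow, dtype=bool)
        if np.any(self.diameters <= 0):
            raise ValueError("all diameters must be > 0")
        for c in self.capillaries:
            if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 2:
                raise ValueError("each capillary is an (m>=2, 3) polyline")
            xy = c[:, :2]
            if np.any(xy < -1e-9) or np.any(xy > self.fov_um + 1e-9):
                raise ValueError("polyline points must lie inside the FOV")

    def measured_dominant_angle(self) -> float:
        """Length-weighted circular mean of segment orientations (deg,
        period 180)."""
        sin2 = cos2 = 0.0
        for c in self.capillaries:
            d = np.diff(c[:, :2], axis=0)
            lengths = np.hypot(d[:, 0], d[:, 1])
            ang = np.arctan2(d[:, 1], d[:, 0])
            cos2 += float(np.sum(lengths * np.cos(2 * ang)))
            sin2 += float(np.sum(lengths * np.sin(2 * ang)))
        return math.degrees(0.5 * math.atan2(sin2, cos2)) % 180.0

    def total_length_um(self) -> float:
        return float(sum(
            np.hypot(*np.diff(c[:, :2], axis=0).T).sum()
            for c in self.capillaries))

    def to_dict(self) -> dict:
        return {
            "region_label": self.region_label,
            "dominant_angle": self.dominant_angle,
            "fov_um": self.fov_um,
            "diameters_um": self.diameters.tolist(),
            "flow": self.flow.astype(int).tolist(),
            "capillaries_um": [c.tolist() for c in self.capillaries],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CapillaryNetwork":
        return cls(
            capillaries=[np.asarray(c) for c in d["capillaries_um"]],
            diameters=np.asarray(d["diameters_um"]),
            flow=np.asarray(d["flow"], dtype=bool),
            region_label=d["region_label"],
            dominant_angle=d["dominant_angle"],
            fov_um=d["fov_um"],
        )


@dataclass
class RetinaLayersTruth:
    """Ground-truth layer boundary depth maps (μm) over (slow, fast).

    ``reflectivity`` gives the mean speckle intensity of each
    compartment in arbitrary units; ``rpe_band_um`` is the thickness of
    the bright RPE/BM complex below the ``rpe_depth`` boundary.
    """

    ilm_depth: np.ndarray
    rnfl_gcl_depth: np.ndarray
    rpe_depth: np.ndarray
    reflectivity: dict = field(default_factory=lambda: {
        "vitreous": 0.05, "rnfl": 1.0, "inner": 0.4,
        "rpe": 1.6, "below": 0.1,
    })
    rpe_band_um: float = 15.0

    def __post_init__(self) -> None:
        self.ilm_depth = np.asarray(self.ilm_depth, dtype=float)
        self.rnfl_gcl_depth = np.asarray(self.rnfl_gcl_depth, dtype=float)
        self.rpe_depth = np.asarray(self.rpe_depth, dtype=float)
        if not (np.all(self.ilm_depth < self.rnfl_gcl_depth)
                and np.all(self.rnfl_gcl_depth < self.rpe_depth)):
            raise ValueError("layer ordering ilm < rnfl_gcl < rpe violated")


@dataclass(frozen=True)
class SpeckleParams:
    """Speckle/noise model of one repeat-resolved acquisition.

    ``flow_decorrelation`` is the mixing weight of fresh per-repeat
    speckle inside flowing capillaries (1 = fully independent speckle
    per repeat); static tissue reuses a single speckle realization
    across repeats. ``noise_floor`` is the std of additive detector
    noise applied per repeat after PSF blur.
    """

    n_repeats: int = 3
    static_scale: float = 1.0
    flow_decorrelation: float = 0.9
    noise_floor: float = 0.02
    bulk_motion_prob: float = 0.0
    bulk_motion_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if not (0.0 <= self.flow_decorrelation <= 1.0):
            raise ValueError("flow_decorrelation must be in [0, 1]")
        if not (0.0 <= self.bulk_motion_prob <= 1.0):
            raise ValueError("bulk_motion_prob must be in [0, 1]")


def max_capillaries(region_label: str, spacing_um: float,
                    diameter_um: float = 5.0, fov_um: float = 636.5,
                    waviness: float = 0.0) -> int:
    """Largest capillary count that fits the FOV at the given spacing
    along the region's orientation (used to fill the field)."""
    a = math.radians(REGION_ANGLES[region_label])
    extent = fov_um * (abs(math.sin(a)) + abs(math.cos(a)))
    margin = diameter_um / 2.0 + waviness * spacing_um
    return int((extent - 2.0 * margin) // spacing_um) + 1


def generate_network(region_label: str, spacing_um: float = 35.0,
                     diameter_um: float = 5.0, n_capillaries: int = 18,
                     waviness: float = 0.0, seed: int = 0, *,
                     fov_um: float = 636.5, depth_um: float = 65.0,
                     depth_jitter_um: float = 2.0) -> CapillaryNetwork:
    """Generate approximately parallel capillaries for one region.

    Capillaries are straight (waviness 0) or sinusoidally perturbed
    polylines along the region's radial direction, at a constant
    perpendicular spacing ``spacing_um``, centered in a square FOV and
    placed at mid-RNFL depth. Deterministic per seed.

    ``waviness`` scales a sinusoidal perpendicular displacement with
    amplitude ``waviness * spacing_um``.
    """
    if region_label not in REGION_ANGLES:
        raise KeyError(f"unknown region {region_label!r}; "
                       f"expected one of {REGIONS}")
    if not (spacing_um > diameter_um > 0):
        raise ValueError("require spacing_um > diameter_um > 0")
    if n_capillaries < 1:
        raise ValueError("n_capillaries must be >= 1")

    rng = np.random.default_rng(seed)
    angle = REGION_ANGLES[region_label]
    a = math.radians(angle)
    u = np.array([math.cos(a), math.sin(a)])      # along capillaries
    p = np.array([-math.sin(a), math.cos(a)])     # perpendicular

    amp = waviness * spacing_um
    margin = diameter_um / 2.0 + amp
    extent = fov_um * (abs(p[0]) + abs(p[1]))     # FOV extent along p
    span = (n_capillaries - 1) * spacing_um
    if span + 2 * margin > extent:
        max_n = int((extent - 2 * margin) // spacing_um) + 1
        raise ValueError(
            f"{n_capillaries} capillaries at {spacing_um} μm spacing do not "
            f"fit the {fov_um} μm FOV; at most {max_n} are feasible")

    center = np.array([fov_um / 2.0, fov_um / 2.0])
    lo, hi = margin, fov_um - margin
    caps: list[np.ndarray] = []
    for i in range(n_capillaries):
        offset = (i - (n_capillaries - 1) / 2.0) * spacing_um
        base = center + offset * p
        # Liang–Barsky: parameter range of base + t·u inside [lo, hi]²
        t0, t1 = -np.inf, np.inf
        for dim in range(2):
            if abs(u[dim]) < 1e-12:
                if not (lo <= base[dim] <= hi):
                    t0, t1 = 0.0, 0.0
                continue
            ta = (lo - base[dim]) / u[dim]
            tb = (hi - base[dim]) / u[dim]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
        if not (t1 > t0):
            continue
        z = depth_um + rng.uniform(-depth_jitter_um, depth_jitter_um)
        if waviness == 0.0:
            pts2 = np.stack([base + t0 * u, base + t1 * u])
        else:
            length = t1 - t0
            n_pts = max(8, int(length / 10.0))
            ts = np.linspace(t0, t1, n_pts)
            wavelength = rng.uniform(150.0, 320.0)
            phase = rng.uniform(0.0, 2.0 * math.pi)
            disp = amp * np.sin(2.0 * math.pi * ts / wavelength + phase)
            pts2 = base[None, :] + ts[:, None] * u[None, :] \
                + disp[:, None] * p[None, :]
        pts2 = np.clip(pts2, 0.0, fov_um)
        pts = np.column_stack([pts2, np.full(len(pts2), z)])
        caps.append(pts)

    n = len(caps)
    return CapillaryNetwork(
        capillaries=caps,
        diameters=np.full(n, diameter_um),
        flow=np.ones(n, dtype=bool),
        region_label=region_label,
        dominant_angle=angle,
        fov_um=fov_um,
    )


def generate_layers(geometry: ScanGeometry, ilm_um: float = 40.0,
                    rnfl_um: float = 60.0, rpe_um: float = 280.0,
                    tilt_x_um: float = 0.0, tilt_y_um: float = 0.0,
                    rnfl_gradient_um: float = 0.0,
                    reflectivity: dict | None = None) -> RetinaLayersTruth:
    """Smooth layered-retina truth maps on a scan grid.

    ``tilt_*`` tilt all boundaries linearly across the FOV (total μm
    change edge to edge); ``rnfl_gradient_um`` additionally varies the
    RNFL thickness linearly along the fast axis.
    """
    ny, nx = geometry.n_slow, geometry.n_fast
    fx = (np.arange(nx) + 0.5) / nx - 0.5
    fy = (np.arange(ny) + 0.5) / ny - 0.5
    tilt = tilt_x_um * fx[None, :] + tilt_y_um * fy[:, None]
    ilm = ilm_um + tilt
    thickness = rnfl_um + rnfl_gradient_um * fx[None, :] + 0.0 * fy[:, None]
    if np.any(thickness <= 0):
        raise ValueError("RNFL thickness must stay positive across the FOV")
    rnfl_gcl = ilm + thickness
    rpe = rpe_um + tilt
    kwargs = {} if reflectivity is None else {"reflectivity": reflectivity}
    return RetinaLayersTruth(ilm_depth=np.broadcast_to(ilm, (ny, nx)).copy(),
                             rnfl_gcl_depth=rnfl_gcl,
                             rpe_depth=np.broadcast_to(rpe, (ny, nx)).copy(),
                             **kwargs)


def _segment_coverage_2d(img: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                         radius: float, pixel_um: float) -> None:
    """Accumulate (max) anti-aliased coverage of one tube segment."""
    pad = radius + pixel_um
    x_lo = max(0, int((min(p0[0], p1[0]) - pad) / pixel_um))
    x_hi = min(img.shape[1], int((max(p0[0], p1[0]) + pad) / pixel_um) + 2)
    y_lo = max(0, int((min(p0[1], p1[1]) - pad) / pixel_um))
    y_hi = min(img.shape[0], int((max(p0[1], p1[1]) + pad) / pixel_um) + 2)
    if x_lo >= x_hi or y_lo >= y_hi:
        return
    xs = (np.arange(x_lo, x_hi) + 0.5) * pixel_um
    ys = (np.arange(y_lo, y_hi) + 0.5) * pixel_um
    X, Y = np.meshgrid(xs, ys)
    d = p1 - p0
    l2 = float(d @ d)
    if l2 == 0:
        dist = np.hypot(X - p0[0], Y - p0[1])
    else:
        t = np.clip(((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / l2, 0.0, 1.0)
        dist = np.hypot(X - (p0[0] + t * d[0]), Y - (p0[1] + t * d[1]))
    cov = np.clip((radius - dist) / pixel_um + 0.5, 0.0, 1.0)
    region = img[y_lo:y_hi, x_lo:x_hi]
    np.maximum(region, cov, out=region)


def render_histology(network: CapillaryNetwork, pixel_um: float = 1.0,
                     psf_fwhm_um: float = 0.5) -> EnFaceImage:
    """Rasterize the network en face at its true diameters.

    Tubes are drawn with anti-aliased (area-accurate) edges at
    ``pixel_um`` pitch on a zero background, then blurred by a Gaussian
    PSF of the given FWHM; a small PSF (~0.5 μm) emulates confocal
    flat-mount resolution, a large one (~8.6 μm) emulates the OCT spot.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be > 0")
    if psf_fwhm_um < 0:
        raise ValueError("psf_fwhm_um must be >= 0")
    n = int(round(network.fov_um / pixel_um))
    img = np.zeros((n, n), dtype=float)
    for cap, diam in zip(network.capillaries, network.diameters):
        r = diam / 2.0
        for j in range(len(cap) - 1):
            _segment_coverage_2d(img, cap[j, :2], cap[j + 1, :2], r, pixel_um)
    if psf_fwhm_um > 0:
        img = gaussian_filter(img, sigma=psf_fwhm_um * _FWHM_TO_SIGMA / pixel_um)
    return EnFaceImage(pixels=img, pixel_um=pixel_um, slab="histology")


def _flow_fraction_3d(network: CapillaryNetwork, geometry: ScanGeometry,
                      offset_um: float, n_sub: int = 3) -> np.ndarray:
    """Volume fraction of each voxel inside a flowing tube, [y, z, x].

    Estimated by subsampling each voxel on an n_sub³ grid and testing
    distance to the capillary polylines; accurate to ~1% of tube volume.
    """
    ny, nz, nx = geometry.n_slow, geometry.n_depth, geometry.n_fast
    px, py, pz = geometry.pixel_um, geometry.pixel_slow_um, geometry.depth_pixel_um
    frac = np.zeros((ny, nz, nx), dtype=np.float32)
    offs = (np.arange(n_sub) + 0.5) / n_sub - 0.5
    sub = np.stack(np.meshgrid(offs * py, offs * pz, offs * px,
                               indexing="ij"), axis=-1).reshape(-1, 3)
    for cap, diam, flowing in zip(network.capillaries, network.diameters,
                                  network.flow):
        if not flowing:
            continue
        r = diam / 2.0
        pts = cap + np.array([offset_um, offset_um, 0.0])
        for j in range(len(pts) - 1):
            p0, p1 = pts[j], pts[j + 1]
            pad = r + max(px, py, pz)
            y_lo = max(0, int((min(p0[1], p1[1]) - pad) / py))
            y_hi = min(ny, int((max(p0[1], p1[1]) + pad) / py) + 2)
            z_lo = max(0, int((min(p0[2], p1[2]) - pad) / pz))
            z_hi = min(nz, int((max(p0[2], p1[2]) + pad) / pz) + 2)
            x_lo = max(0, int((min(p0[0], p1[0]) - pad) / px))
            x_hi = min(nx, int((max(p0[0], p1[0]) + pad) / px) + 2)
            if y_lo >= y_hi or z_lo >= z_hi or x_lo >= x_hi:
                continue
            yc = (np.arange(y_lo, y_hi) + 0.5) * py
            zc = (np.arange(z_lo, z_hi) + 0.5) * pz
            xc = (np.arange(x_lo, x_hi) + 0.5) * px
            Y, Z, X = np.meshgrid(yc, zc, xc, indexing="ij")
            d = np.array([p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]])
            l2 = float(d @ d)
            count = np.zeros(Y.shape, dtype=np.float32)
            for oy, oz, ox in sub:
                sx, sy, sz = X + ox, Y + oy, Z + oz
                if l2 == 0:
                    dist2 = ((sx - p0[0]) ** 2 + (sy - p0[1]) ** 2
                             + (sz - p0[2]) ** 2)
                else:
                    t = np.clip(((sx - p0[0]) * d[0] + (sy - p0[1]) * d[1]
                                 + (sz - p0[2]) * d[2]) / l2, 0.0, 1.0)
                    dist2 = ((sx - (p0[0] + t * d[0])) ** 2
                             + (sy - (p0[1] + t * d[1])) ** 2
                             + (sz - (p0[2] + t * d[2])) ** 2)
                count += dist2 <= r * r
            cov = count / len(sub)
            region = frac[y_lo:y_hi, z_lo:z_hi, x_lo:x_hi]
            np.maximum(region, cov, out=region)
    return frac


def _reflectivity_volume(layers: RetinaLayersTruth,
                         geometry: ScanGeometry) -> np.ndarray:
    ny, nz, nx = geometry.n_slow, geometry.n_depth, geometry.n_fast
    zc = ((np.arange(nz) + 0.5) * geometry.depth_pixel_um)[None, :, None]
    refl = layers.reflectivity
    ilm = layers.ilm_depth[:, None, :]
    rnfl_gcl = layers.rnfl_gcl_depth[:, None, :]
    rpe = layers.rpe_depth[:, None, :]
    vol = np.full((ny, nz, nx), refl["vitreous"], dtype=np.float32)
    vol[(zc >= ilm) & (zc < rnfl_gcl)] = refl["rnfl"]
    vol[(zc >= rnfl_gcl) & (zc < rpe)] = refl["inner"]
    vol[(zc >= rpe) & (zc < rpe + layers.rpe_band_um)] = refl["rpe"]
    vol[zc >= rpe + layers.rpe_band_um] = refl["below"]
    return vol


def render_oct_volume(network: CapillaryNetwork, layers: RetinaLayersTruth,
                      geometry: ScanGeometry, params: SpeckleParams, *,
                      lateral_fwhm_um: float = 8.59,
                      axial_fwhm_um: float = 6.06,
                      ) -> tuple[OCTVolume, dict]:
    """Render the phantom as a repeat-resolved svOCT acquisition.

    Speckle is modelled as the magnitude of a complex circular-Gaussian
    field low-pass filtered at the PSF scale (lateral FWHM and axial
    coherence length), then renormalised to unit mean — i.e. fully
    developed Rayleigh speckle whose grain size is the resolution cell,
    as in a coherent imaging system. Static voxels reuse one such
    realization across the N repeats; voxels inside flowing capillaries
    mix in a fresh per-repeat realization with weight
    ``flow_decorrelation × (tube volume fraction)``, so the
    across-repeat variance they carry is the sv flow contrast. The
    layer reflectivity map is blurred by the same PSF before modulating
    the speckle, and additive detector noise is applied per repeat.
    Optional bulk motion laterally shifts whole B-scans of single
    repeats, producing the bright en-face streak rows the streak filter
    removes.

    Returns the volume and a truth sidecar with the voxel flow fraction
    and mask, the layer truth, and the network.
    """
    if network.fov_um > geometry.fov_um + 1e-9:
        raise ValueError(
            f"network FOV {network.fov_um} μm exceeds scan FOV "
            f"{geometry.fov_um} μm")
    if layers.ilm_depth.shape != (geometry.n_slow, geometry.n_fast):
        raise ValueError(
            f"layer maps of shape {layers.ilm_depth.shape} do not match the "
            f"scan grid {(geometry.n_slow, geometry.n_fast)}")
    if float(np.max(layers.rpe_depth)) + layers.rpe_band_um >= geometry.depth_um:
        raise ValueError("depth range does not cover the RPE band")
    offset_um = (geometry.fov_um - network.fov_um) / 2.0
    zmin = float(np.min(layers.ilm_depth))
    zmax = float(np.max(layers.rnfl_gcl_depth))
    for cap in network.capillaries:
        if np.any(cap[:, 2] < zmin - 1e-6) or np.any(cap[:, 2] > zmax + 1e-6):
            raise ValueError("capillary depth outside the RNFL slab")

    rng = np.random.default_rng(params.seed)
    sigma = (lateral_fwhm_um * _FWHM_TO_SIGMA / geometry.pixel_slow_um,
             axial_fwhm_um * _FWHM_TO_SIGMA / geometry.depth_pixel_um,
             lateral_fwhm_um * _FWHM_TO_SIGMA / geometry.pixel_um)

    refl = _reflectivity_volume(layers, geometry)
    if any(s > 0 for s in sigma):
        refl = gaussian_filter(refl, sigma=sigma)
    scale = params.static_scale * refl

    def _speckle_field() -> np.ndarray:
        """Unit-mean Rayleigh speckle with PSF-sized grains."""
        re = rng.normal(size=refl.shape).astype(np.float32)
        im = rng.normal(size=refl.shape).astype(np.float32)
        if any(s > 0 for s in sigma):
            re = gaussian_filter(re, sigma=sigma)
            im = gaussian_filter(im, sigma=sigma)
        amp = np.hypot(re, im)
        return amp / amp.mean()

    base_field = _speckle_field()
    base = scale * base_field
    frac = _flow_fraction_3d(network, geometry, offset_um)
    flow_idx = frac > 0
    weight = (params.flow_decorrelation * frac[flow_idx]).astype(np.float32)

    n_rep = params.n_repeats
    motion = rng.random((n_rep, geometry.n_slow)) < params.bulk_motion_prob

    repeats = []
    for t in range(n_rep):
        vol = base.copy()
        if flow_idx.any():
            fresh = (scale * _speckle_field())[flow_idx]
            vol[flow_idx] = base[flow_idx] + weight * (fresh - base[flow_idx])
        for y in np.nonzero(motion[t])[0]:
            vol[y] = np.roll(vol[y], params.bulk_motion_px, axis=-1)
        if params.noise_floor > 0:
            vol = vol + rng.normal(
                0.0, params.noise_floor, vol.shape).astype(np.float32)
        repeats.append(np.clip(vol, 0.0, None))

    volume = OCTVolume(
        intensity=np.stack(repeats),
        spacing=(geometry.pixel_slow_um, geometry.depth_pixel_um,
                 geometry.pixel_um),
    )
    truth = {
        "flow_fraction": frac,
        "flow_mask": frac >= 0.5,
        "layers": layers,
        "network": network,
        "offset_um": offset_um,
        "seed": params.seed,
    }
    return volume, truth


STUDY_COLUMNS = ("subject", "eye", "region", "technique", "icd_um",
                 "density_per_100um", "diameter_um", "rnfl_um")

# Region means used by the study-table generator: ICD within the 30–42 μm
# range reported for RPC beds, smaller in the arcuate (ST/IT) sectors;
# RNFL means follow the typical human peripapillary double-hump profile.
DEFAULT_ICD_MEANS_UM = {
    "Sup": 38.0, "ST": 31.0, "Temp": 36.0, "IT": 32.0, "Inf": 38.0, "N": 35.0,
}
DEFAULT_RNFL_MEANS_UM = {
    "Sup": 115.0, "ST": 125.0, "Temp": 70.0, "IT": 125.0, "Inf": 118.0,
    "N": 85.0,
}
DEFAULT_DIAMETER_MEANS_UM = {"svOCT": 16.0, "histology": 7.0}


def generate_study_table(n_subjects: int = 9, regions=REGIONS,
                         icd_means: dict | None = None,
                         rnfl_slope: float = -0.065,
                         noise_sd: float = 2.0,
                         random_intercept_sd: float = 1.5,
                         seed: int = 0, *,
                         n_eyes: int | None = None,
                         techniques=("svOCT",),
                         technique_icd_offsets: dict | None = None,
                         rnfl_means: dict | None = None,
                         rnfl_sd: float = 12.0,
                         diameter_means: dict | None = None,
                         diameter_sd: float = 1.5) -> pd.DataFrame:
    """Simulate a per-(subject, eye, region, technique) study table.

    ICD is generated as ``region mean + rnfl_slope · (RNFL − mean RNFL)
    + subject intercept + eye intercept + noise``; RNFL varies around
    region means with sd ``rnfl_sd``; density is 100/ICD by
    construction. Subjects contribute 2 eyes except the last ones, so
    that ``n_eyes`` (default ``2·n_subjects − 2``, the study's 9
    subjects / 16 eyes) are emitted. ``technique_icd_offsets`` adds a
    per-region ICD shift to non-svOCT rows. Deterministic per seed.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_eyes is None:
        n_eyes = 2 * n_subjects - 2
    if not (n_subjects <= n_eyes <= 2 * n_subjects):
        raise ValueError("need n_subjects <= n_eyes <= 2*n_subjects")
    icd_means = dict(DEFAULT_ICD_MEANS_UM if icd_means is None else icd_means)
    rnfl_means = dict(
        DEFAULT_RNFL_MEANS_UM if rnfl_means is None else rnfl_means)
    diameter_means = dict(DEFAULT_DIAMETER_MEANS_UM
                          if diameter_means is None else diameter_means)
    offsets = technique_icd_offsets or {}
    rnfl_grand_mean = float(np.mean([rnfl_means[r] for r in regions]))

    rng = np.random.default_rng(seed)
    n_two_eyed = n_eyes - n_subjects
    rows = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        b_subject = rng.normal(0.0, random_intercept_sd)
        eyes = ("OD", "OS") if s < n_two_eyed else ("OD",)
        for eye in eyes:
            b_eye = rng.normal(0.0, random_intercept_sd)
            for region in regions:
                rnfl = rnfl_means[region] + rng.normal(0.0, rnfl_sd)
                for tech in techniques:
                    icd = (icd_means[region]
                           + rnfl_slope * (rnfl - rnfl_grand_mean)
                           + b_subject + b_eye
                           + rng.normal(0.0, noise_sd))
                    if tech != "svOCT":
                        icd += offsets.get(region, 0.0)
                    diam = rng.normal(
                        diameter_means.get(tech, 12.0), diameter_sd)
                    rows.append({
                        "subject": subject, "eye": eye, "region": region,
                        "technique": tech, "icd_um": icd,
                        "density_per_100um": 100.0 / icd,
                        "diameter_um": diam,
                        "rnfl_um": rnfl if tech == "svOCT" else np.nan,
                    })
    return pd.DataFrame(rows, columns=list(STUDY_COLUMNS))
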