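"""Speckle-variance angiography.

Flow contrast is obtained from N repeat B-scans acquired at each
slow-axis location: moving blood cells decorrelate the speckle pattern
between repeats, so the per-voxel intensity variance across the repeat
axis is high inside perfused capillaries and low in static tissue. This
module computes that variance, suppresses the static background
(percentile threshold), removes bulk-motion streak rows, and projects
the retinal-nerve-fibre-layer slab to a 2-D en-face angiogram.

Array convention: volumes are indexed ``[repeat, slow, depth, fast]``;
en-face images ``[slow, fast]``. Physical spacing is in μm per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "OCTVolume",
    "SVVolume",
    "EnFaceImage",
    "speckle_variance",
    "threshold_sv",
    "remove_streaks",
    "enface_project",
    "crop_enface",
]


@dataclass
class OCTVolume:
    """Repeat-resolved intensity volume.

    ``intensity`` has shape (n_repeats, n_slow, n_depth, n_fast);
    ``spacing`` is (slow_um, depth_um, fast_um) per voxel.
    """

    intensity: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        if self.intensity.ndim != 4:
            raise ValueError("intensity must be 4-D [repeat, slow, depth, fast]")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def n_repeats(self) -> int:
        return self.intensity.shape[0]

    def mean_intensity(self) -> np.ndarray:
        """Repeat-averaged structural volume [slow, depth, fast]."""
        return self.intensity.mean(axis=0)


@dataclass
class SVVolume:
    """Speckle-variance volume [slow, depth, fast] with voxel spacing."""

    sv: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv)
        if self.sv.ndim != 3:
            raise ValueError("sv must be 3-D [slow, depth, fast]")


@dataclass
class EnFaceImage:
    """2-D en-face projection [slow, fast] at a square lateral pitch."""

    pixels: np.ndarray
    pixel_um: float
    slab: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D [slow, fast]")


def speckle_variance(volume: OCTVolume) -> SVVolume:
    """Per-voxel population variance of intensity across repeats.

    sv = (1/N) Σ_t (I_t − Ī)², computed with the population (1/N)
    normalisation on values shifted by the first repeat (variance is
    shift-invariant; the shift makes identical repeats give exactly
    zero in floating point).
    """
    if volume.n_repeats < 2:
        raise ValueError("speckle variance requires at least 2 repeats")
    intensity = volume.intensity.astype(np.float64, copy=False)
    n = volume.n_repeats
    d = intensity - intensity[0]
    # explicit left-to-right accumulation over the (short) repeat axis:
    # bit-identical to a per-voxel scalar loop
    mean = d[0].copy()
    for t in range(1, n):
        mean += d[t]
    mean /= n
    sv = (d[0] - mean) ** 2
    for t in range(1, n):
        sv += (d[t] - mean) ** 2
    sv /= n
    return SVVolume(sv=sv, spacing=volume.spacing)


def _apply_to_pixels(obj, fn):
    if isinstance(obj, SVVolume):
        return replace(obj, sv=fn(obj.sv))
    if isinstance(obj, EnFaceImage):
        return replace(obj, pixels=fn(obj.pixels))
    return fn(np.asarray(obj))


def threshold_sv(sv, percentile: float = 75.0):
    """Zero out low speckle-variance values.

    The cut is the given percentile of the *nonzero* values; entries
    strictly below it are set to 0, everything else (including exact
    ties) is kept. Operates on SVVolume, EnFaceImage, or a bare array
    and returns the same type.
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must be in [0, 100)")

    def _thresh(a: np.ndarray) -> np.ndarray:
        nz = a[a > 0]
        if nz.size == 0:
            return a.copy()
        cut = np.percentile(nz, percentile)
        out = a.copy()
        out[out < cut] = 0.0
        return out

    return _apply_to_pixels(sv, _thresh)


def remove_streaks(enface: EnFaceImage, k_mad: float = 3.0) -> EnFaceImage:
    """Attenuate bulk-motion streak rows in an en-face angiogram.

    Bulk motion at a single B-scan location decorrelates the whole
    frame and produces a bright row (constant slow-axis coordinate) in
    which the genuine flow signal is unrecoverable. Rows whose median
    exceeds the global median of row medians by more than ``k_mad``
    MADs are replaced by linear interpolation between the nearest
    unflagged rows — capillaries crossing the corrupted B-scan location
    are continued from their neighbours, so vessel-scale structure is
    preserved. Flagged edge rows copy the nearest good row.
    """
    img = np.asarray(enface.pixels, dtype=float)
    row_med = np.median(img, axis=1)
    global_med = np.median(row_med)
    mad = np.median(np.abs(row_med - global_med))
    cut = global_med + k_mad * mad
    bad = row_med > cut
    if not bad.any() or bad.all():
        return replace(enface, pixels=img.copy())
    good = np.nonzero(~bad)[0]
    out = img.copy()
    for i in np.nonzero(bad)[0]:
        below = good[good < i]
        above = good[good > i]
        if below.size and above.size:
            j0, j1 = below[-1], above[0]
            w = (i - j0) / (j1 - j0)
            out[i] = (1 - w) * img[j0] + w * img[j1]
        else:
            out[i] = img[below[-1] if below.size else above[0]]
    return replace(enface, pixels=out)


_BOUNDARY_ATTRS = {
    "ILM": "ilm",
    "RNFL/GCL": "rnfl_gcl",
    "RPE/BM": "rpe",
    "RPE": "rpe",
}


def _slab_maps(layer_model, slab, lateral_shape):
    maps = []
    numeric = all(not isinstance(name, str) for name in slab)
    for name in slab:
        if isinstance(name, str):
            attr = _BOUNDARY_ATTRS.get(name)
            if attr is None:
                raise KeyError(f"unknown boundary name {name!r}; "
                               f"expected one of {sorted(_BOUNDARY_ATTRS)}")
            if layer_model is None:
                raise ValueError("named slab boundaries require a layer model")
            maps.append(np.asarray(getattr(layer_model, attr), dtype=float))
        else:
            maps.append(np.full(lateral_shape, float(name)))
    return maps, numeric


def enface_project(sv_volume: SVVolume, layer_model=None,
                   slab=("ILM", "RNFL/GCL"), reducer: str = "mean",
                   ) -> EnFaceImage:
    """Reduce sv over a depth slab to a 2-D en-face image.

    ``slab`` names two boundaries of the layer model ("ILM",
    "RNFL/GCL", "RPE/BM") or gives two fixed depths in μm. Voxels whose
    centers lie in [top, bottom) are reduced with ``mean`` or ``max``.
    A numerically equal pair of fixed depths selects the single nearest
    depth plane.
    """
    if reducer not in ("mean", "max"):
        raise ValueError("reducer must be 'mean' or 'max'")
    sv = np.asarray(sv_volume.sv, dtype=float)
    n_slow, n_depth, n_fast = sv.shape
    pz = sv_volume.spacing[1]
    (top, bot), numeric = _slab_maps(layer_model, slab, (n_slow, n_fast))
    for m in (top, bot):
        if m.shape != (n_slow, n_fast):
            raise ValueError(
                f"boundary map shape {m.shape} does not match lateral grid "
                f"{(n_slow, n_fast)}")

    # voxel z-centers are (iz + 0.5) * pz; select centers in [top, bot)
    i0 = np.ceil(top / pz - 0.5).astype(int)
    i1 = np.ceil(bot / pz - 0.5).astype(int)
    if numeric and np.allclose(top, bot):
        # an exactly-degenerate numeric slab selects the nearest plane
        i0 = np.clip(np.round(top / pz - 0.5), 0, n_depth - 1).astype(int)
        yi, xi = np.ogrid[:n_slow, :n_fast]
        out = sv[yi, i0, xi]
        return EnFaceImage(pixels=out, pixel_um=sv_volume.spacing[2],
                           slab=f"{slab[0]}..{slab[1]} (plane)")
    i0 = np.clip(i0, 0, n_depth)
    i1 = np.clip(i1, 0, n_depth)
    count = i1 - i0
    if np.any(count <= 0):
        bad = np.argwhere(count <= 0)
        head = ", ".join(f"(slow={y}, fast={x})" for y, x in bad[:10])
        raise ValueError(
            f"empty slab at {bad.shape[0]} lateral positions: {head}"
            + ("…" if bad.shape[0] > 10 else ""))

    if reducer == "mean":
        cs = np.concatenate(
            [np.zeros((n_slow, 1, n_fast)), np.cumsum(sv, axis=1)], axis=1)
        yi, xi = np.ogrid[:n_slow, :n_fast]
        total = cs[yi, i1, xi] - cs[yi, i0, xi]
        out = total / count
    else:
        zi = np.arange(n_depth)[None, :, None]
        inside = (zi >= i0[:, None, :]) & (zi < i1[:, None, :])
        out = np.where(inside, sv, -np.inf).max(axis=1)

    slab_desc = f"{slab[0]}..{slab[1]} ({reducer})"
    return EnFaceImage(pixels=out, pixel_um=sv_volume.spacing[2],
                       slab=slab_desc)


def crop_enface(enface: EnFaceImage, crop_um: float = 636.5) -> EnFaceImage:
    """Centered square crop of ``crop_um`` per side (floor convention).

    The output is ``floor(crop_um / pixel_um)`` pixels per side, taken
    from a centered window whose start index is floored; pixel pitch is
    preserved, so cropping is idempotent.
    """
    img = enface.pixels
    n = int(np.floor(crop_um / enface.pixel_um))
    if n > min(img.shape):
        raise ValueError(
            f"crop of {n} px exceeds image of shape {img.shape}")
    y0 = (img.shape[0] - n) // 2
    x0 = (img.shape[1] - n) // 2
    return replace(enface, pixels=img[y0:y0 + n, x0:x0 + n].copy())
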