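"""Beam optics and reduced-eye scan geometry.

Closed-form calibration converting swept-source OCT device parameters
(center wavelength, bandwidth, pupil beam diameter) and per-subject eye
length into the physical scales the rest of the pipeline consumes: axial
resolution (coherence length in tissue), lateral resolution (focal-spot
FWHM on the retina), and the lateral field of view traced by an angular
scan on a reduced (single refracting surface) eye.

All functions are pure; units are stated per argument (nm for
wavelengths, mm for macroscopic lengths, μm for results at retinal
scale).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

__all__ = [
    "BeamOptics",
    "ScanGeometry",
    "coherence_length",
    "lateral_fwhm",
    "focal_waist",
    "scan_arc_length",
    "GULLSTRAND_LEGRAND_FOCAL_LENGTH_MM",
    "GULLSTRAND_LEGRAND_INDEX",
]

# Gullstrand–Le Grand full theoretical eye: total power 59.94 D with
# image-space (vitreous) index 1.336 gives a posterior focal length of
# n'/P ≈ 22.29 mm. These are the documented defaults used when
# estimating the retinal spot size from the pupil beam.
GULLSTRAND_LEGRAND_FOCAL_LENGTH_MM = 22.29
GULLSTRAND_LEGRAND_INDEX = 1.336

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0):
            raise ValueError(f"{name} must be > 0, got {v!r}")


def coherence_length(lambda0_nm: float, delta_lambda_nm: float,
                     n_tissue: float = 1.33) -> float:
    """Axial resolution (coherence length) in tissue, in μm.

    For a Gaussian source spectrum the round-trip coherence length is
    ``(2 ln 2 / π) · λ0² / Δλ``, divided by the tissue refractive index
    to express it in optical-path-corrected tissue depth.

    Parameters
    ----------
    lambda0_nm : center wavelength in nm.
    delta_lambda_nm : FWHM spectral bandwidth in nm.
    n_tissue : group refractive index of the medium (default 1.33,
        vitreous/retina).
    """
    _require_positive(lambda0_nm=lambda0_nm, delta_lambda_nm=delta_lambda_nm,
                      n_tissue=n_tissue)
    lc_nm = (2.0 * math.log(2.0) / math.pi) * lambda0_nm ** 2 / (
        delta_lambda_nm * n_tissue)
    return lc_nm * 1e-3


def lateral_fwhm(omega0_um: float) -> float:
    """FWHM of a Gaussian focal spot with 1/e² intensity radius ω0 (μm).

    FWHM = √(2 ln 2) · ω0 ≈ 1.1774 · ω0.
    """
    _require_positive(omega0_um=omega0_um)
    return _SQRT_2LN2 * omega0_um


def focal_waist(pupil_beam_diameter_mm: float, lambda0_nm: float,
                eye_focal_length_mm: float = GULLSTRAND_LEGRAND_FOCAL_LENGTH_MM,
                n_media: float = GULLSTRAND_LEGRAND_INDEX) -> float:
    """Gaussian-optics focal waist radius ω0 on the retina, in μm.

    A collimated Gaussian beam of 1/e² radius ``w = diameter/2`` at the
    pupil, focused by an eye of posterior focal length ``f`` in a medium
    of index ``n``, reaches a diffraction-limited waist

        ω0 = (λ0 / n) · f / (π · w).

    The defaults are the Gullstrand–Le Grand theoretical-eye constants
    documented at module level.
    """
    _require_positive(pupil_beam_diameter_mm=pupil_beam_diameter_mm,
                      lambda0_nm=lambda0_nm,
                      eye_focal_length_mm=eye_focal_length_mm,
                      n_media=n_media)
    w_pupil_um = pupil_beam_diameter_mm * 1e3 / 2.0
    lambda_um = lambda0_nm * 1e-3 / n_media
    f_um = eye_focal_length_mm * 1e3
    return lambda_um * f_um / (math.pi * w_pupil_um)


def scan_arc_length(scan_half_angle_deg: float, eye_length_mm: float,
                    n_media: float = 1.33) -> float:
    """Lateral scan extent on the retina as an arc length, in mm.

    The beam pivots at the cornea of a reduced eye: the external scan
    half-angle θ refracts to θ' = asin(sin θ / n) (Snell), and the spot
    traces an arc of radius equal to the eye length, so the full scan
    extent is 2 · L · θ' with θ' in radians.
    """
    if not (0 <= scan_half_angle_deg < 90):
        raise ValueError("scan_half_angle_deg must be in [0, 90)")
    _require_positive(eye_length_mm=eye_length_mm, n_media=n_media)
    s = math.sin(math.radians(scan_half_angle_deg)) / n_media
    if s > 1:
        raise ValueError("sin(theta)/n exceeds 1: total internal geometry")
    theta_internal = math.asin(s)
    return 2.0 * eye_length_mm * theta_internal


@dataclass(frozen=True)
class BeamOptics:
    """Device beam parameters and the derived resolutions.

    ``lateral_fwhm_um`` and ``coherence_length_um`` are derived from the
    primary fields at construction via :func:`derive`.
    """

    lambda0_nm: float = 1060.0
    delta_lambda_nm: float = 61.5
    n_tissue: float = 1.33
    pupil_beam_diameter_mm: float = 1.5
    omega0_um: float = 7.3
    lateral_fwhm_um: float = field(default=0.0)
    coherence_length_um: float = field(default=0.0)

    @classmethod
    def derive(cls, lambda0_nm: float = 1060.0, delta_lambda_nm: float = 61.5,
               n_tissue: float = 1.33, pupil_beam_diameter_mm: float = 1.5,
               omega0_um: float | None = None) -> "BeamOptics":
        """Build with resolutions computed from the closed forms.

        If ``omega0_um`` is None it is estimated from the pupil beam via
        :func:`focal_waist`.
        """
        w0 = (focal_waist(pupil_beam_diameter_mm, lambda0_nm)
              if omega0_um is None else omega0_um)
        return cls(
            lambda0_nm=lambda0_nm, delta_lambda_nm=delta_lambda_nm,
            n_tissue=n_tissue,
            pupil_beam_diameter_mm=pupil_beam_diameter_mm,
            omega0_um=w0,
            lateral_fwhm_um=lateral_fwhm(w0),
            coherence_length_um=coherence_length(
                lambda0_nm, delta_lambda_nm, n_tissue),
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "BeamOptics":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class ScanGeometry:
    """Sampling grid and physical scale of one angiography volume.

    The lateral field of view follows from the scan angle and the
    subject's eye length through :func:`scan_arc_length`; the lateral
    pixel pitch is ``fov_um / n_fast``. Depth sampling is a declared
    default (it only needs to cover the layered retina).
    """

    ascan_rate_hz: float = 100_000.0
    n_fast: int = 300
    n_slow: int = 300
    n_repeats: int = 3
    fov_um: float = 1000.0
    eye_length_mm: float = 24.0
    n_depth: int = 160
    depth_pixel_um: float = 2.0

    @property
    def pixel_um(self) -> float:
        return self.fov_um / self.n_fast

    @property
    def pixel_slow_um(self) -> float:
        return self.fov_um / self.n_slow

    @property
    def depth_um(self) -> float:
        return self.n_depth * self.depth_pixel_um

    @classmethod
    def from_scan_angle(cls, scan_half_angle_deg: float,
                        eye_length_mm: float = 24.0, n_media: float = 1.33,
                        **kwargs) -> "ScanGeometry":
        fov_mm = scan_arc_length(scan_half_angle_deg, eye_length_mm, n_media)
        return cls(fov_um=fov_mm * 1e3, eye_length_mm=eye_length_mm, **kwargs)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScanGeometry":
        return cls(**json.loads(text))
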