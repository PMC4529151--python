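"""End-to-end orchestration: simulate → angiogram → segment → quantify →
stats, driven by a validated configuration and fully seeded.

For every configured (subject, eye, region) the pipeline generates a
ground-truth capillary network whose spacing is linked to a per-eye RNFL
thickness, renders the repeat-resolved OCT volume (and optionally a
histology-style image of the same truth), runs the speckle-variance
angiography chain, segments the layers, measures density/ICD/diameter on
the cropped en-face image, and finally fits the mixed models on the
collected study table. Every run writes a manifest with the seed,
parameter hash and artifact checksums; the same config + seed reproduces
byte-identical CSV output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import angiography as ang
from . import io as rio
from . import morphometry as morph
from . import phantom
from . import segmentation as seg
from . import stats as st
from .optics import ScanGeometry

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("rpcsvoct")

ALL_STAGES = ("simulate", "angiogram", "segment", "quantify", "stats")

_DEFAULTS: dict = {
    "seed": None,          # required
    "out_dir": None,       # required
    "stages": list(ALL_STAGES),
    "study": {
        "n_subjects": 9,
        "n_eyes": 16,
        "regions": list(phantom.REGIONS),
        "spacing_means_um": dict(phantom.DEFAULT_ICD_MEANS_UM),
        "spacing_eye_sd_um": 1.5,
        "rnfl_means_um": dict(phantom.DEFAULT_RNFL_MEANS_UM),
        "rnfl_eye_sd_um": 10.0,
        "rnfl_slope": -0.065,
        "diameter_um": 5.0,
        "include_histology": True,
    },
    "grid": {
        "n_fast": 120, "n_slow": 120, "n_depth": 150,
        "n_repeats": 3, "fov_um": 700.0, "depth_pixel_um": 2.0,
    },
    "speckle": {
        "static_scale": 1.0, "flow_decorrelation": 0.9,
        "noise_floor": 0.02, "bulk_motion_prob": 0.0, "bulk_motion_px": 8,
    },
    "processing": {
        "sv_percentile": 75.0, "k_mad": 3.0, "offset_um": "auto",
        "n_bscans": 10, "crop_um": 636.5,
        "lateral_fwhm_um": 8.59, "axial_fwhm_um": 6.06,
        "histology_pixel_um": 1.0, "histology_psf_um": 0.5,
        "measure_diameters": True,
    },
    "stats": {"transform": "none", "p_method": "wald"},
}

_REQUIRED = ("seed", "out_dir")


def _merge_validated(defaults: dict, given: dict, path: str = "") -> dict:
    out = {}
    for key, value in given.items():
        if key not in defaults:
            raise KeyError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise TypeError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_validated(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    for key, value in defaults.items():
        if key not in out:
            out[key] = ({k: v for k, v in value.items()}
                        if isinstance(value, dict) else value)
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (schema-checked, unknown keys
    rejected, seed mandatory and recorded in every output)."""

    seed: int
    out_dir: str
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    study: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    speckle: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        merged = _merge_validated(_DEFAULTS, d)
        for key in _REQUIRED:
            if merged.get(key) is None:
                raise KeyError(f"missing required config key {key!r}")
        unknown = [s for s in merged["stages"] if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {ALL_STAGES}")
        return cls(**merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def params_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _eye_list(n_subjects: int, n_eyes: int):
    if not (2 <= n_subjects <= n_eyes <= 2 * n_subjects):
        raise ValueError("need 2 <= n_subjects <= n_eyes <= 2*n_subjects")
    eyes = []
    n_two = n_eyes - n_subjects
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for eye in (("OD", "OS") if s < n_two else ("OD",)):
            eyes.append((subject, eye))
    return eyes


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest.

    Raises RuntimeError naming the failing stage; artifacts written up
    to the failure are preserved on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study, grid = config.study, config.grid
    proc, spk = config.processing, config.speckle
    regions = list(study["regions"])
    eyes = _eye_list(study["n_subjects"], study["n_eyes"])
    geometry = ScanGeometry(
        n_fast=grid["n_fast"], n_slow=grid["n_slow"],
        n_repeats=grid["n_repeats"], fov_um=grid["fov_um"],
        n_depth=grid["n_depth"], depth_pixel_um=grid["depth_pixel_um"])

    master = np.random.default_rng(config.seed)
    rnfl_bar = float(np.mean([study["rnfl_means_um"][r] for r in regions]))
    # the layered truth must fit the depth grid: ILM at 40 μm, 60 μm of
    # inner retina below the RNFL, a 15 μm RPE band and a 10 μm margin
    rnfl_max = geometry.depth_um - 40.0 - 60.0 - 15.0 - 10.0
    if rnfl_max < 50.0:
        raise ValueError(
            f"depth grid of {geometry.depth_um:.0f} μm cannot hold the "
            f"layered retina; increase n_depth or depth_pixel_um")
    records = []
    stage = "simulate"
    try:
        for subject, eye in eyes:
            for region in regions:
                sub_seed = int(master.integers(0, 2 ** 31 - 1))
                rng = np.random.default_rng(sub_seed)
                rnfl_true = (study["rnfl_means_um"][region]
                             + rng.normal(0.0, study["rnfl_eye_sd_um"]))
                rnfl_true = float(np.clip(rnfl_true, 30.0, rnfl_max))
                spacing = (study["spacing_means_um"][region]
                           + study["rnfl_slope"] * (rnfl_true - rnfl_bar)
                           + rng.normal(0.0, study["spacing_eye_sd_um"]))
                spacing = float(max(spacing, study["diameter_um"] * 2.5))
                ws = out / f"{subject}_{eye}" / region
                ws.mkdir(parents=True, exist_ok=True)

                stage = "simulate"
                n_caps = phantom.max_capillaries(
                    region, spacing, study["diameter_um"], grid["fov_um"])
                net = phantom.generate_network(
                    region, spacing_um=spacing,
                    diameter_um=study["diameter_um"],
                    n_capillaries=n_caps, waviness=0.0, seed=sub_seed,
                    fov_um=grid["fov_um"],
                    depth_um=40.0 + 0.5 * rnfl_true)
                layers = phantom.generate_layers(
                    geometry, ilm_um=40.0, rnfl_um=rnfl_true,
                    rpe_um=40.0 + rnfl_true + 60.0)
                params = phantom.SpeckleParams(
                    n_repeats=grid["n_repeats"], seed=sub_seed, **spk)
                volume, truth = phantom.render_oct_volume(
                    net, layers, geometry, params,
                    lateral_fwhm_um=proc["lateral_fwhm_um"],
                    axial_fwhm_um=proc["axial_fwhm_um"])
                rio.write_network(ws / "network.json", net)
                rio.write_volume(ws / "volume.tif", volume,
                                 extra={"seed": sub_seed,
                                        "params_hash": config.params_hash()})
                rio.write_mask(ws / "flow_mask.tif",
                               truth["flow_mask"].reshape(-1,
                                                          geometry.n_fast))

                if "angiogram" not in config.stages:
                    continue
                stage = "angiogram"
                sv = ang.speckle_variance(volume)

                stage = "segment"
                if "segment" in config.stages:
                    ilm_map, rpe_map = seg.segment_boundaries(
                        volume.mean_intensity(),
                        depth_pixel_um=geometry.depth_pixel_um)
                    offset = proc["offset_um"]
                    if offset == "auto":
                        offset = seg.fit_rnfl_offset(
                            rpe_map, layers.rnfl_gcl_depth)
                    model = seg.build_layer_model(ilm_map, rpe_map,
                                                  float(offset))
                    rio.write_layer_model(ws / "layers.json", model)
                    thickness = seg.rnfl_thickness(
                        model, n_bscans=proc["n_bscans"]).mean_um
                else:
                    model = seg.LayerModel(
                        ilm=layers.ilm_depth, rnfl_gcl=layers.rnfl_gcl_depth,
                        rpe=layers.rpe_depth)
                    thickness = rnfl_true

                stage = "angiogram"
                enface = ang.enface_project(sv, model,
                                            slab=("ILM", "RNFL/GCL"))
                if spk["bulk_motion_prob"] > 0:
                    enface = ang.remove_streaks(enface, k_mad=proc["k_mad"])
                enface = ang.threshold_sv(enface,
                                          percentile=proc["sv_percentile"])
                enface = ang.crop_enface(enface, crop_um=proc["crop_um"])
                rio.write_enface(ws / "enface_sv.tif", enface,
                                 extra={"seed": sub_seed})

                if "quantify" not in config.stages:
                    continue
                stage = "quantify"
                res = morph.measure_enface(
                    enface, region_label=region, technique="svOCT",
                    angle_deg=(net.dominant_angle + 90.0) % 180.0,
                    measure_diameters=proc["measure_diameters"])
                records.append({
                    "subject": subject, "eye": eye, "region": region,
                    "technique": "svOCT", "icd_um": res.icd_um,
                    "density_per_100um": res.density_per_100um,
                    "diameter_um": res.mean_diameter_um,
                    "rnfl_um": thickness,
                })
                if study["include_histology"]:
                    hist = phantom.render_histology(
                        net, pixel_um=proc["histology_pixel_um"],
                        psf_fwhm_um=proc["histology_psf_um"])
                    hist = ang.crop_enface(hist, crop_um=proc["crop_um"])
                    rio.write_enface(ws / "enface_histology.tif", hist,
                                     extra={"seed": sub_seed})
                    hres = morph.measure_enface(
                        hist, region_label=region, technique="histology",
                        angle_deg=(net.dominant_angle + 90.0) % 180.0,
                        measure_diameters=proc["measure_diameters"])
                    records.append({
                        "subject": subject, "eye": eye, "region": region,
                        "technique": "histology", "icd_um": hres.icd_um,
                        "density_per_100um": hres.density_per_100um,
                        "diameter_um": hres.mean_diameter_um,
                        "rnfl_um": np.nan,
                    })
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage '{stage}' failed for {subject}/{eye}/{region} "
            f"(artifacts under {out} are preserved): {exc}") from exc

    manifest = {
        "seed": config.seed,
        "params_hash": config.params_hash(),
        "stages": list(config.stages),
        "n_records": len(records),
        "outputs": {},
    }
    if records:
        table = pd.DataFrame(records, columns=list(phantom.STUDY_COLUMNS))
        rio.write_records(out / "records.csv", table)
        manifest["outputs"]["records.csv"] = _sha256(out / "records.csv")

        if "stats" in config.stages:
            # each analysis degrades to an error note rather than
            # aborting the run: small configured studies can be
            # singular for the mixed models
            stats_out = {}
            sv_tab = table[table["technique"] == "svOCT"]
            try:
                fit = st.fit_icd_rnfl(sv_tab, **config.stats)
                stats_out["icd_rnfl"] = {
                    "slope": fit.slope, "se": fit.slope_se, "p": fit.slope_p,
                    "converged": fit.converged,
                }
            except Exception as exc:
                stats_out["icd_rnfl"] = {"error": str(exc)}
            region_set = set(table["region"])
            if (set(phantom.ARCUATE_REGIONS) <= region_set
                    and region_set - set(phantom.ARCUATE_REGIONS)):
                try:
                    est, p = st.compare_arcuate(
                        table, p_method=config.stats.get("p_method", "wald"))
                    stats_out["arcuate_vs_other"] = {"estimate": est, "p": p}
                except Exception as exc:
                    stats_out["arcuate_vs_other"] = {"error": str(exc)}
            if table["technique"].nunique() > 1:
                try:
                    tech = st.compare_techniques(
                        table, p_method=config.stats.get("p_method", "wald"))
                    stats_out["techniques"] = tech.to_dict(orient="records")
                except Exception as exc:
                    stats_out["techniques"] = {"error": str(exc)}
            (out / "stats.json").write_text(
                json.dumps(stats_out, indent=2, default=float))
            manifest["outputs"]["stats.json"] = _sha256(out / "stats.json")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d records, manifest at %s",
             len(records), out / "manifest.json")
    return manifest
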