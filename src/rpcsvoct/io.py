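"""Readers and writers for the pipeline's artifact formats.

Volumes are multi-page TIFF (pages ordered repeat-major: all slow-axis
frames of repeat 0, then repeat 1, …) with a mandatory JSON sidecar
carrying the physical spacing and grid; en-face images are single-page
float TIFF with the same sidecar convention; study tables are CSV
(pandas, full-precision floats); networks and layer models are JSON.
Reading a volume without its sidecar is an error — spacing is never
silently defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .angiography import EnFaceImage, OCTVolume
from .phantom import CapillaryNetwork
from .segmentation import LayerModel

__all__ = [
    "write_volume", "read_volume",
    "write_enface", "read_enface",
    "write_records", "read_records",
    "write_network", "read_network",
    "write_mask", "read_mask",
    "write_layer_model", "read_layer_model",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def _write_sidecar(path, payload: dict) -> None:
    sidecar_path(path).write_text(json.dumps(payload, indent=2))


def _read_sidecar(path) -> dict:
    sc = sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc}: spacing metadata is required and is "
            f"never defaulted")
    return json.loads(sc.read_text())


def write_volume(path, volume: OCTVolume, extra: dict | None = None) -> None:
    """Multi-page TIFF (pages = repeat-major slow-axis frames) + JSON
    sidecar with spacing, grid dimensions and any extra provenance."""
    n_rep, n_slow, n_depth, n_fast = volume.intensity.shape
    pages = volume.intensity.reshape(n_rep * n_slow, n_depth, n_fast)
    tifffile.imwrite(path, pages.astype(np.float32))
    meta = {
        "kind": "oct_volume",
        "n_repeats": n_rep, "n_slow": n_slow,
        "n_depth": n_depth, "n_fast": n_fast,
        "pixel_um": {"slow": volume.spacing[0], "depth": volume.spacing[1],
                     "fast": volume.spacing[2]},
        "page_order": "repeat-major",
    }
    meta.update(extra or {})
    _write_sidecar(path, meta)


def read_volume(path) -> OCTVolume:
    meta = _read_sidecar(path)
    pages = tifffile.imread(path)
    expected = (meta["n_repeats"] * meta["n_slow"],
                meta["n_depth"], meta["n_fast"])
    if pages.shape != expected:
        raise ValueError(
            f"volume shape mismatch: sidecar expects pages {expected}, "
            f"found {pages.shape}")
    intensity = pages.reshape(meta["n_repeats"], meta["n_slow"],
                              meta["n_depth"], meta["n_fast"])
    sp = meta["pixel_um"]
    return OCTVolume(intensity=intensity,
                     spacing=(sp["slow"], sp["depth"], sp["fast"]))


def write_enface(path, enface: EnFaceImage, extra: dict | None = None) -> None:
    tifffile.imwrite(path, np.asarray(enface.pixels, dtype=np.float32))
    meta = {"kind": "enface", "pixel_um": enface.pixel_um,
            "slab": enface.slab}
    meta.update(extra or {})
    _write_sidecar(path, meta)


def read_enface(path) -> EnFaceImage:
    meta = _read_sidecar(path)
    pixels = tifffile.imread(path)
    return EnFaceImage(pixels=pixels, pixel_um=meta["pixel_um"],
                       slab=meta.get("slab", ""))


def write_mask(path, mask: np.ndarray) -> None:
    """Boolean mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_records(path, records: pd.DataFrame) -> None:
    """CSV with full-precision floats (shortest round-tripping repr)."""
    records.to_csv(path, index=False)


def read_records(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_network(path, network: CapillaryNetwork) -> None:
    Path(path).write_text(json.dumps(network.to_dict(), indent=2))


def read_network(path) -> CapillaryNetwork:
    return CapillaryNetwork.from_dict(json.loads(Path(path).read_text()))


def write_layer_model(path, model: LayerModel) -> None:
    payload = {
        "kind": "layer_model",
        "offset_um": model.offset_um,
        "ilm_um": model.ilm.tolist(),
        "rnfl_gcl_um": model.rnfl_gcl.tolist(),
        "rpe_um": model.rpe.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_layer_model(path) -> LayerModel:
    d = json.loads(Path(path).read_text())
    return LayerModel(ilm=np.asarray(d["ilm_um"]),
                      rnfl_gcl=np.asarray(d["rnfl_gcl_um"]),
                      rpe=np.asarray(d["rpe_um"]),
                      offset_um=d["offset_um"])
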