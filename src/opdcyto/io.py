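"""Standard-format I/O: 8-bit interferogram images, float-TIFF OPD maps
with sidecar metadata, CSV feature tables and JSON model/result files."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from opdcyto.reconstruction import Interferogram, OPDMap

FEATURE_COLUMNS = ["cell_id", "sample_id", "area_um2", "perimeter_um",
                   "avg_opd_nm", "dry_mass_pg", "label"]


def write_interferogram(ig: Interferogram, path: str | Path) -> None:
    """Write the 8-bit raster (BMP/PNG/TIFF by extension) plus a sidecar
    JSON with the acquisition metadata."""
    path = Path(path)
    iio.imwrite(path, ig.pixels)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "pixel_pitch_camera_um": ig.pixel_pitch_camera_um,
        "magnification": ig.magnification,
        "wavelength_nm": ig.wavelength_nm,
    }, indent=2) + "\n")


def read_interferogram(
    path: str | Path,
    pixel_pitch_camera_um: float | None = None,
    magnification: float | None = None,
    wavelength_nm: float | None = None,
) -> Interferogram:
    """Read an 8-bit interferogram; metadata from the sidecar JSON when
    present, overridable by arguments."""
    path = Path(path)
    pixels = np.asarray(iio.imread(path))
    if pixels.ndim == 3:  # collapse accidental RGB
        pixels = pixels[..., 0]
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    kwargs = {}
    for key, override in (
        ("pixel_pitch_camera_um", pixel_pitch_camera_um),
        ("magnification", magnification),
        ("wavelength_nm", wavelength_nm),
    ):
        if override is not None:
            kwargs[key] = override
        elif key in meta:
            kwargs[key] = meta[key]
    return Interferogram(pixels.astype(np.uint8), **kwargs)


def write_opd_map(opd: OPDMap, path: str | Path) -> None:
    """Write an OPD map as 32-bit float TIFF (nm) with a sidecar JSON
    recording the object-plane pixel pitch and provenance."""
    path = Path(path)
    tifffile.imwrite(path, opd.values.astype(np.float32))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "unit": "nm",
        "object_pixel_pitch_um": opd.object_pixel_pitch_um,
        "provenance": opd.provenance,
    }, indent=2) + "\n")


def read_opd_map(path: str | Path,
                 object_pixel_pitch_um: float | None = None) -> OPDMap:
    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=np.float64)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    pitch = object_pixel_pitch_um or meta.get("object_pixel_pitch_um")
    if pitch is None:
        raise ValueError(f"pixel pitch unknown for {path} (no sidecar)")
    return OPDMap(values, pitch, meta.get("provenance", "reconstructed"))


def write_features_csv(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in FEATURE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False)


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
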