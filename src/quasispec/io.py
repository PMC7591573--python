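"""Readers and writers for images, spectral cubes, spectra and configs.

Raw images are read bit-exactly (no rescaling, no gamma): the method
requires the camera primary signal straight after analog-to-digital
conversion.  Spectral cubes travel as multi-page TIFF (one page per
wavelength) with a sidecar CSV listing the grid wavelengths; spectra and
traces are plain CSV.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .reconstruction import SolverConfig
from .spectra import (ChannelImage, EffectiveLight, Spectrum,
                      TransparencyField, WavelengthGrid)

__all__ = ["read_image", "write_image", "read_spectrum_csv",
           "write_spectrum_csv", "write_cube", "read_cube",
           "load_config", "provenance_record"]


def read_image(path) -> ChannelImage:
    """Read a TIFF/PNG image with intensities preserved bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    elif suffix == ".png":
        import imageio.v3 as iio
        arr = iio.imread(str(path))
    else:
        raise ValueError(f"unsupported image dialect: {suffix!r} "
                         "(expected TIFF or PNG)")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    elif np.issubdtype(arr.dtype, np.integer):
        depth = int(np.ceil(np.log2(max(int(arr.max()), 1) + 1)))
    else:
        depth = 16
    return ChannelImage(np.asarray(arr, dtype=float), bit_depth=depth)


def write_image(path, image: ChannelImage) -> None:
    path = Path(path)
    dtype = np.uint8 if image.bit_depth <= 8 else np.uint16
    arr = np.clip(np.round(image.data), 0, image.max_count).astype(dtype)
    if arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    elif path.suffix.lower() == ".png":
        import imageio.v3 as iio
        iio.imwrite(str(path), arr)
    else:
        raise ValueError(f"unsupported image dialect: {path.suffix!r}")


def read_spectrum_csv(path, grid: WavelengthGrid):
    """Read a wavelength_nm + value(s) CSV, resampled to the working grid.

    One value column gives a Spectrum, several give an EffectiveLight.
    Grid points outside the file's wavelength range are zero-filled with a
    warning; non-monotone wavelengths are an error.
    """
    df = pd.read_csv(path)
    lam = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(lam) > 0):
        raise ValueError("wavelength column must be strictly increasing")
    if grid.lam_min < lam[0] - 1e-9 or grid.lam_max > lam[-1] + 1e-9:
        warnings.warn("grid extends past the file's wavelength range; "
                      "out-of-range points filled with 0")
    cols = df.columns[1:]
    values = np.stack([
        np.interp(grid.wavelengths, lam, df[c].to_numpy(dtype=float),
                  left=0.0, right=0.0)
        for c in cols])
    if len(cols) == 1:
        return Spectrum(grid, values[0], name=str(cols[0]))
    return EffectiveLight(grid, values, tuple(str(c) for c in cols))


def write_spectrum_csv(path, obj: Spectrum | EffectiveLight) -> None:
    if isinstance(obj, Spectrum):
        df = pd.DataFrame({"wavelength_nm": obj.grid.wavelengths,
                           obj.name or "value": obj.values})
    else:
        df = pd.DataFrame({"wavelength_nm": obj.grid.wavelengths})
        for c, label in enumerate(obj.channels):
            df[label] = obj.values[c]
    df.to_csv(path, index=False)


def write_cube(path, field: TransparencyField) -> None:
    """Multi-page float TIFF (one page per wavelength) + grid sidecar CSV."""
    path = Path(path)
    pages = np.moveaxis(field.data, 2, 0).astype(np.float32)
    tifffile.imwrite(str(path), pages)
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    pd.DataFrame({"wavelength_nm": field.grid.wavelengths}
                 ).to_csv(sidecar, index=False)
    mask_path = path.with_suffix(path.suffix + ".valid.csv")
    np.savetxt(mask_path, field.valid.astype(int), fmt="%d", delimiter=",")


def read_cube(path) -> TransparencyField:
    path = Path(path)
    pages = tifffile.imread(str(path))
    sidecar = path.with_suffix(path.suffix + ".wavelengths.csv")
    lam = pd.read_csv(sidecar)["wavelength_nm"].to_numpy(dtype=float)
    grid = WavelengthGrid(lam)
    data = np.moveaxis(np.asarray(pages, dtype=float), 0, 2)
    mask_path = path.with_suffix(path.suffix + ".valid.csv")
    valid = None
    if mask_path.exists():
        valid = np.loadtxt(mask_path, dtype=int, delimiter=",").astype(bool)
    return TransparencyField(grid, np.clip(data, 0.0, 1.0), valid=valid)


def load_config(path) -> SolverConfig:
    """SolverConfig from a YAML/JSON file mirroring its fields."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(SolverConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SolverConfig(**raw)


def provenance_record(config: SolverConfig, seed: int) -> dict:
    """Reproducibility stamp written next to every CLI run's outputs."""
    from . import __version__
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {"package": "quasispec", "version": __version__,
            "seed": seed, "config": cfg, "config_hash": digest}
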