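"""Reading and writing hyperspectral cubes.

Three dialects are supported:

``envi``
    A raw binary cube next to a plain-text ``.hdr`` header (the de-facto
    exchange format of push-broom instruments).  BSQ and BIL interleaves
    are supported; BIP is rejected because line-scan systems do not
    produce it.  The wavelength list in the header is mandatory.
``tiff-stack``
    One page per band; grid and metadata stored as JSON in the image
    description tag.
``hdf5``
    A single ``data`` dataset with wavelength/kind attributes.

Binary masks travel as single-band ENVI images of 0/1 via
:func:`write_mask` / :func:`read_mask` (these bypass the ``Hypercube``
container, which requires at least 3 bands).
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np

from .hypercube import Hypercube, WavelengthGrid

__all__ = [
    "read_cube",
    "write_cube",
    "read_spectrum",
    "write_spectrum",
    "read_mask",
    "write_mask",
]

DIALECTS = ("envi", "tiff-stack", "hdf5")

# ENVI numeric data-type codes
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_TO_ENVI = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def read_cube(path: str | os.PathLike, dialect: str = "envi") -> Hypercube:
    """Read a hyperspectral cube; the wavelength grid must be present."""
    path = Path(path)
    if dialect == "envi":
        return _read_envi(path)
    if dialect == "tiff-stack":
        return _read_tiff(path)
    if dialect == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def write_cube(
    cube: Hypercube,
    path: str | os.PathLike,
    dialect: str = "envi",
    interleave: str = "bsq",
) -> Path:
    """Write ``cube`` so that :func:`read_cube` round-trips it bitwise.

    Data are stored as float64; the wavelength grid is written to full
    precision.  Returns the data-file path.
    """
    WavelengthGrid(cube.grid.values)  # re-validate: arrays are mutable
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "envi":
        return _write_envi(cube, path, interleave)
    if dialect == "tiff-stack":
        return _write_tiff(cube, path)
    if dialect == "hdf5":
        return _write_hdf5(cube, path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# ENVI


def _header_path(data_path: Path) -> Path:
    for cand in (data_path.with_suffix(data_path.suffix + ".hdr"),
                 data_path.with_suffix(".hdr")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"no ENVI header found next to {data_path}")


def _parse_envi_header(text: str) -> dict:
    """Parse ``key = value`` pairs; ``{...}`` values may span lines."""
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    first = next(lines, "")
    if first.strip() != "ENVI":
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    for line in lines:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            for cont in lines:
                parts.append(cont.strip())
                if cont.strip().endswith("}"):
                    break
            value = " ".join(parts)
        fields[key] = value
    return fields


def _read_envi(data_path: Path) -> Hypercube:
    hdr = _parse_envi_header(_header_path(data_path).read_text())
    try:
        samples = int(hdr["samples"])
        lines_n = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
        interleave = hdr["interleave"].lower()
    except KeyError as exc:
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if "wavelength" not in hdr:
        raise ValueError(
            "ENVI header has no 'wavelength' entry; the wavelength grid is "
            "mandatory for this pipeline"
        )
    wavelengths = np.array(
        [float(v) for v in hdr["wavelength"].strip("{} ").split(",") if v.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if interleave == "bip":
        raise ValueError(
            "BIP interleave is not supported (line-scan cubes are BSQ or BIL); "
            "convert to BSQ first"
        )
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unknown interleave {interleave!r}")

    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    offset = int(hdr.get("header offset", "0"))
    expected = lines_n * samples * bands * dtype.itemsize + offset
    actual = data_path.stat().st_size
    if actual != expected:
        raise ValueError(
            f"ENVI data file size mismatch: header implies {expected} bytes "
            f"({lines_n}x{samples}x{bands} {dtype.name}), file has {actual}"
        )
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    if interleave == "bsq":
        data = raw.reshape(bands, lines_n, samples).transpose(1, 2, 0)
    else:  # bil
        data = raw.reshape(lines_n, bands, samples).transpose(0, 2, 1)

    kind = hdr.get("data kind", "reflectance")
    res = hdr.get("spatial resolution mm", None)
    return Hypercube(
        data=np.ascontiguousarray(data),
        grid=WavelengthGrid(wavelengths),
        kind=kind,
        spatial_resolution_mm_per_pixel=float(res) if res is not None else None,
    )


def _write_envi(cube: Hypercube, path: Path, interleave: str) -> Path:
    interleave = interleave.lower()
    if interleave == "bip":
        raise ValueError("BIP interleave is not supported; use bsq or bil")
    if interleave not in ("bsq", "bil"):
        raise ValueError(f"unknown interleave {interleave!r}")
    data = np.asarray(cube.data, dtype=np.float64)
    ny, nx, nb = data.shape
    if interleave == "bsq":
        ordered = data.transpose(2, 0, 1)
    else:
        ordered = data.transpose(0, 2, 1)
    ordered.astype("<f8").tofile(path)

    wl = ", ".join(repr(float(v)) for v in cube.grid.values)
    hdr_lines = [
        "ENVI",
        "description = {deglare hyperspectral cube}",
        f"samples = {nx}",
        f"lines = {ny}",
        f"bands = {nb}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_TO_ENVI[np.dtype('<f8')]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        f"data kind = {cube.kind}",
    ]
    if cube.spatial_resolution_mm_per_pixel is not None:
        hdr_lines.append(
            f"spatial resolution mm = {cube.spatial_resolution_mm_per_pixel!r}"
        )
    hdr_lines.append("wavelength = {" + wl + "}")
    path.with_suffix(path.suffix + ".hdr").write_text("\n".join(hdr_lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# TIFF stack


def _read_tiff(path: Path) -> Hypercube:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()  # (bands, Y, X)
        desc = tif.pages[0].description
    if not desc:
        raise ValueError("TIFF stack has no description tag with wavelength metadata")
    meta = json.loads(desc)
    if "wavelengths_nm" not in meta:
        raise ValueError("TIFF metadata lacks 'wavelengths_nm'; grid is mandatory")
    if data.ndim == 2:
        data = data[None]
    wavelengths = np.asarray(meta["wavelengths_nm"], dtype=float)
    if data.shape[0] != wavelengths.size:
        raise ValueError(
            f"TIFF has {data.shape[0]} pages but {wavelengths.size} wavelengths listed"
        )
    return Hypercube(
        data=data.transpose(1, 2, 0),
        grid=WavelengthGrid(wavelengths),
        kind=meta.get("kind", "reflectance"),
        spatial_resolution_mm_per_pixel=meta.get("spatial_resolution_mm_per_pixel"),
    )


def _write_tiff(cube: Hypercube, path: Path) -> Path:
    import tifffile

    meta = {
        "wavelengths_nm": [float(v) for v in cube.grid.values],
        "kind": cube.kind,
        "spatial_resolution_mm_per_pixel": cube.spatial_resolution_mm_per_pixel,
    }
    tifffile.imwrite(
        path,
        np.asarray(cube.data, dtype=np.float64).transpose(2, 0, 1),
        description=json.dumps(meta),
        photometric="minisblack",
    )
    return path


# ---------------------------------------------------------------------------
# HDF5


def _read_hdf5(path: Path) -> Hypercube:
    import h5py

    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError("HDF5 cube file has no 'data' dataset")
        dset = f["data"]
        if "wavelengths_nm" not in dset.attrs:
            raise ValueError("HDF5 dataset lacks 'wavelengths_nm'; grid is mandatory")
        data = dset[...]
        wavelengths = np.asarray(dset.attrs["wavelengths_nm"], dtype=float)
        kind = dset.attrs.get("kind", "reflectance")
        if isinstance(kind, bytes):
            kind = kind.decode()
        res = dset.attrs.get("spatial_resolution_mm_per_pixel", None)
    return Hypercube(
        data=data,
        grid=WavelengthGrid(wavelengths),
        kind=str(kind),
        spatial_resolution_mm_per_pixel=float(res) if res is not None else None,
    )


def _write_hdf5(cube: Hypercube, path: Path) -> Path:
    import h5py

    with h5py.File(path, "w") as f:
        dset = f.create_dataset("data", data=np.asarray(cube.data, dtype=np.float64))
        dset.attrs["wavelengths_nm"] = cube.grid.values
        dset.attrs["kind"] = cube.kind
        if cube.spatial_resolution_mm_per_pixel is not None:
            dset.attrs["spatial_resolution_mm_per_pixel"] = (
                cube.spatial_resolution_mm_per_pixel
            )
    return path


# ---------------------------------------------------------------------------
# Spectra and masks


def read_spectrum(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column text spectrum: wavelength (nm), value."""
    arr = np.loadtxt(path, comments="#")
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 2:
        raise ValueError("spectrum file must have exactly two columns: nm, value")
    return arr[:, 0], arr[:, 1]


def write_spectrum(
    path: str | os.PathLike, wavelengths_nm: np.ndarray, values: np.ndarray
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(
        path,
        np.column_stack([wavelengths_nm, values]),
        header="wavelength_nm value",
        fmt="%.10g",
    )
    return path


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> Path:
    """Write a 2-D boolean mask as a single-band 0/1 ENVI image."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D (Y, X)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mask.astype(np.uint8).tofile(path)
    ny, nx = mask.shape
    hdr = "\n".join(
        [
            "ENVI",
            "description = {deglare binary mask, 1 = flagged}",
            f"samples = {nx}",
            f"lines = {ny}",
            "bands = 1",
            "header offset = 0",
            "file type = ENVI Standard",
            "data type = 1",
            "interleave = bsq",
            "byte order = 0",
        ]
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr + "\n")
    return path


def read_mask(path: str | os.PathLike) -> np.ndarray:
    path = Path(path)
    hdr = _parse_envi_header(_header_path(path).read_text())
    ny, nx = int(hdr["lines"]), int(hdr["samples"])
    dtype = np.dtype(_ENVI_DTYPES[int(hdr.get("data type", "1"))])
    raw = np.fromfile(path, dtype=dtype)
    if raw.size != ny * nx:
        raise ValueError("mask file size does not match its header")
    return raw.reshape(ny, nx).astype(bool)
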