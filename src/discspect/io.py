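"""On-disk formats: ENVI image pairs, delimited matrices, HDF5 archives.

Cubes round-trip losslessly in float64. The ENVI reader/writer covers the
plain header + raw binary layout (BSQ/BIL/BIP interleaves, band names and
wavelengths carrying the wavenumber axis); masks are written as single-band
8-bit ENVI grids; maps as single-band ENVI or 32/64-bit TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .errors import FormatError, InvalidParameterError
from .spectra import HyperspectralImage, PixelMask, WavenumberAxis

__all__ = [
    "read_cube",
    "write_cube",
    "read_envi",
    "write_envi",
    "read_delimited",
    "write_delimited",
    "read_archive",
    "write_archive",
    "write_mask_envi",
    "write_map_tiff",
    "write_model_archive",
    "read_model_archive",
]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64,
                12: np.uint16}
_DTYPE_CODES = {np.dtype(np.float64): 5, np.dtype(np.float32): 4,
                np.dtype(np.uint8): 1}


# ---------------------------------------------------------------------------
# ENVI
# ---------------------------------------------------------------------------

def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise FormatError(f"{hdr_path}: missing ENVI magic on line 1")
    fields: dict[str, str] = {}
    lines = text.splitlines()
    i = 1
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            parts = [value]
            while i < len(lines):
                parts.append(lines[i].strip())
                if lines[i].strip().endswith("}"):
                    i += 1
                    break
                i += 1
            else:
                raise FormatError(f"{hdr_path}: unterminated brace list "
                                  f"for field {key!r}")
            value = " ".join(parts)
        fields[key] = value
    return fields


def _brace_list(value: str) -> list[str]:
    return [v.strip() for v in value.strip().lstrip("{").rstrip("}").split(",")
            if v.strip()]


def write_envi(image: HyperspectralImage, base_path: str | Path,
               interleave: str = "bsq") -> tuple[Path, Path]:
    """Write an image as `<base>.hdr` + `<base>.dat` (float64)."""
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise InvalidParameterError(f"unknown interleave {interleave!r}")
    base = Path(base_path)
    hdr, dat = base.with_suffix(".hdr"), base.with_suffix(".dat")
    cube = image.cube.astype(np.float64)
    nr, nc, nb = cube.shape
    if interleave == "bip":
        arr = cube                                  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(cube, (0, 2, 1))          # (lines, bands, samples)
    else:
        arr = np.transpose(cube, (2, 0, 1))          # (bands, lines, samples)
    names = ", ".join(f"{v:.2f}" for v in image.axis.values)
    header = [
        "ENVI",
        f"samples = {nc}",
        f"lines = {nr}",
        f"bands = {nb}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",
        f"interleave = {interleave}",
        "byte order = 0",
        f"band names = {{{names}}}",
        f"wavelength = {{{names}}}",
        "wavelength units = cm-1",
        f"derivative order = {image.derivative_order}",
    ]
    if image.pixel_size_um is not None:
        header.append(f"pixel size um = {image.pixel_size_um!r}")
    hdr.write_text("\n".join(header) + "\n")
    arr.tofile(dat)
    return hdr, dat


def read_envi(hdr_path: str | Path) -> HyperspectralImage:
    """Read an ENVI header + raw binary pair."""
    hdr = Path(hdr_path)
    fields = _parse_envi_header(hdr)
    try:
        nc = int(fields["samples"])
        nr = int(fields["lines"])
        nb = int(fields["bands"])
        interleave = fields.get("interleave", "bsq").lower()
        dtype_code = int(fields.get("data type", 5))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{hdr}: malformed header field ({exc})") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"{hdr}: unsupported data type {dtype_code}")
    dtype = _ENVI_DTYPES[dtype_code]
    offset = int(fields.get("header offset", 0))

    dat = None
    for suffix in (".dat", ".img", ".bin", ""):
        cand = hdr.with_suffix(suffix) if suffix else hdr.with_suffix("")
        if cand.exists() and cand != hdr:
            dat = cand
            break
    if dat is None:
        raise FormatError(f"no binary companion found for {hdr}")
    raw = np.fromfile(dat, dtype=dtype, offset=offset)
    expected = nr * nc * nb
    if raw.size != expected:
        raise FormatError(
            f"{dat}: has {raw.size} values at byte offset {offset}, header "
            f"promises {expected} (lines*samples*bands = {nr}*{nc}*{nb})"
        )
    if interleave == "bip":
        cube = raw.reshape(nr, nc, nb)
    elif interleave == "bil":
        cube = raw.reshape(nr, nb, nc).transpose(0, 2, 1)
    elif interleave == "bsq":
        cube = raw.reshape(nb, nr, nc).transpose(1, 2, 0)
    else:
        raise FormatError(f"{hdr}: unknown interleave {interleave!r}")

    wl_field = fields.get("wavelength") or fields.get("band names")
    if wl_field is None:
        raise FormatError(f"{hdr}: no wavelength/band-name axis")
    try:
        axis = WavenumberAxis(np.array([float(v) for v in _brace_list(wl_field)]))
    except ValueError as exc:
        raise FormatError(f"{hdr}: non-numeric band names") from exc
    if len(axis) != nb:
        raise FormatError(f"{hdr}: {len(axis)} band names for {nb} bands")
    deriv = int(fields.get("derivative order", 0))
    px = fields.get("pixel size um")
    return HyperspectralImage(axis, np.ascontiguousarray(cube, dtype=float),
                              derivative_order=deriv,
                              pixel_size_um=float(px) if px else None)


def write_mask_envi(mask: PixelMask, base_path: str | Path) -> tuple[Path, Path]:
    """Write a mask as a single-band 8-bit ENVI grid (1 = tissue)."""
    base = Path(base_path)
    hdr, dat = base.with_suffix(".hdr"), base.with_suffix(".dat")
    arr = mask.included.astype(np.uint8)
    hdr.write_text("\n".join([
        "ENVI",
        f"samples = {mask.n_cols}",
        f"lines = {mask.n_rows}",
        "bands = 1",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 1",
        "interleave = bsq",
        "byte order = 0",
        "band names = {tissue mask}",
    ]) + "\n")
    arr.tofile(dat)
    return hdr, dat


# ---------------------------------------------------------------------------
# Delimited matrix + axis file
# ---------------------------------------------------------------------------

def write_delimited(image: HyperspectralImage, matrix_path: str | Path,
                    axis_path: str | Path, delimiter: str = "\t") -> None:
    """Pixels x channels matrix with a one-column wavenumber axis file.

    The grid shape and derivative order ride along in a comment header so
    the cube round-trips without sidecar metadata.
    """
    matrix_path, axis_path = Path(matrix_path), Path(axis_path)
    header = (f"rows={image.n_rows} cols={image.n_cols} "
              f"derivative_order={image.derivative_order}")
    np.savetxt(matrix_path, image.as_matrix(), delimiter=delimiter,
               header=header, fmt="%.17g")
    np.savetxt(axis_path, image.axis.values, fmt="%.17g")


def read_delimited(matrix_path: str | Path, axis_path: str | Path,
                   delimiter: str = "\t",
                   shape: tuple[int, int] | None = None) -> HyperspectralImage:
    matrix_path, axis_path = Path(matrix_path), Path(axis_path)
    axis_vals = np.loadtxt(axis_path, ndmin=1)
    deriv = 0
    with open(matrix_path) as fh:
        first = fh.readline()
    if shape is None:
        if not first.startswith("#"):
            raise FormatError(
                f"{matrix_path}: line 1 lacks the shape comment header and "
                "no explicit shape was given"
            )
        meta = dict(tok.split("=") for tok in first[1:].split())
        shape = (int(meta["rows"]), int(meta["cols"]))
        deriv = int(meta.get("derivative_order", 0))
    mat = np.loadtxt(matrix_path, delimiter=delimiter, ndmin=2)
    if mat.shape[1] != axis_vals.size:
        raise FormatError(
            f"{matrix_path}: {mat.shape[1]} channels per pixel but the axis "
            f"file {axis_path} has {axis_vals.size} wavenumbers"
        )
    if mat.shape[0] != shape[0] * shape[1]:
        raise FormatError(
            f"{matrix_path}: {mat.shape[0]} pixel rows, expected "
            f"{shape[0]}*{shape[1]}"
        )
    return HyperspectralImage(WavenumberAxis(axis_vals),
                              mat.reshape(shape[0], shape[1], axis_vals.size),
                              derivative_order=deriv)


# ---------------------------------------------------------------------------
# HDF5 archives
# ---------------------------------------------------------------------------

def write_archive(image: HyperspectralImage, path: str | Path,
                  mask: PixelMask | None = None) -> None:
    """Single-file archive: /cube, /axis, optional /mask, metadata attrs."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=image.cube.astype(np.float64))
        f.create_dataset("axis", data=image.axis.values)
        f.attrs["derivative_order"] = image.derivative_order
        if image.pixel_size_um is not None:
            f.attrs["pixel_size_um"] = image.pixel_size_um
        if mask is not None:
            f.create_dataset("mask", data=mask.included.astype(np.uint8))


def read_archive(path: str | Path
                 ) -> tuple[HyperspectralImage, PixelMask | None]:
    with h5py.File(path, "r") as f:
        if "cube" not in f or "axis" not in f:
            raise FormatError(f"{path}: archive lacks /cube or /axis")
        image = HyperspectralImage(
            WavenumberAxis(f["axis"][:]),
            f["cube"][:],
            derivative_order=int(f.attrs.get("derivative_order", 0)),
            pixel_size_um=(float(f.attrs["pixel_size_um"])
                           if "pixel_size_um" in f.attrs else None),
        )
        mask = PixelMask(f["mask"][:].astype(bool)) if "mask" in f else None
    return image, mask


def write_model_archive(model, path: str | Path) -> None:
    """MCR model archive: /C, /S, /axis, /mask plus fit attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("C", data=model.C)
        f.create_dataset("S", data=model.S)
        f.create_dataset("lof_history", data=np.asarray(model.lof_history))
        if model.axis is not None:
            f.create_dataset("axis", data=model.axis.values)
        if model.mask is not None:
            f.create_dataset("mask", data=model.mask.included.astype(np.uint8))
        f.attrs["k"] = model.k
        f.attrs["iterations_run"] = model.iterations_run
        f.attrs["converged"] = model.converged
        f.attrs["init_method"] = model.init_method
        if model.region is not None:
            f.attrs["region"] = model.region


def read_model_archive(path: str | Path):
    from .mcr import MCRModel

    with h5py.File(path, "r") as f:
        model = MCRModel(
            k=int(f.attrs["k"]),
            C=f["C"][:],
            S=f["S"][:],
            iterations_run=int(f.attrs["iterations_run"]),
            lof_history=list(f["lof_history"][:]),
            converged=bool(f.attrs["converged"]),
            init_method=str(f.attrs["init_method"]),
            axis=WavenumberAxis(f["axis"][:]) if "axis" in f else None,
            mask=(PixelMask(f["mask"][:].astype(bool))
                  if "mask" in f else None),
            region=(tuple(float(v) for v in f.attrs["region"])
                    if "region" in f.attrs else None),
        )
    return model


# ---------------------------------------------------------------------------
# Maps and dispatch
# ---------------------------------------------------------------------------

def write_map_tiff(values: np.ndarray, path: str | Path) -> None:
    """Write a 2-D map as a float TIFF (NaN marks masked pixels)."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float64))


def write_cube(image: HyperspectralImage, path: str | Path,
               format: str = "hdf5", **kw) -> None:
    if format == "hdf5":
        write_archive(image, path, **kw)
    elif format == "envi":
        write_envi(image, path, **kw)
    elif format == "delimited":
        axis_path = kw.pop("axis_path", str(Path(path).with_suffix(".axis.txt")))
        write_delimited(image, path, axis_path, **kw)
    else:
        raise InvalidParameterError(f"unknown cube format {format!r}")


def read_cube(path: str | Path, format: str = "hdf5", **kw):
    if format == "hdf5":
        return read_archive(path)[0]
    if format == "envi":
        return read_envi(path)
    if format == "delimited":
        axis_path = kw.pop("axis_path", str(Path(path).with_suffix(".axis.txt")))
        return read_delimited(path, axis_path, **kw)
    raise InvalidParameterError(f"unknown cube format {format!r}")
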