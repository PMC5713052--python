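"""Hyperspectral cube container and file I/O.

A cube is an ``M x N x L`` array of per-pixel spectra sampled on a strictly
increasing wavelength grid (visible to near-infrared, typically 400-1000 nm
for pushbroom ophthalmic scans).  Cubes carry a ``kind`` tag distinguishing
raw sensor counts from flat-field-corrected relative reflectance (in %).

Two on-disk layouts are supported: ENVI header + raw binary pairs (band
sequential) and multi-page TIFF stacks (one page per band).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["HyperCube", "read_cube", "write_cube"]

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_ENVI_CODES = {np.dtype(v).name: k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperCube:
    """An ``M x N x L`` stack of band images with its wavelength grid.

    Parameters
    ----------
    data
        Non-negative intensities (``kind='raw'``) or percent reflectance
        (``kind='reflectance'``); shape ``(rows, cols, bands)``.
    wavelengths
        Strictly increasing band centres in nanometres, length ``bands``.
    kind
        ``'raw'`` or ``'reflectance'``.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength grid length {len(self.wavelengths)} does not match "
                f"band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.data[~np.isnan(self.data)])):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, i: int) -> np.ndarray:
        """Return band image ``i`` as a 2-D view."""
        return self.data[:, :, i]

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "HyperCube":
        return HyperCube(data, self.wavelengths.copy(), kind or self.kind)


# ---------------------------------------------------------------------------
# ENVI header + raw pairs (band-sequential interleave only)
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    # Collapse {...} blocks (possibly multi-line) into single values first.
    entries: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{.*?\}|[^\n]*)", re.M | re.S)
    # Join brace blocks spanning lines.
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for m in pattern.finditer(text):
        entries[m.group(1).strip().lower()] = m.group(2).strip()
    return entries


def _read_envi(hdr_path: Path) -> HyperCube:
    hdr = _parse_envi_header(hdr_path.read_text())
    samples = int(hdr["samples"])
    lines = int(hdr["lines"])
    bands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr.get("data type", 4))]
    interleave = hdr.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"only bsq interleave is supported, got {interleave!r}")
    offset = int(hdr.get("header offset", 0))
    wl_text = hdr.get("wavelength", "")
    if wl_text:
        wavelengths = np.array(
            [float(v) for v in wl_text.strip("{} ").replace(",", " ").split()]
        )
    else:
        wavelengths = np.arange(bands, dtype=float)
    raw_path = hdr_path.with_suffix(".raw")
    if not raw_path.exists():
        raw_path = hdr_path.with_suffix(".img")
    data = np.fromfile(raw_path, dtype=dtype, offset=offset, count=samples * lines * bands)
    data = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    kind = hdr.get("corneahsi kind", "raw")
    return HyperCube(data.astype(np.float64), wavelengths, kind)


def _write_envi(cube: HyperCube, hdr_path: Path) -> None:
    data32 = cube.data.astype(np.float32)
    raw_path = hdr_path.with_suffix(".raw")
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.wavelengths)
    hdr_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_ENVI_CODES['float32']}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"corneahsi kind = {cube.kind}\n"
        f"wavelength = {{{wl}}}\n"
    )
    data32.transpose(2, 0, 1).tofile(raw_path)


# ---------------------------------------------------------------------------
# Multi-page TIFF stacks
# ---------------------------------------------------------------------------

def _read_tiff(path: Path) -> HyperCube:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    data = np.moveaxis(data, 0, 2)  # pages are bands
    wl = meta.get("wavelengths")
    wavelengths = np.array(wl, dtype=float) if wl is not None else np.arange(data.shape[2], dtype=float)
    return HyperCube(data.astype(np.float64), wavelengths, meta.get("kind", "raw"))


def _write_tiff(cube: HyperCube, path: Path) -> None:
    pages = np.moveaxis(cube.data.astype(np.float32), 2, 0)
    tifffile.imwrite(
        path,
        pages,
        metadata={"wavelengths": list(map(float, cube.wavelengths)), "kind": cube.kind},
    )


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube from an ENVI ``.hdr`` (+ ``.raw``/``.img``) or TIFF file."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        return _read_envi(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path)
    raise ValueError(f"unrecognised cube format: {path.suffix!r}")


def write_cube(cube: HyperCube, path: str | Path) -> None:
    """Write a cube as an ENVI pair (``.hdr`` path) or multi-page TIFF."""
    path = Path(path)
    if path.suffix.lower() == ".hdr":
        _write_envi(cube, path)
    elif path.suffix.lower() in (".tif", ".tiff"):
        _write_tiff(cube, path)
    else:
        raise ValueError(f"unrecognised cube format: {path.suffix!r}")
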