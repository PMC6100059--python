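"""Reading and writing of hyperspectral cubes and pipeline artifacts.

The cube dialect is a minimal ENVI-style pair of files: a text header
(``.hdr``) and a flat binary (``.dat``).  Written cubes are band-sequential
(BSQ), little-endian, 32- or 64-bit float depending on the array dtype;
band-interleaved-by-line (BIL) is additionally accepted on read.  Pixel
coordinates are 0-based, row-major, origin at the top-left corner.

Label maps and classification maps are written as paletted PNG (lossless
integer round-trip); tables are plain CSV with a header row.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "HyperCube",
    "EnviFormatError",
    "read_cube",
    "write_cube",
    "write_map",
    "read_map",
    "write_table",
    "read_table",
    "make_spectra_table",
    "spectra_matrix",
    "wavelength_columns",
]

# ENVI numeric codes for the dtypes this dialect supports
_DTYPE_TO_ENVI = {np.dtype("float32"): 4, np.dtype("float64"): 5}
_ENVI_TO_DTYPE = {4: np.dtype("<f4"), 5: np.dtype("<f8")}


class EnviFormatError(ValueError):
    """Raised for malformed or unsupported cube files."""


@dataclasses.dataclass
class HyperCube:
    """A reflectance (or raw-count) image cube with its wavelength axis.

    Parameters
    ----------
    values
        Array of shape ``(height, width, bands)``.
    wavelengths_nm
        Strictly increasing vector of band-centre wavelengths, length equal
        to the band axis.
    kind
        ``"raw"`` for sensor counts, ``"corrected"`` for relative
        reflectance.  Stages that require one kind refuse the other.
    """

    values: np.ndarray
    wavelengths_nm: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be rank 3, got shape {self.values.shape}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.values.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths_nm.size} does not match "
                f"band axis {self.values.shape[2]}"
            )
        if self.wavelengths_nm.size >= 2 and not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "corrected"):
            raise ValueError(f"kind must be 'raw' or 'corrected', got {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is closest to ``wavelength_nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))


def _header_path(path: Path) -> Path:
    return path.with_suffix(".hdr")


def _data_path(path: Path) -> Path:
    return path.with_suffix(".dat")


def write_cube(cube: HyperCube, path: str | Path) -> Path:
    """Write ``cube`` as an ENVI-style ``.hdr``/``.dat`` pair.

    ``path`` may carry either suffix (or none); both files are placed next
    to each other.  Returns the header path.
    """
    path = Path(path)
    dtype = np.dtype(cube.values.dtype)
    if dtype not in _DTYPE_TO_ENVI:
        raise EnviFormatError(f"unsupported dtype {dtype}; use float32 or float64")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    _header_path(path).write_text(header)
    # BSQ: band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype=dtype.newbyteorder("<"))
    bsq.tofile(_data_path(path))
    return _header_path(path)


def _parse_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("missing ENVI magic line in header")
    fields: dict = {}
    # multi-line brace values (wavelength lists)
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*\{(.*?)\}", text, re.S | re.M):
        fields[m.group(1).strip().lower()] = m.group(2)
    for m in re.finditer(r"^\s*([\w ]+?)\s*=\s*([^{\n]+)$", text, re.M):
        fields.setdefault(m.group(1).strip().lower(), m.group(2).strip())
    return fields


def read_cube(path: str | Path) -> HyperCube:
    """Read an ENVI-style cube written by :func:`write_cube` (BSQ or BIL)."""
    path = Path(path)
    hdr = _header_path(path)
    if not hdr.exists():
        raise FileNotFoundError(hdr)
    fields = _parse_header(hdr.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].strip().lower()
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    if code not in _ENVI_TO_DTYPE:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    if interleave not in ("bsq", "bil"):
        raise EnviFormatError(f"unsupported interleave {interleave!r} (bsq/bil only)")
    if "wavelength" not in fields:
        raise EnviFormatError("header has no wavelength list")
    wavelengths = np.array(
        [float(x) for x in fields["wavelength"].replace("\n", " ").split(",") if x.strip()]
    )
    if wavelengths.size != b:
        raise EnviFormatError(
            f"wavelength list length {wavelengths.size} does not match bands = {b}"
        )
    dtype = _ENVI_TO_DTYPE[code]
    raw = np.fromfile(_data_path(path), dtype=dtype)
    if raw.size != h * w * b:
        raise EnviFormatError(
            f"binary size mismatch: expected {h * w * b} values "
            f"({h}x{w}x{b}), file holds {raw.size}"
        )
    if interleave == "bsq":
        values = np.moveaxis(raw.reshape(b, h, w), 0, 2)
    else:  # bil: lines outer, then bands, then samples
        values = np.moveaxis(raw.reshape(h, b, w), 1, 2)
    kind = fields.get("cube kind", "raw").strip()
    return HyperCube(np.ascontiguousarray(values), wavelengths, kind=kind)


def write_map(image: np.ndarray, palette: Mapping[int, tuple[int, int, int]], path: str | Path) -> Path:
    """Write an integer label/class image as a paletted PNG.

    ``palette`` maps every value present in ``image`` to an RGB triple;
    a missing entry is an error rather than a silent recolouring.
    """
    image = np.asarray(image)
    present = np.unique(image)
    missing = [int(v) for v in present if int(v) not in palette]
    if missing:
        raise ValueError(f"palette missing entries for values {missing}")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("map values must fit in 0..255 for paletted PNG")
    pal = np.zeros((256, 3), dtype=np.uint8)
    for value, rgb in palette.items():
        pal[value] = rgb
    img = Image.fromarray(image.astype(np.uint8), mode="P")
    img.putpalette(pal.ravel().tolist())
    path = Path(path)
    img.save(path, format="PNG")
    return path


def read_map(path: str | Path) -> np.ndarray:
    """Read a paletted PNG back to its integer index image."""
    with Image.open(path) as img:
        if img.mode != "P":
            img = img.convert("P")
        return np.asarray(img, dtype=np.int64)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def wavelength_columns(table: pd.DataFrame) -> list[str]:
    """Names of the per-wavelength reflectance columns of a spectra table."""
    out = []
    for c in table.columns:
        try:
            float(c)
        except ValueError:
            continue
        out.append(c)
    return out


def make_spectra_table(
    spectra: np.ndarray,
    wavelengths_nm: Sequence[float],
    ids: Sequence[int] | None = None,
    classes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Assemble an object- (or pixel-) wise spectra table.

    Columns: ``roi_label``, optionally ``class`` (codes in {1, 2, 3}), then
    one reflectance column per wavelength named by the wavelength in nm.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[1] != len(wavelengths_nm):
        raise ValueError("spectra must be (rows, bands) matching wavelengths")
    n = spectra.shape[0]
    data: dict = {"roi_label": np.asarray(ids if ids is not None else np.arange(1, n + 1))}
    if classes is not None:
        cls = np.asarray(classes, dtype=int)
        if not np.isin(cls, [1, 2, 3]).all():
            raise ValueError("class codes must be in {1, 2, 3}")
        data["class"] = cls
    for j, wl in enumerate(wavelengths_nm):
        data[f"{wl:.2f}"] = spectra[:, j]
    return pd.DataFrame(data)


def spectra_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (values, wavelengths) of a spectra table's reflectance block."""
    cols = wavelength_columns(table)
    return table[cols].to_numpy(dtype=float), np.array([float(c) for c in cols])
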