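"""Readers and writers for the on-disk formats.

Two hyperspectral-cube dialects are supported: a plain ENVI-style pair
(text ``.hdr`` header plus raw binary payload, BSQ/BIL/BIP interleaves,
float32/float64) for interoperability with real HSI exports, and a NumPy
array archive (``.npz``) used by the synthetic pipeline. All writer/reader
pairs round-trip bit-exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "HyperspectralCube",
    "CubeFormatError",
    "read_cube",
    "write_cube",
    "read_mask_png",
    "write_mask_png",
    "read_label_png",
    "write_label_png",
]

_DTYPES = {4: np.float32, 5: np.float64}
_DTYPE_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


class CubeFormatError(ValueError):
    """Header/payload mismatch or unparseable cube file."""


@dataclass
class HyperspectralCube:
    """An H x W x B remission cube with its wavelength axis and provenance."""

    data: np.ndarray
    wavelengths: np.ndarray
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, float)
        if self.data.ndim != 3:
            raise CubeFormatError("cube data must be H x W x B")
        if self.data.shape[2] != self.wavelengths.size:
            raise CubeFormatError(
                f"{self.data.shape[2]} bands vs {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise CubeFormatError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(self.data)):
            raise CubeFormatError("cube contains non-finite values")


def _envi_paths(path: Path) -> tuple[Path, Path]:
    path = Path(path)
    if path.suffix == ".hdr":
        return path, path.with_suffix(".raw")
    return path.with_suffix(path.suffix + ".hdr"), path


def write_cube(cube: HyperspectralCube, path, dialect: str = "envi",
               interleave: str = "bsq") -> None:
    """Write a cube as ENVI header+raw (``dialect='envi'``) or ``.npz``."""
    path = Path(path)
    if dialect == "npz":
        np.savez(
            path,
            data=cube.data,
            wavelengths=cube.wavelengths,
            mask=(np.zeros(cube.data.shape[:2], bool)
                  if cube.mask is None else cube.mask),
            has_mask=np.array(cube.mask is not None),
        )
        return
    if dialect != "envi":
        raise ValueError(f"unknown dialect {dialect!r}")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    hdr_path, raw_path = _envi_paths(path)
    h, w, b = cube.data.shape
    code = _DTYPE_CODES.get(cube.data.dtype, 5)
    data = cube.data.astype(_DTYPES[code], copy=False)
    if interleave == "bip":
        arr = data  # (lines, samples, bands)
    elif interleave == "bil":
        arr = np.transpose(data, (0, 2, 1))  # (lines, bands, samples)
    else:
        arr = np.transpose(data, (2, 0, 1))  # (bands, lines, samples)
    wl = ", ".join(f"{v:.6g}" for v in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    arr.tofile(raw_path)


def _parse_envi_header(text: str) -> dict:
    fields = {}
    for m in re.finditer(r"^([a-z ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)$", text, re.M):
        fields[m.group(1).strip()] = m.group(2).strip()
    return fields


def read_cube(path, dialect: str | None = None) -> HyperspectralCube:
    """Read a cube, auto-detecting the dialect from the file name."""
    path = Path(path)
    if dialect is None:
        dialect = "npz" if path.suffix == ".npz" else "envi"
    if dialect == "npz":
        try:
            with np.load(path) as z:
                mask = z["mask"] if bool(z["has_mask"]) else None
                return HyperspectralCube(z["data"], z["wavelengths"], mask=mask)
        except FileNotFoundError:
            raise
        except Exception as exc:  # zip/key errors
            raise CubeFormatError(f"unreadable array archive {path}: {exc}") from exc

    hdr_path, raw_path = _envi_paths(path)
    if not hdr_path.exists():
        raise FileNotFoundError(hdr_path)
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").lower()
    except (KeyError, ValueError) as exc:
        raise CubeFormatError(f"bad ENVI header {hdr_path}: {exc}") from exc
    if code not in _DTYPES:
        raise CubeFormatError(f"unsupported ENVI data type {code}")
    wl_field = fields.get("wavelength", "{}").strip("{} \n")
    wavelengths = np.array(
        [float(v) for v in wl_field.split(",") if v.strip()], float
    )
    if wavelengths.size != b:
        raise CubeFormatError(
            f"header lists {wavelengths.size} wavelengths for {b} bands"
        )
    dtype = _DTYPES[code]
    expected = h * w * b * dtype().itemsize
    actual = raw_path.stat().st_size
    if actual != expected:
        raise CubeFormatError(
            f"{raw_path}: payload is {actual} bytes, header implies {expected} "
            f"({h}x{w}x{b} {dtype().dtype.name})"
        )
    flat = np.fromfile(raw_path, dtype=dtype)
    if interleave == "bip":
        data = flat.reshape(h, w, b)
    elif interleave == "bil":
        data = np.transpose(flat.reshape(h, b, w), (0, 2, 1))
    elif interleave == "bsq":
        data = np.transpose(flat.reshape(b, h, w), (1, 2, 0))
    else:
        raise CubeFormatError(f"unknown interleave {interleave!r}")
    return HyperspectralCube(data, wavelengths)


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 0


def write_label_png(labels: np.ndarray, path) -> None:
    """Integer label image, 0 = background (16-bit PNG)."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > 65535:
        raise ValueError("labels must fit in uint16")
    Image.fromarray(arr.astype(np.uint16)).save(path)


def read_label_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)).astype(np.int32)
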