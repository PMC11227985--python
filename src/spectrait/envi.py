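"""Minimal ENVI-format hypercube I/O.

ENVI stores a cube as a raw binary file plus a plain-text ``.hdr`` header
describing shape, interleave (BIL/BSQ/BIP), data type and band wavelengths.
Only the subset of the header needed for grain-imaging cubes is supported:
``samples``, ``lines``, ``bands``, ``data type``, ``interleave``,
``byte order`` and ``wavelength``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .bands import BandGrid
from .cube import SpectralCube

# ENVI data-type codes -> numpy dtypes (the ones that occur in practice)
_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}


def _parse_header(text: str) -> dict:
    # strip the leading "ENVI" magic, then parse  key = value  pairs where a
    # value in braces may span lines
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1].strip()
        fields[key] = val
    return fields


def read_envi(header_path: str | Path, data_path: str | Path | None = None,
              kind: str = "dn") -> SpectralCube:
    """Read an ENVI cube; ``data_path`` defaults to the header path minus .hdr."""
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    if data_path is None:
        data_path = header_path.with_suffix("")
        if not Path(data_path).exists():
            data_path = header_path.with_suffix(".img")
    samples = int(fields["samples"])   # columns
    lines = int(fields["lines"])       # rows
    bands = int(fields["bands"])
    dtype = np.dtype(_DTYPES[int(fields["data type"])])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    raw = np.fromfile(str(data_path), dtype=dtype)
    if raw.size != samples * lines * bands:
        raise ValueError(
            f"data size {raw.size} does not match header "
            f"{lines}x{samples}x{bands}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl = np.array([float(w) for w in fields["wavelength"].replace("\n", " ").split(",")])
    return SpectralCube(cube.astype(float), BandGrid(wl), kind=kind)


def write_envi(cube: SpectralCube, header_path: str | Path,
               interleave: str = "bil", dtype=np.float32) -> Path:
    """Write a cube as raw binary + .hdr; returns the data path."""
    header_path = Path(header_path)
    data_path = header_path.with_suffix("")
    arr = cube.values.astype(dtype)
    interleave = interleave.lower()
    if interleave == "bsq":
        out = arr.transpose(2, 0, 1)
    elif interleave == "bil":
        out = arr.transpose(0, 2, 1)
    elif interleave == "bip":
        out = arr
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    out.tofile(str(data_path))
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.wavelengths_nm)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cube.n_cols}\n"
        f"lines = {cube.n_rows}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    return data_path
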