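"""ENVI cube and label-table I/O.

Cubes are stored as an ENVI text header (``.hdr``) next to a band-sequential
(BSQ) float32 binary (``.img``).  Only the header fields the pipeline needs are
written: samples, lines, bands, interleave, data type, byte order and the
wavelength list in nanometres.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_envi", "read_envi", "write_labels", "read_labels"]

_DTYPE_CODES = {4: np.float32, 5: np.float64}
_CODE_FOR_DTYPE = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(path: str | Path, data: np.ndarray, wavelengths: np.ndarray) -> Path:
    """Write ``data`` (rows x cols x bands) as ENVI header + BSQ binary.

    ``path`` may carry any extension; the pair ``<stem>.hdr`` / ``<stem>.img``
    is created.  Returns the header path.
    """
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D cube, got shape {data.shape}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.shape != (data.shape[2],):
        raise ValueError("wavelength axis length must equal the band count")
    path = Path(path)
    stem = path.with_suffix("")
    arr = data.astype(np.float32, copy=False)
    code = _CODE_FOR_DTYPE[arr.dtype]
    # BSQ: band-major on disk
    bsq = np.ascontiguousarray(np.moveaxis(arr, 2, 0))
    img = stem.with_suffix(".img")
    bsq.tofile(img)
    wl = ", ".join(f"{w:.6f}" for w in wavelengths)
    hdr_text = (
        "ENVI\n"
        f"samples = {data.shape[1]}\n"
        f"lines = {data.shape[0]}\n"
        f"bands = {data.shape[2]}\n"
        "interleave = bsq\n"
        f"data type = {code}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr = stem.with_suffix(".hdr")
    hdr.write_text(hdr_text)
    return hdr


def read_envi(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an ENVI ``.hdr``/``.img`` pair; returns (cube rows x cols x bands, wavelengths nm)."""
    stem = Path(path).with_suffix("")
    hdr_text = stem.with_suffix(".hdr").read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^(\w[\w ]*?)\s*=\s*(\{[^}]*\}|[^\n]*)$", hdr_text, re.M):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _DTYPE_CODES[int(fields["data type"])]
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"only BSQ interleave is supported, got {interleave!r}")
    wl_text = fields["wavelength"].strip("{} \n")
    wavelengths = np.array([float(tok) for tok in wl_text.split(",") if tok.strip()])
    raw = np.fromfile(stem.with_suffix(".img"), dtype=dtype)
    if raw.size != lines * samples * bands:
        raise ValueError("binary size does not match header dimensions")
    cube = np.moveaxis(raw.reshape(bands, lines, samples), 0, 2)
    return cube.astype(np.float64), wavelengths


def write_labels(path: str | Path, table: pd.DataFrame) -> Path:
    """Write the label table (columns sample_id, ssc_brix, split) as CSV."""
    required = {"sample_id", "ssc_brix", "split"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.6f")
    return path


def read_labels(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
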