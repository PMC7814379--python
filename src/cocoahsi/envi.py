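"""Minimal ENVI raster I/O.

Supports the subset of the ENVI format produced by line-scanning NIR
cameras: an ASCII ``.hdr`` with ``key = value`` pairs (values may be
``{...}`` lists spanning lines) next to a headerless binary cube in BIL,
BIP or BSQ interleave, little-endian.  Unknown header keys are preserved
verbatim on write.

Data types follow the ENVI numeric codes; only the ones a 14-bit HgCdTe
detector plus float processing chains actually emit are implemented:
1 (uint8), 2 (int16), 4 (float32), 5 (float64), 12 (uint16).
"""

from __future__ import annotations

import os
import re

import numpy as np

from .errors import BandMismatchError, EnviFormatError, UnsupportedInterleaveError

DTYPE_CODES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
CODE_FOR_DTYPE = {np.dtype(v): k for k, v in DTYPE_CODES.items()}

_REQUIRED = ("samples", "lines", "bands", "interleave", "data type")

# axis order of the on-disk array for each interleave; in-memory layout is
# always (lines, samples, bands)
_DISK_ORDER = {
    "bil": (0, 2, 1),  # lines, bands, samples
    "bip": (0, 1, 2),  # lines, samples, bands
    "bsq": (2, 0, 1),  # bands, lines, samples
}


def parse_header(text: str) -> dict:
    """Parse ENVI header text into a dict (keys lower-cased, list values as python lists)."""
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing 'ENVI' magic line)")
    body = text.lstrip()[4:]
    fields: dict = {}
    # join {...} blocks onto one line
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            items = [v.strip() for v in value.strip("{}").split(",") if v.strip()]
            fields[key] = items
        else:
            fields[key] = value
    return fields


def _fmt_value(value) -> str:
    if isinstance(value, (list, tuple, np.ndarray)):
        items = ", ".join(_fmt_scalar(v) for v in value)
        return "{ " + items + " }"
    return _fmt_scalar(value)


def _fmt_scalar(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))  # shortest round-trip representation
    return str(v)


def _data_path(header_path: str) -> str:
    base, _ = os.path.splitext(header_path)
    for cand in (base, base + ".raw", base + ".img", base + ".dat"):
        if os.path.exists(cand) and cand != header_path:
            return cand
    raise FileNotFoundError(f"no binary file found next to {header_path!r}")


def read(header_path: str) -> tuple[np.ndarray, dict]:
    """Read an ENVI raster.

    Returns ``(array, header_fields)`` with the array shaped
    (lines, samples, bands) regardless of on-disk interleave.
    """
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    with open(header_path) as fh:
        fields = parse_header(fh.read())
    missing = [k for k in _REQUIRED if k not in fields]
    if missing:
        raise EnviFormatError(f"header missing required keys: {missing}")
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = str(fields["interleave"]).lower()
    if interleave not in _DISK_ORDER:
        raise UnsupportedInterleaveError(f"interleave {interleave!r} not supported")
    code = int(fields["data type"])
    if code not in DTYPE_CODES:
        raise EnviFormatError(f"ENVI data type code {code} not supported")
    dtype = np.dtype(DTYPE_CODES[code]).newbyteorder("<")
    raw = np.fromfile(_data_path(header_path), dtype=dtype)
    if raw.size != lines * samples * bands:
        raise BandMismatchError(
            f"binary has {raw.size} values, header promises "
            f"{lines}x{samples}x{bands} = {lines * samples * bands}"
        )
    order = _DISK_ORDER[interleave]
    disk_shape = tuple((lines, samples, bands)[ax] for ax in order)
    cube = raw.reshape(disk_shape).transpose(np.argsort(order))
    if "wavelength" in fields:
        wl = np.asarray([float(v) for v in fields["wavelength"]])
        if wl.size != bands:
            raise BandMismatchError(
                f"header lists {wl.size} wavelengths for {bands} bands"
            )
        fields["wavelength"] = wl
    return np.ascontiguousarray(cube), fields


def write(header_path: str, data: np.ndarray, fields: dict | None = None,
          interleave: str = "bil", dtype=None) -> str:
    """Write ``data`` (lines, samples, bands) as an ENVI pair; returns the binary path."""
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("expected a 2-D or 3-D array")
    interleave = interleave.lower()
    if interleave not in _DISK_ORDER:
        raise UnsupportedInterleaveError(f"interleave {interleave!r} not supported")
    if dtype is not None:
        data = data.astype(dtype)
    code = CODE_FOR_DTYPE.get(data.dtype)
    if code is None:
        data = data.astype(np.float32)
        code = 4
    lines, samples, bands = data.shape
    out = dict(fields or {})
    out.update({
        "samples": samples, "lines": lines, "bands": bands,
        "interleave": interleave, "data type": code, "byte order": 0,
        "header offset": 0,
    })
    base, _ = os.path.splitext(header_path)
    data_path = base + ".raw"
    order = _DISK_ORDER[interleave]
    data.transpose(order).astype(data.dtype.newbyteorder("<")).tofile(data_path)
    with open(header_path, "w") as fh:
        fh.write("ENVI\n")
        for key, value in out.items():
            fh.write(f"{key} = {_fmt_value(value)}\n")
    return data_path
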