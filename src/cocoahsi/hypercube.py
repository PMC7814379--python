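"""Hypercube container, radiometric calibration and band management.

A hypercube is the (rows x cols x bands) output of a pushbroom SWIR
camera.  Raw detector counts S are converted to reflectance with the
dark-current frame D (shutter closed) and the white PTFE reference W:

    R = (S - D) / (W - D)

applied per pixel and per band.  Detectors of this class deliver ~256
bands across ~980-2500 nm of which the leading handful are outside the
sensitive range and are dropped before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import envi
from .errors import BandMismatchError, CalibrationError

#: reflectance ceiling after calibration; specular highlights may exceed the
#: PTFE standard slightly, 1.5 keeps them without destabilising log(1/R)
CLIP_MAX = 1.5

#: absorbance floor applied to reflectance before log10(1/R)
ABSORBANCE_FLOOR = 1e-4


@dataclass
class Hypercube:
    """A (rows x cols x bands) image with its wavelength axis.

    ``kind`` is one of ``raw`` (detector counts), ``reflectance``
    (fraction of the white standard) or ``absorbance`` (log10(1/R)).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("hypercube data must be rows x cols x bands")
        if self.wavelengths.size != self.data.shape[2]:
            raise BandMismatchError(
                f"{self.wavelengths.size} wavelengths for {self.data.shape[2]} bands"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "reflectance", "absorbance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReferenceFrames:
    """Dark and white reference spectra, already averaged over frames.

    Either per-band vectors of length ``bands`` or per-column arrays of
    shape ``(cols, bands)`` (pushbroom columns see different optics).
    """

    dark: np.ndarray
    white: np.ndarray

    def __post_init__(self):
        self.dark = np.asarray(self.dark, dtype=float)
        self.white = np.asarray(self.white, dtype=float)
        if self.dark.shape != self.white.shape:
            raise BandMismatchError("dark and white shapes differ")

    @classmethod
    def from_frames(cls, dark_frames: np.ndarray, white_frames: np.ndarray) -> "ReferenceFrames":
        """Reduce stacks of reference frames (frames x ... x bands) by the mean."""
        return cls(np.mean(np.asarray(dark_frames, float), axis=0),
                   np.mean(np.asarray(white_frames, float), axis=0))


def read_envi(header_path: str) -> Hypercube:
    """Read an ENVI header/binary pair into a :class:`Hypercube`."""
    data, fields = envi.read(str(header_path))
    if "wavelength" not in fields:
        raise BandMismatchError("header carries no wavelength list")
    wl = fields.pop("wavelength")
    kind = fields.pop("cube kind", "raw")
    meta = {k: v for k, v in fields.items()
            if k not in ("samples", "lines", "bands", "interleave",
                         "data type", "byte order", "header offset")}
    return Hypercube(data=data, wavelengths=wl, kind=str(kind), metadata=meta)


def write_envi(cube: Hypercube, header_path: str, interleave: str = "bil",
               dtype=None) -> str:
    """Write a cube as an ENVI pair; metadata keys are preserved verbatim."""
    fields = dict(cube.metadata)
    fields["wavelength"] = cube.wavelengths
    fields["cube kind"] = cube.kind
    return envi.write(str(header_path), cube.data, fields,
                      interleave=interleave, dtype=dtype)


def calibrate_reflectance(raw: Hypercube, refs: ReferenceFrames,
                          clip_max: float = CLIP_MAX) -> Hypercube:
    """Radiometric calibration R = (S - D)/(W - D), clipped to [0, clip_max]."""
    if raw.kind != "raw":
        raise ValueError(f"expected a raw cube, got kind={raw.kind!r}")
    dark, white = refs.dark, refs.white
    if dark.shape[-1] != raw.n_bands:
        raise BandMismatchError(
            f"references have {dark.shape[-1]} bands, cube has {raw.n_bands}"
        )
    span = white - dark
    bad = np.nonzero(~np.all(span > 0, axis=tuple(range(span.ndim - 1))))[0]
    if bad.size:
        raise CalibrationError(
            f"white <= dark at band indices {bad.tolist()[:8]}"
            f"{'...' if bad.size > 8 else ''}"
        )
    # per-band vectors broadcast over rows and cols; per-column arrays
    # (cols, bands) broadcast over rows
    refl = (raw.data.astype(float) - dark) / span
    refl = np.clip(refl, 0.0, clip_max)
    meta = dict(raw.metadata, calibration="dark-white")
    return Hypercube(refl, raw.wavelengths.copy(), kind="reflectance", metadata=meta)


def exclude_bands(cube: Hypercube, n_leading: int) -> Hypercube:
    """Drop the first ``n_leading`` bands (detector warm-up region)."""
    n_leading = int(n_leading)
    if n_leading < 0:
        raise ValueError("n_leading must be >= 0")
    if n_leading >= cube.n_bands:
        raise ValueError(
            f"cannot exclude {n_leading} of {cube.n_bands} bands"
        )
    if n_leading == 0:
        return cube
    meta = dict(cube.metadata)
    meta["excluded leading bands"] = int(meta.get("excluded leading bands", 0)) + n_leading
    return Hypercube(cube.data[:, :, n_leading:], cube.wavelengths[n_leading:],
                     kind=cube.kind, metadata=meta)


def to_absorbance(obj, floor: float = ABSORBANCE_FLOOR):
    """Convert reflectance to absorbance A = log10(1/R).

    Accepts a :class:`Hypercube` (kind must be ``reflectance``) or a bare
    array of reflectance spectra.  Values below ``floor`` are raised to it
    so background pixels do not produce infinities.
    """
    if isinstance(obj, Hypercube):
        if obj.kind != "reflectance":
            raise ValueError(f"expected a reflectance cube, got kind={obj.kind!r}")
        a = -np.log10(np.maximum(obj.data, floor))
        return Hypercube(a, obj.wavelengths.copy(), kind="absorbance",
                         metadata=dict(obj.metadata))
    arr = np.asarray(obj, dtype=float)
    return -np.log10(np.maximum(arr, floor))
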