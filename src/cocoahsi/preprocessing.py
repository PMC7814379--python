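"""Spectral pre-treatments as composable fit/apply operators.

The battery a chemometrician runs before PLS on NIR spectra: log(1/R)
conversion, unit-vector normalisation, multiplicative scatter correction
(MSC), standard normal variate (SNV) and Savitzky-Golay derivatives,
plus their compositions.  Every operator is row-local except MSC, whose
reference spectrum is *fitted* on the calibration set and then applied
unchanged to validation rows and to single pixels — the fit/apply split
is enforced so validation data can never leak into the reference.

All operators accept an ``n x p`` array of spectra and return the same
shape.  By convention the treatment chains operate on absorbance
log10(1/R); the ``log1r`` step performs that conversion, so a chain fed
with reflectance starts with it.
"""

from __future__ import annotations

import numpy as np
import yaml
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, UnfittedError
from .hypercube import ABSORBANCE_FLOOR, Hypercube


def _as_matrix(spectra) -> np.ndarray:
    x = np.asarray(spectra, dtype=float)
    return x[None, :] if x.ndim == 1 else x


def snv(spectra) -> np.ndarray:
    """Standard normal variate: centre and scale each spectrum to unit sd (n-1)."""
    x = _as_matrix(spectra)
    sd = x.std(axis=1, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise DegenerateSpectrumError(f"constant spectrum in rows {flat.tolist()[:5]}")
    return (x - x.mean(axis=1, keepdims=True)) / sd[:, None]


def msc_fit(spectra) -> np.ndarray:
    """MSC reference = mean spectrum of the fitting set."""
    return _as_matrix(spectra).mean(axis=0)


def msc_apply(spectra, reference) -> np.ndarray:
    """Regress each spectrum on the reference, x ~ a + b*ref, return (x - a)/b."""
    x = _as_matrix(spectra)
    ref = np.asarray(reference, dtype=float)
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom == 0:
        raise DegenerateSpectrumError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    small = np.nonzero(np.abs(b) < 1e-12)[0]
    if small.size:
        raise DegenerateSpectrumError(
            f"spectrum orthogonal to MSC reference in rows {small.tolist()[:5]}"
        )
    a = x.mean(axis=1) - b * ref.mean()
    return (x - a[:, None]) / b[:, None]


def sg_derivative(spectra, order: int, window: int = 11, poly: int | None = None) -> np.ndarray:
    """Savitzky-Golay derivative w.r.t. band index.

    Defaults: window 11; polynomial degree 2 for the 1st derivative and 3
    for the 2nd.  Edge bands are evaluated from the polynomial fitted to
    the first/last full window.
    """
    if poly is None:
        poly = 2 if order == 1 else 3
    if window % 2 == 0 or not (window > poly >= order >= 1):
        raise ValueError(
            f"need odd window > poly >= order >= 1, got window={window} "
            f"poly={poly} order={order}"
        )
    x = _as_matrix(spectra)
    if x.shape[1] < window:
        raise ValueError(f"{x.shape[1]} bands < window {window}")
    return savgol_filter(x, window, poly, deriv=order, delta=1.0,
                         axis=1, mode="interp")


def normalise(spectra, mode: str = "unit") -> np.ndarray:
    """Normalise each spectrum: ``unit`` (Euclidean), ``area`` (sum of |x|) or ``max``."""
    x = _as_matrix(spectra)
    if mode == "unit":
        scale = np.linalg.norm(x, axis=1)
    elif mode == "area":
        scale = np.abs(x).sum(axis=1)
    elif mode == "max":
        scale = np.abs(x).max(axis=1)
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    zero = np.nonzero(scale == 0)[0]
    if zero.size:
        raise DegenerateSpectrumError(f"zero spectrum in rows {zero.tolist()[:5]}")
    return x / scale[:, None]


def log1r(spectra, floor: float = ABSORBANCE_FLOOR) -> np.ndarray:
    """Reflectance to absorbance, A = log10(1/R), with a floor under R."""
    x = _as_matrix(spectra)
    return -np.log10(np.maximum(x, floor))


class PreprocessSpec:
    """An ordered chain of pre-treatment steps with fitted state.

    Steps are dicts ``{"op": name, **params}``; MSC gains a ``reference``
    vector at fit time.  Named presets mirror the usual comparison table::

        log1r | norm | msc | snv | d1 | d2 | snv+d1
    """

    _PRESETS = {
        "log1r": [],
        "norm": [{"op": "normalise"}],
        "msc": [{"op": "msc"}],
        "snv": [{"op": "snv"}],
        "d1": [{"op": "sg_derivative", "order": 1, "window": 11, "poly": 2}],
        "d2": [{"op": "sg_derivative", "order": 2, "window": 11, "poly": 3}],
        "snv+d1": [{"op": "snv"},
                   {"op": "sg_derivative", "order": 1, "window": 11, "poly": 2}],
    }

    def __init__(self, steps: list | None = None, label: str = "custom",
                 from_reflectance: bool = True):
        self.steps = [dict(s) for s in (steps or [])]
        self.label = label
        self.from_reflectance = from_reflectance
        self._fitted = not any(s["op"] == "msc" for s in self.steps)

    @classmethod
    def from_name(cls, name: str, from_reflectance: bool = True) -> "PreprocessSpec":
        if name not in cls._PRESETS:
            raise ValueError(f"unknown pre-treatment {name!r}; "
                             f"one of {sorted(cls._PRESETS)}")
        return cls(cls._PRESETS[name], label=name, from_reflectance=from_reflectance)

    @property
    def fitted(self) -> bool:
        return self._fitted

    def _chain(self, x: np.ndarray, fit: bool) -> np.ndarray:
        if self.from_reflectance:
            x = log1r(x)
        for step in self.steps:
            op = step["op"]
            if op == "snv":
                x = snv(x)
            elif op == "normalise":
                x = normalise(x, step.get("mode", "unit"))
            elif op == "sg_derivative":
                x = sg_derivative(x, step["order"], step.get("window", 11),
                                  step.get("poly"))
            elif op == "msc":
                if fit:
                    step["reference"] = msc_fit(x)
                elif "reference" not in step:
                    raise UnfittedError("MSC step applied before fitting")
                x = msc_apply(x, step["reference"])
            elif op == "log1r":
                x = log1r(x)
            else:
                raise ValueError(f"unknown step op {op!r}")
        return x

    def fit_transform(self, spectra) -> np.ndarray:
        """Fit stateful steps on calibration spectra and return them transformed."""
        out = self._chain(_as_matrix(spectra), fit=True)
        self._fitted = True
        return out

    def transform(self, spectra) -> np.ndarray:
        """Apply the (already fitted) chain to new spectra."""
        if not self._fitted:
            raise UnfittedError(f"spec {self.label!r} has unfitted steps")
        return self._chain(_as_matrix(spectra), fit=False)

    def transform_cube(self, cube: Hypercube, mask=None) -> np.ndarray:
        """Apply pixel-wise to a reflectance cube; masked-out pixels return NaN.

        Returns a (rows x cols x bands) array of pre-treated spectra.
        """
        rows, cols, bands = cube.shape
        flat = cube.data.reshape(-1, bands)
        if mask is None:
            return self.transform(flat).reshape(rows, cols, bands)
        m = np.asarray(mask, dtype=bool).reshape(-1)
        out = np.full((rows * cols, bands), np.nan)
        if m.any():
            out[m] = self.transform(flat[m])
        return out.reshape(rows, cols, bands)

    # --- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        steps = []
        for s in self.steps:
            s = dict(s)
            if isinstance(s.get("reference"), np.ndarray):
                s["reference"] = [float(v) for v in s["reference"]]
            steps.append(s)
        return {"label": self.label, "from_reflectance": self.from_reflectance,
                "steps": steps}

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        spec = cls(d.get("steps", []), label=d.get("label", "custom"),
                   from_reflectance=d.get("from_reflectance", True))
        for s in spec.steps:
            if "reference" in s:
                s["reference"] = np.asarray(s["reference"], dtype=float)
        spec._fitted = all(
            s["op"] != "msc" or "reference" in s for s in spec.steps
        )
        return spec

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __repr__(self) -> str:
        ops = "+".join(s["op"] for s in self.steps) or "identity"
        return f"PreprocessSpec({self.label!r}: log1r->{ops})" \
            if self.from_reflectance else f"PreprocessSpec({self.label!r}: {ops})"


PRETREATMENTS = tuple(PreprocessSpec._PRESETS)
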