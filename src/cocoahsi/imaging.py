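"""Chemical images: per-pixel and per-bean fat maps from a fitted model.

A fitted calibration is applied to a hypercube in two ways: per pixel
(each foreground spectrum is pre-treated with the model's stored chain
and dotted with the regression vector — reveals within-bean fat
distribution) or per bean (predict once from the bean's mean spectrum
and paint its mask uniformly — the practical screening mode).  The two
agree exactly only when the pre-treatment chain is linear in the
spectrum (log1r alone is; SNV/MSC per pixel are not).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import envi
from .hypercube import Hypercube
from .pls import PLSModel
from .segmentation import LabelMap, extract_mean_spectra

#: flag predictions outside this plausible fat range in the QC table
QC_RANGE = (30.0, 75.0)


@dataclass
class ChemicalImage:
    """Predicted-fat map; background pixels are NaN, never 0."""

    values: np.ndarray                 # rows x cols, % fat, NaN background
    per_bean: pd.DataFrame             # bean_id (label), predicted_fat, n_pixels, qc_flag
    basis: str = "as_is"
    mode: str = "pixel"                # pixel | mean_spectrum | mean_of_pixels
    scale_limits: tuple | None = None  # colour scale (lo, hi)
    centroids: np.ndarray | None = field(default=None)

    @property
    def background_mask(self) -> np.ndarray:
        return np.isnan(self.values)


def _qc(per_bean: pd.DataFrame) -> pd.DataFrame:
    lo, hi = QC_RANGE
    per_bean["qc_flag"] = np.where(
        (per_bean["predicted_fat"] < lo) | (per_bean["predicted_fat"] > hi),
        "out_of_range", "")
    return per_bean


def predict_pixelwise(cube: Hypercube, labels: LabelMap, model: PLSModel,
                      scale_limits=None) -> ChemicalImage:
    """Predict fat for every foreground pixel."""
    if cube.kind != "reflectance":
        raise ValueError(f"expected a reflectance cube, got kind={cube.kind!r}")
    if cube.n_bands != model.wavelengths.size or \
            not np.allclose(cube.wavelengths, model.wavelengths):
        raise ValueError("cube wavelength grid does not match the model's")
    fg = labels.labels > 0
    values = np.full(cube.shape[:2], np.nan)
    if fg.any():
        values[fg] = model.predict_reflectance(cube.data[fg])
    rows = []
    for k in range(1, labels.n_objects + 1):
        mask = labels.labels == k
        rows.append({"bean_id": k, "predicted_fat": float(values[mask].mean()),
                     "n_pixels": int(mask.sum())})
    per_bean = _qc(pd.DataFrame(rows))
    return ChemicalImage(values, per_bean, basis=model.basis, mode="pixel",
                         scale_limits=scale_limits, centroids=labels.centroids)


def predict_per_bean(cube: Hypercube, labels: LabelMap, model: PLSModel,
                     mode: str = "mean_spectrum", scale_limits=None) -> ChemicalImage:
    """Predict one fat value per bean and paint its mask uniformly.

    ``mean_spectrum`` (default): pre-treat the bean's mean spectrum and
    predict once — the practical mode.  ``mean_of_pixels``: average the
    pixel-wise map over the mask.
    """
    if mode == "mean_of_pixels":
        px = predict_pixelwise(cube, labels, model, scale_limits)
        preds = px.per_bean["predicted_fat"].to_numpy()
    elif mode == "mean_spectrum":
        table = extract_mean_spectra(cube, labels)
        preds = model.predict_reflectance(table.X)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    values = np.full(cube.shape[:2], np.nan)
    rows = []
    for k in range(1, labels.n_objects + 1):
        mask = labels.labels == k
        values[mask] = preds[k - 1]
        rows.append({"bean_id": k, "predicted_fat": float(preds[k - 1]),
                     "n_pixels": int(mask.sum())})
    per_bean = _qc(pd.DataFrame(rows))
    return ChemicalImage(values, per_bean, basis=model.basis, mode=mode,
                         scale_limits=scale_limits, centroids=labels.centroids)


def render(chem: ChemicalImage, out_path, annotate: bool = True,
           cmap: str = "viridis", dpi: int = 120) -> str:
    """Write a graded-colour PNG with a colour bar.

    With ``annotate``, the per-bean predicted mean is printed at each
    centroid to one decimal (round-half-even).  Scale limits are taken
    from ``chem.scale_limits`` when set (fixed limits keep images of the
    two bean sides comparable), else the finite value range.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = chem.values[~np.isnan(chem.values)]
    if chem.scale_limits is not None:
        lo, hi = chem.scale_limits
    elif finite.size:
        lo, hi = float(finite.min()), float(finite.max())
    else:
        lo, hi = 0.0, 1.0
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(chem.values, cmap=cmap, vmin=lo, vmax=hi)
    ax.set_xticks([]), ax.set_yticks([])
    fig.colorbar(im, ax=ax, label=f"predicted fat (% {chem.basis})")
    if annotate and chem.centroids is not None and len(chem.per_bean):
        for (r, c), v in zip(chem.centroids,
                             chem.per_bean["predicted_fat"].to_numpy()):
            ax.text(c, r, format_annotation(v), ha="center", va="center",
                    fontsize=7, color="white",
                    bbox=dict(facecolor="black", alpha=0.4, pad=0.5, lw=0))
    fig.savefig(out_path, dpi=dpi, metadata={"Software": None})
    plt.close(fig)
    return str(out_path)


def format_annotation(value: float) -> str:
    """One-decimal annotation, round-half-even (numpy/IEEE rounding)."""
    return f"{np.round(value, 1):.1f}"


def write_envi_map(chem: ChemicalImage, header_path) -> str:
    """Write the fat map as a single-band float ENVI raster (NaN background)."""
    return envi.write(str(header_path), chem.values.astype(np.float32),
                      {"description": f"predicted fat % {chem.basis}"})
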