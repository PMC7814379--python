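"""Band ranking and multispectral reduction of a full-spectrum model.

A multispectral camera acquires a handful of discrete filters instead
of a continuous spectrum, so a deployed model must (a) use few bands
and (b) renounce pre-treatments that need full spectra — only log(1/R)
per band survives.  Bands are ranked by the sd-weighted magnitude of
the PLS regression vector, |beta_j| * sd(X_j), the usual reading of
"weighted regression coefficients"; raw |beta| is available by flag.
"""

from __future__ import annotations

import numpy as np

from .pls import PLSModel, run_calibration
from .spectra import SpectraTable

#: physical filters cannot sit closer than one instrument bandwidth
MIN_BAND_SPACING_NM = 6.0


def rank_bands(model: PLSModel, weighted: bool = True) -> list:
    """All bands as (wavelength, importance), descending importance.

    Ties break toward the shorter wavelength.
    """
    imp = np.abs(model.beta) * (model.x_sd if weighted else 1.0)
    order = np.lexsort((model.wavelengths, -imp))
    return [(float(model.wavelengths[j]), float(imp[j])) for j in order]


def select_top_bands(model: PLSModel, k: int, weighted: bool = True,
                     min_spacing: float = MIN_BAND_SPACING_NM) -> np.ndarray:
    """Indices of the top-k bands after merging near-coincident picks.

    Walking the ranking in descending importance, a band closer than
    ``min_spacing`` nm to an already-selected one is merged into it
    (the higher-importance band stays).
    """
    ranked = rank_bands(model, weighted)
    chosen_wl: list = []
    for wl, _ in ranked:
        if all(abs(wl - w) >= min_spacing for w in chosen_wl):
            chosen_wl.append(wl)
        if len(chosen_wl) == k:
            break
    idx = np.sort([int(np.argmin(np.abs(model.wavelengths - w))) for w in chosen_wl])
    return idx


def refit_multispectral(table: SpectraTable, bands, pretreatment: str = "log1r",
                        deployment_mode: bool = True, **calib_kwargs):
    """Refit the calibration on a band subset.

    ``bands`` is an index array into ``table.wavelengths``.  With
    ``deployment_mode`` (the realistic multispectral setting) only the
    ``log1r`` per-band treatment is allowed: SNV, MSC, derivatives and
    normalisation all need the full spectrum, which a filter instrument
    never measures.
    """
    bands = np.asarray(bands, dtype=int)
    if bands.size == 0:
        raise ValueError("no bands selected")
    if deployment_mode and pretreatment != "log1r":
        raise ValueError(
            f"pre-treatment {pretreatment!r} needs full spectra; a multispectral "
            "instrument acquires discrete bands, so only log1r is deployable "
            "(pass deployment_mode=False to override)")
    sub = table.select_bands(bands)
    n_lv = calib_kwargs.pop("n_lv", None)
    if n_lv is not None and n_lv > bands.size:
        raise ValueError(f"n_lv={n_lv} exceeds {bands.size} selected bands")
    calib_kwargs.setdefault("max_lv", min(15, bands.size))
    model, report, extras = run_calibration(
        sub, pretreatment=pretreatment, n_lv=n_lv, **calib_kwargs)
    report.pretreatment = f"{pretreatment}[{bands.size} bands]"
    return model, report, extras
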