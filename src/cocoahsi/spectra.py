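"""Tabular container for per-bean mean spectra.

One row per (bean, side): the mean spectrum over the bean's pixels plus
the identifiers and reference values the calibration needs.  Stored on
disk as a flat CSV with the metadata columns first and one column per
wavelength (named by the wavelength in nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ("bean_id", "batch", "side", "presentation",
                "fat_as_is", "fat_dmb", "moisture", "n_pixels")


@dataclass
class SpectraTable:
    X: np.ndarray                 # n x p
    wavelengths: np.ndarray       # p
    meta: pd.DataFrame            # n rows, subset of META_COLUMNS

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != self.wavelengths.size:
            raise ValueError("X must be n x len(wavelengths)")
        if len(self.meta) != self.X.shape[0]:
            raise ValueError("meta rows must match X rows")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def bean_ids(self) -> np.ndarray:
        return self.meta["bean_id"].to_numpy()

    def y(self, basis: str = "as_is") -> np.ndarray:
        """Reference fat values, ``as_is`` or ``dmb``."""
        col = {"as_is": "fat_as_is", "dmb": "fat_dmb"}[basis]
        return self.meta[col].to_numpy(dtype=float)

    def subset(self, rows) -> "SpectraTable":
        rows = np.asarray(rows)
        return SpectraTable(self.X[rows], self.wavelengths,
                            self.meta.iloc[rows].reset_index(drop=True))

    def select_bands(self, band_idx) -> "SpectraTable":
        band_idx = np.asarray(band_idx, dtype=int)
        return SpectraTable(self.X[:, band_idx], self.wavelengths[band_idx],
                            self.meta.copy())

    def to_csv(self, path) -> None:
        spectra = pd.DataFrame(self.X,
                               columns=[f"{wl:.2f}" for wl in self.wavelengths])
        pd.concat([self.meta.reset_index(drop=True), spectra],
                  axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraTable":
        df = pd.read_csv(path)
        meta_cols = [c for c in df.columns if c in META_COLUMNS]
        wl_cols = [c for c in df.columns if c not in META_COLUMNS]
        wl = np.asarray([float(c) for c in wl_cols])
        return cls(df[wl_cols].to_numpy(dtype=float), wl, df[meta_cols])


def concat(tables: list) -> SpectraTable:
    """Stack spectra tables sharing one wavelength grid."""
    first = tables[0]
    for t in tables[1:]:
        if not np.allclose(t.wavelengths, first.wavelengths):
            raise ValueError("wavelength grids differ between tables")
    X = np.vstack([t.X for t in tables])
    meta = pd.concat([t.meta for t in tables], ignore_index=True)
    return SpectraTable(X, first.wavelengths, meta)
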