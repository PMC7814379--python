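"""Single-bean detection and per-bean spectrum extraction.

Several beans are scanned together in one hypercube; each is detected,
given a stable sample number from its position in the image (reading
order: row-major by centroid), and reduced to its mean spectrum.  The
two sides of a scan are paired by that same positional rank, assuming
beans are flipped in place (optionally mirrored within each row).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing as binary_closing, disk

from .errors import PairingError, SegmentationError
from .hypercube import ABSORBANCE_FLOOR, Hypercube
from .spectra import SpectraTable


@dataclass
class LabelMap:
    """Labelled bean image: 0 = background, k = bean k in reading order."""

    labels: np.ndarray
    centroids: np.ndarray          # K x 2 (row, col)
    pixel_counts: np.ndarray       # K
    rows: np.ndarray               # K, 0-based stage-row index of each label
    border_touching: np.ndarray    # K bool, objects clipped by the image edge

    @property
    def n_objects(self) -> int:
        return self.centroids.shape[0]


def _reading_order(centroids: np.ndarray, heights: np.ndarray):
    """Row-major ordering: bin rows at half the median object height."""
    order = np.argsort(centroids[:, 0], kind="stable")
    half_h = max(np.median(heights) / 2.0, 1.0)
    row_of = np.empty(len(order), dtype=int)
    current_row, row_anchor = 0, centroids[order[0], 0]
    for idx in order:
        if centroids[idx, 0] - row_anchor > half_h:
            current_row += 1
            row_anchor = centroids[idx, 0]
        row_of[idx] = current_row
    rank = np.lexsort((centroids[:, 1], row_of))
    return rank, row_of


def segment_beans(cube: Hypercube, min_area: int | None = None,
                  band: int | None = None, closing_radius: int = 1) -> LabelMap:
    """Threshold (Otsu), connected components, reading-order relabel.

    Thresholding runs on the band-mean reflectance image unless a single
    ``band`` index is given.  ``min_area`` defaults to 0.2x the median
    object area found in this image.
    """
    if cube.kind != "reflectance":
        raise ValueError(f"expected a reflectance cube, got kind={cube.kind!r}")
    img = cube.data[:, :, band] if band is not None else cube.data.mean(axis=2)
    if np.ptp(img) == 0:
        raise SegmentationError("image is constant; no objects found")
    fg = img > threshold_otsu(img)
    if closing_radius > 0:
        # closing heals 1-px noise gaps; it defines connectivity only, the
        # pixel support stays the raw threshold so no background leaks in
        closed = binary_closing(fg, disk(closing_radius))
        lab = cc_label(closed, connectivity=2) * fg
    else:
        lab = cc_label(fg, connectivity=2)
    props = regionprops(lab)
    if not props:
        raise SegmentationError("no objects found above threshold")
    areas = np.array([p.area for p in props])
    if min_area is None:
        min_area = 0.2 * np.median(areas)
    keep = [p for p in props if p.area >= min_area]
    if not keep:
        raise SegmentationError(
            f"all {len(props)} objects smaller than min_area={min_area:.0f}"
        )
    centroids = np.array([p.centroid for p in keep])
    heights = np.array([p.bbox[2] - p.bbox[0] for p in keep])
    rank, row_of = _reading_order(centroids, heights)
    out = np.zeros_like(lab, dtype=np.int32)
    nrows, ncols = lab.shape
    border, counts = [], []
    for new_id, idx in enumerate(rank, start=1):
        p = keep[idx]
        out[lab == p.label] = new_id
        r0, c0, r1, c1 = p.bbox
        border.append(r0 == 0 or c0 == 0 or r1 == nrows or c1 == ncols)
        counts.append(p.area)
    return LabelMap(labels=out,
                    centroids=centroids[rank],
                    pixel_counts=np.array([keep[i].area for i in rank]),
                    rows=row_of[rank],
                    border_touching=np.array(border))


def extract_mean_spectra(cube: Hypercube, labels: LabelMap,
                         meta: pd.DataFrame | None = None,
                         stat: str = "geometric") -> SpectraTable:
    """One row per label: the mean spectrum over that label's pixels.

    For reflectance cubes the default is the geometric mean — i.e. the
    arithmetic mean *absorbance* spectrum mapped back to reflectance,
    the convention under which per-bean prediction from the mean
    spectrum commutes with averaging pixel-level log(1/R) predictions.
    ``stat="arithmetic"`` averages reflectance directly.
    """
    if labels.labels.shape != cube.shape[:2]:
        raise ValueError("label map does not match cube spatial dimensions")
    n = labels.n_objects
    X = np.empty((n, cube.n_bands))
    counts = np.empty(n, dtype=int)
    geometric = stat == "geometric" and cube.kind == "reflectance"
    for k in range(1, n + 1):
        mask = labels.labels == k
        if not mask.any():
            raise SegmentationError(f"label {k} has no pixels")
        px = cube.data[mask]
        if geometric:
            X[k - 1] = 10.0 ** np.log10(np.maximum(px, ABSORBANCE_FLOOR)).mean(axis=0)
        else:
            X[k - 1] = px.mean(axis=0)
        counts[k - 1] = mask.sum()
    if meta is None:
        meta = pd.DataFrame({"bean_id": np.arange(1, n + 1)})
    else:
        meta = meta.reset_index(drop=True)
        if len(meta) != n:
            raise ValueError(f"meta has {len(meta)} rows for {n} labels")
    meta = meta.copy()
    meta["n_pixels"] = counts
    return SpectraTable(X, cube.wavelengths, meta)


def pair_sides(side1: LabelMap, side2: LabelMap, bean_ids=None,
               mirror_flip: bool = False) -> np.ndarray:
    """Match side-2 labels to side-1 bean identities by reading-order rank.

    Beans are assumed to keep their stage position between flips; with
    ``mirror_flip`` the column order reverses within each stage row
    (beans overturned about the vertical axis).  Returns an array
    mapping side-2 label k (index k-1) to the bean id of its side-1
    partner.  ``bean_ids`` defaults to side-1 labels 1..K.
    """
    if side1.n_objects != side2.n_objects:
        raise PairingError(
            f"side 1 has {side1.n_objects} objects, side 2 has {side2.n_objects}"
        )
    ids = np.asarray(bean_ids) if bean_ids is not None \
        else np.arange(1, side1.n_objects + 1)
    if not mirror_flip:
        return ids.copy()
    mapping = np.empty(side2.n_objects, dtype=ids.dtype)
    for row in np.unique(side2.rows):
        in_row = np.nonzero(side2.rows == row)[0]
        src = np.nonzero(side1.rows == row)[0]
        if in_row.size != src.size:
            raise PairingError(f"stage row {row} has unequal counts between sides")
        mapping[in_row] = ids[src[::-1]]
    return mapping
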