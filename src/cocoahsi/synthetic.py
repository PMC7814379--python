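"""Synthetic single-bean hyperspectral scenes with known fat truth.

Emulates a two-side, multi-batch SWIR imaging study of whole cocoa
beans: each scene holds ten elliptical beans on a dark stage, rendered
from a small linear-mixture model in absorbance space,

    A(px, lam) = (c_px/100) * eps_fat(lam)
               + (1 - c_px/100) * eps_matrix(lam)
               + (m/100) * eps_water(lam) + baseline(lam)

where ``c_px`` is the pixel's fat concentration (% as-is, the bean value
plus a zero-mean radial/tilt gradient) and ``m`` the bean moisture.
Scatter is applied per pixel as ``a*A + b`` with ``a`` log-normal and
``b`` normal — exactly the multiplicative+additive family SNV and MSC
are designed to remove, which makes pre-treatment efficacy a testable
property rather than folklore.  Reflectance is R = 10**(-A) plus
additive sensor noise; raw detector counts are synthesised from R with
synthetic dark/white frames so the radiometric-calibration path is
exercised end to end.

The in-shell presentation stacks a shell layer on top of the nib signal:
attenuation of the nib absorbance, a per-bean random shell-thickness
term with its own absorption band near 1428 nm, and inflated scatter.
That is not radiative transfer — it is the minimal model that makes
in-shell calibrations measurably worse than shelled ones, which is the
qualitative behaviour the analysis must reproduce.

Reference fat values carry measurement noise (default sd 0.81% as-is,
the repeatability of an NMR/microwave reference method on ground nibs),
so the irreducible error floor of any calibration is known by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import LayoutError
from .hypercube import Hypercube, ReferenceFrames, calibrate_reflectance, exclude_bands
from .spectra import SpectraTable


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def _default_batch_means(n: int) -> np.ndarray:
    return np.linspace(48.0, 60.0, n)


def _default_batch_sds(n: int) -> np.ndarray:
    return np.linspace(1.0, 6.0, n)


@dataclass
class StudyDesign:
    """Sampling design of a multi-batch single-bean study.

    Defaults mirror a 17-batch x 10-bean x 2-side design (340 mean
    spectra from 170 beans), batch mean fat spread across ~48-60% as-is
    and within-batch sds from 1 to 6% so that at least one batch has a
    range below 4% and at least one above 10%.
    """

    n_batches: int = 17
    beans_per_batch: int = 10
    sides_per_bean: int = 2
    presentation: str = "shelled"          # or "in_shell"
    batch_fat_means: np.ndarray | None = None
    batch_fat_sds: np.ndarray | None = None
    fat_bounds: tuple = (40.0, 70.0)
    moisture_mean: float = 6.5
    moisture_sd: float = 0.7
    moisture_bounds: tuple = (4.0, 9.0)
    reference_noise_sd: float = 0.81       # fat reference repeatability, % as-is
    moisture_noise_sd: float = 0.2         # moisture reference repeatability, %
    seed: int = 0

    def __post_init__(self):
        if min(self.n_batches, self.beans_per_batch, self.sides_per_bean) < 1:
            raise ValueError("counts must be positive")
        if self.presentation not in ("shelled", "in_shell"):
            raise ValueError(f"unknown presentation {self.presentation!r}")
        if self.batch_fat_means is None:
            self.batch_fat_means = _default_batch_means(self.n_batches)
        if self.batch_fat_sds is None:
            self.batch_fat_sds = _default_batch_sds(self.n_batches)
        self.batch_fat_means = np.asarray(self.batch_fat_means, dtype=float)
        self.batch_fat_sds = np.asarray(self.batch_fat_sds, dtype=float)
        if self.batch_fat_means.size != self.n_batches:
            raise ValueError("need one fat mean per batch")
        if self.batch_fat_sds.size != self.n_batches:
            raise ValueError("need one fat sd per batch")
        if not np.all((self.batch_fat_means > 0) & (self.batch_fat_means < 100)):
            raise ValueError("batch fat means must lie in (0, 100)")

    @property
    def n_beans(self) -> int:
        return self.n_batches * self.beans_per_batch

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["batch_fat_means"] = [float(v) for v in self.batch_fat_means]
        d["batch_fat_sds"] = [float(v) for v in self.batch_fat_sds]
        d["fat_bounds"] = list(self.fat_bounds)
        d["moisture_bounds"] = list(self.moisture_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("fat_bounds", "moisture_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SceneParams:
    """Geometry, optics and noise of one rendered scene."""

    n_rows: int = 64
    n_cols: int = 64
    grid: tuple = (2, 5)                   # bean grid: rows x cols = capacity
    semi_axis_row: float = 10.0            # bean half-length along scan axis, px
    semi_axis_col: float = 4.2
    position_jitter: float = 0.8           # keeps inter-bean gaps > 2 px
    gradient_amplitude: float = 2.0        # max |within-bean fat deviation|, % fat
    sigma_a: float = 0.10                  # log-sd of multiplicative scatter
    sigma_b: float = 0.04                  # sd of additive scatter, absorbance
    sigma_n: float = 0.003                 # additive sensor noise on reflectance
    background_reflectance: float = 0.05
    n_bands: int = 256
    wavelength_range: tuple = (980.0, 2500.0)
    n_junk_bands: int = 16                 # leading low-sensitivity detector bands
    junk_noise: float = 0.05
    # in-shell rendering: measured reflectance is the nib signal after a
    # two-pass transmission through the testa PLUS a surface-reflection
    # term, R = T^2 * R_nib + R_surf.  The sum in reflectance makes the
    # recorded log(1/R) nonlinear in the nib absorbance, which is the
    # degradation a shell actually causes and which no linear
    # pre-treatment can undo.
    shell_thickness_mean: float = 1.0
    shell_thickness_sd: float = 0.35
    shell_scale: float = 0.25              # shell absorbance per unit thickness
    shell_surface_mean: float = 0.10       # mean shell surface reflectance
    shell_surface_sd: float = 0.03         # per-bean surface variability
    shell_fat_mean: float = 0.15           # lipid-like fraction of shell absorbance
    shell_fat_sd: float = 0.08             # per-bean variability of that fraction
    shell_sigma_a: float = 0.20            # scatter inflation under shell

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(*self.wavelength_range, self.n_bands)

    @property
    def capacity(self) -> int:
        return self.grid[0] * self.grid[1]

    def noise_free(self) -> "SceneParams":
        """Copy with every stochastic term switched off (gradient kept)."""
        return replace(self, sigma_a=0.0, sigma_b=0.0, sigma_n=0.0,
                       junk_noise=0.0, position_jitter=0.0)


# --------------------------------------------------------------------------
# endmembers
# --------------------------------------------------------------------------

def _gauss(wl: np.ndarray, centre: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - centre) / width) ** 2)


@dataclass
class Endmembers:
    """Absorptivity spectra of the scene constituents on the cube's grid."""

    wavelengths: np.ndarray
    fat: np.ndarray
    water: np.ndarray
    matrix: np.ndarray
    shell: np.ndarray
    baseline: np.ndarray

    def __post_init__(self):
        for name in ("fat", "water", "matrix", "shell", "baseline"):
            arr = getattr(self, name)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} not on the wavelength grid")
            if np.any(arr < 0):
                raise ValueError(f"{name} absorptivity has negative values")


#: (centre nm, width nm, height) of the lipid C-H overtone/combination bands
FAT_PEAKS = ((1210.0, 18.0, 0.45), (1725.0, 16.0, 0.80), (1765.0, 16.0, 0.55),
             (2310.0, 14.0, 1.00), (2345.0, 14.0, 0.70))
WATER_PEAKS = ((1450.0, 45.0, 0.60), (1940.0, 55.0, 1.00))
SHELL_PEAK = (1428.0, 20.0, 0.50)


def default_endmembers(wavelengths: np.ndarray) -> Endmembers:
    """Construct the default constituent spectra on ``wavelengths`` (nm).

    Fat bands sit at the C-H first overtone (1725/1765 nm), its second
    overtone (1210 nm) and the 2310/2345 nm combination region; water at
    the 1450 and 1940 nm O-H bands; the non-fat matrix is broad and
    smooth; shell adds a broad baseline plus a band near 1428 nm.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.min() < 950.0 or wl.max() > 2550.0:
        raise ValueError("wavelength grid outside the ~980-2500 nm SWIR range")
    fat = sum(_gauss(wl, *p) for p in FAT_PEAKS)
    water = sum(_gauss(wl, *p) for p in WATER_PEAKS)
    matrix = (0.45 + _gauss(wl, 1500.0, 380.0, 0.30) + _gauss(wl, 2100.0, 320.0, 0.20))
    shell = 0.30 + 0.10 * (wl - wl.min()) / (wl.max() - wl.min()) + _gauss(wl, *SHELL_PEAK)
    baseline = np.full_like(wl, 0.25)
    return Endmembers(wl, fat, water, matrix, shell, baseline)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def as_is_to_dmb(fat_as_is, moisture):
    """Convert fat % per wet weight to % per dry matter."""
    fat_as_is = np.asarray(fat_as_is, dtype=float)
    moisture = np.asarray(moisture, dtype=float)
    if np.any(moisture >= 100) or np.any(moisture < 0):
        raise ValueError("moisture must lie in [0, 100)")
    return 100.0 * fat_as_is / (100.0 - moisture)


@dataclass
class GroundTruth:
    """Per-bean truth and noisy reference measurements.

    ``beans`` has one row per bean: batch, bean_id, true fat_as_is,
    moisture, fat_dmb, plus ``ref_*`` columns — the values a reference
    laboratory would report (truth plus measurement noise), which is
    what calibrations are trained against.
    """

    beans: pd.DataFrame
    design: StudyDesign


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    while True:
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum())) if np.isscalar(mean) \
            else rng.normal(np.broadcast_to(mean, out.shape)[bad], sd)


def sample_beans(design: StudyDesign) -> GroundTruth:
    """Draw per-bean fat and moisture truth plus noisy reference values."""
    rng = np.random.default_rng([design.seed, 0])
    lo, hi = design.fat_bounds
    rows = []
    bean_id = 0
    for b in range(design.n_batches):
        fat = _truncated_normal(rng, design.batch_fat_means[b],
                                design.batch_fat_sds[b], lo, hi,
                                design.beans_per_batch)
        moist = _truncated_normal(rng, design.moisture_mean, design.moisture_sd,
                                  *design.moisture_bounds, size=design.beans_per_batch)
        for j in range(design.beans_per_batch):
            bean_id += 1
            rows.append((b + 1, bean_id, fat[j], moist[j]))
    df = pd.DataFrame(rows, columns=["batch", "bean_id", "fat_as_is", "moisture"])
    df["fat_dmb"] = as_is_to_dmb(df["fat_as_is"], df["moisture"])
    ref_rng = np.random.default_rng([design.seed, 1])
    df["ref_fat_as_is"] = df["fat_as_is"] + ref_rng.normal(
        0.0, design.reference_noise_sd, len(df))
    df["ref_moisture"] = np.clip(
        df["moisture"] + ref_rng.normal(0.0, design.moisture_noise_sd, len(df)),
        0.0, 99.0)
    df["ref_fat_dmb"] = as_is_to_dmb(df["ref_fat_as_is"], df["ref_moisture"])
    return GroundTruth(beans=df, design=design)


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass
class SceneTruth:
    """What the renderer knows: labels, identities and per-pixel fat."""

    labels: np.ndarray            # int image, 0 background, k = k-th bean placed
    bean_ids: np.ndarray          # label k -> bean_id, index k-1
    fat_map: np.ndarray           # per-pixel c_px (% as-is), NaN on background
    reflectance: Hypercube        # the exact (noisy) R the raw counts encode


def _reference_frames(scene: SceneParams) -> ReferenceFrames:
    wl = scene.wavelengths
    dark = 96.0 + 8.0 * np.sin(wl / 300.0)
    span = 2600.0 * (0.70 + 0.30 * np.exp(-0.5 * ((wl - 1600.0) / 600.0) ** 2))
    span[:scene.n_junk_bands] *= 0.05      # warm-up bands barely respond
    return ReferenceFrames(dark=dark, white=dark + span)


def _bean_gradient(rng: np.random.Generator, rr, cc, amplitude: float) -> np.ndarray:
    """Zero-mean within-bean fat deviation: radial dome plus a random tilt."""
    if amplitude == 0 or rr.size < 2:
        return np.zeros(rr.size)
    r2 = rr ** 2 + cc ** 2
    dome = 1.0 - 2.0 * r2 / max(r2.max(), 1e-12)
    theta = rng.uniform(0, 2 * np.pi)
    tilt = np.cos(theta) * rr + np.sin(theta) * cc
    tilt = tilt / max(np.abs(tilt).max(), 1e-12)
    q = dome + 0.6 * tilt
    q -= q.mean()
    peak = np.abs(q).max()
    return amplitude * q / peak if peak > 0 else q


def render_scan(truth: GroundTruth, endmembers: Endmembers, scene: SceneParams,
                batch: int, side: int, presentation: str | None = None):
    """Render one batch scan as raw counts.

    Returns ``(raw cube, reference frames, scene truth)``.  ``side`` (1 or
    2) reseeds the within-bean gradient and all noise, emulating the
    flip-and-rescan protocol; bean truth values are shared between sides.
    """
    presentation = presentation or truth.design.presentation
    beans = truth.beans[truth.beans["batch"] == batch]
    if len(beans) == 0:
        raise ValueError(f"no beans in batch {batch}")
    if len(beans) > scene.capacity:
        raise LayoutError(f"{len(beans)} beans exceed grid capacity {scene.capacity}")
    if side not in (1, 2):
        raise ValueError("side must be 1 or 2")

    rng = np.random.default_rng([truth.design.seed, 2, int(batch), int(side)])
    wl = scene.wavelengths
    if not np.allclose(wl, endmembers.wavelengths):
        raise ValueError("endmembers not on the scene wavelength grid")
    nb = scene.n_bands
    labels = np.zeros((scene.n_rows, scene.n_cols), dtype=np.int32)
    fat_map = np.full((scene.n_rows, scene.n_cols), np.nan)
    moist_map = np.zeros((scene.n_rows, scene.n_cols))
    shell_map = np.zeros((scene.n_rows, scene.n_cols))

    grid_r, grid_c = scene.grid
    cell_r = scene.n_rows / grid_r
    cell_c = scene.n_cols / grid_c
    rr_img, cc_img = np.mgrid[0:scene.n_rows, 0:scene.n_cols]

    shell_rng = np.random.default_rng([truth.design.seed, 3, int(batch)])
    thickness = _truncated_normal(shell_rng, scene.shell_thickness_mean,
                                  scene.shell_thickness_sd, 0.1, 3.0, len(beans))
    surface = _truncated_normal(shell_rng, scene.shell_surface_mean,
                                scene.shell_surface_sd, 0.01, 0.5, len(beans))
    # residual lipid in / under the testa: a per-bean fat-like component of
    # the shell absorbance, uncorrelated with the nib's fat content
    shell_fat = _truncated_normal(shell_rng, scene.shell_fat_mean,
                                  scene.shell_fat_sd, 0.0, 1.0, len(beans))
    surf_map = np.zeros((scene.n_rows, scene.n_cols))
    shell_fat_map = np.zeros((scene.n_rows, scene.n_cols))

    for k, (_, bean) in enumerate(beans.iterrows()):
        gr, gc = divmod(k, grid_c)
        cr = (gr + 0.5) * cell_r + rng.uniform(-scene.position_jitter, scene.position_jitter)
        cc0 = (gc + 0.5) * cell_c + rng.uniform(-scene.position_jitter, scene.position_jitter)
        ar = scene.semi_axis_row * rng.uniform(0.9, 1.03)
        ac = scene.semi_axis_col * rng.uniform(0.9, 1.03)
        mask = (((rr_img - cr) / ar) ** 2 + ((cc_img - cc0) / ac) ** 2) <= 1.0
        if (labels[mask] != 0).any():
            raise LayoutError(f"bean {k + 1} overlaps a previous placement")
        labels[mask] = k + 1
        rr_rel = (rr_img[mask] - cr) / ar
        cc_rel = (cc_img[mask] - cc0) / ac
        grad = _bean_gradient(rng, rr_rel, cc_rel, scene.gradient_amplitude)
        fat_map[mask] = np.clip(bean["fat_as_is"] + grad, 0.0, 100.0)
        moist_map[mask] = bean["moisture"]
        shell_map[mask] = thickness[k]
        surf_map[mask] = surface[k]
        shell_fat_map[mask] = shell_fat[k]

    fg = labels > 0
    n_fg = int(fg.sum())
    # linear mixture in absorbance
    c = fat_map[fg][:, None] / 100.0
    A = (c * endmembers.fat + (1.0 - c) * endmembers.matrix
         + (moist_map[fg][:, None] / 100.0) * endmembers.water + endmembers.baseline)
    sigma_a = scene.shell_sigma_a if presentation == "in_shell" else scene.sigma_a
    if sigma_a > 0:
        a = rng.lognormal(0.0, sigma_a, size=n_fg)[:, None]
    else:
        a = 1.0
    b = rng.normal(0.0, scene.sigma_b, size=n_fg)[:, None] if scene.sigma_b > 0 else 0.0
    A = a * A + b

    R_fg = 10.0 ** (-A)
    if presentation == "in_shell":
        t_px = shell_map[fg][:, None]
        shell_abs = endmembers.shell + shell_fat_map[fg][:, None] * endmembers.fat
        transmission2 = 10.0 ** (-2.0 * t_px * scene.shell_scale * shell_abs)
        R_fg = transmission2 * R_fg + surf_map[fg][:, None]

    R = np.empty((scene.n_rows, scene.n_cols, nb))
    R[~fg] = scene.background_reflectance
    R[fg] = R_fg
    if scene.sigma_n > 0:
        R = R + rng.normal(0.0, scene.sigma_n, size=R.shape)
    if scene.junk_noise > 0:
        R[:, :, :scene.n_junk_bands] += rng.normal(
            0.0, scene.junk_noise, size=(scene.n_rows, scene.n_cols, scene.n_junk_bands))
    R = np.clip(R, 0.0, 1.5)

    refs = _reference_frames(scene)
    raw = Hypercube(refs.dark + R * (refs.white - refs.dark), wl, kind="raw",
                    metadata={"batch": batch, "side": side,
                              "presentation": presentation})
    r_cube = Hypercube(R, wl, kind="reflectance",
                       metadata={"batch": batch, "side": side})
    scene_truth = SceneTruth(labels=labels, bean_ids=beans["bean_id"].to_numpy(),
                             fat_map=fat_map, reflectance=r_cube)
    return raw, refs, scene_truth


# --------------------------------------------------------------------------
# whole-study generation
# --------------------------------------------------------------------------

@dataclass
class Scan:
    raw: Hypercube
    refs: ReferenceFrames
    truth: SceneTruth
    batch: int
    side: int


def mean_spectra_from_truth(cube: Hypercube, scene_truth: SceneTruth) -> np.ndarray:
    """Per-bean mean spectra over the renderer's own label masks.

    Geometric mean of reflectance = arithmetic mean absorbance, the same
    convention the segmentation module uses for extracted spectra.
    """
    out = np.empty((scene_truth.bean_ids.size, cube.n_bands))
    for k in range(scene_truth.bean_ids.size):
        px = cube.data[scene_truth.labels == k + 1]
        out[k] = 10.0 ** np.log10(np.maximum(px, 1e-4)).mean(axis=0)
    return out


def generate_study(design: StudyDesign, scene: SceneParams | None = None,
                   endmembers: Endmembers | None = None,
                   truth: GroundTruth | None = None,
                   keep_scans: bool = True):
    """Render the full study: every batch, both sides.

    Returns ``(scans, table, truth)`` where ``table`` is the per-side
    mean-spectrum :class:`SpectraTable` (computed over the renderer's own
    masks after dark/white calibration and leading-band exclusion) with
    the noisy reference values attached — the input the calibration
    stage consumes.  With ``keep_scans=False`` the scan list is empty
    (saves memory when only the table is needed).
    """
    scene = scene or SceneParams()
    endmembers = endmembers or default_endmembers(scene.wavelengths)
    truth = truth or sample_beans(design)
    scans: list[Scan] = []
    rows = []
    spectra = []
    for batch in range(1, design.n_batches + 1):
        for side in range(1, design.sides_per_bean + 1):
            raw, refs, st = render_scan(truth, endmembers, scene, batch, side,
                                        presentation=design.presentation)
            cube = exclude_bands(calibrate_reflectance(raw, refs), scene.n_junk_bands)
            means = mean_spectra_from_truth(cube, st)
            spectra.append(means)
            beans = truth.beans.set_index("bean_id").loc[st.bean_ids]
            for k, bid in enumerate(st.bean_ids):
                rows.append({
                    "bean_id": int(bid), "batch": int(batch), "side": int(side),
                    "presentation": design.presentation,
                    "fat_as_is": float(beans.loc[bid, "ref_fat_as_is"]),
                    "fat_dmb": float(beans.loc[bid, "ref_fat_dmb"]),
                    "moisture": float(beans.loc[bid, "ref_moisture"]),
                    "n_pixels": int((st.labels == k + 1).sum()),
                })
            if keep_scans:
                scans.append(Scan(raw, refs, st, batch, side))
            wavelengths = cube.wavelengths
    table = SpectraTable(np.vstack(spectra), wavelengths, pd.DataFrame(rows))
    return scans, table, truth
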