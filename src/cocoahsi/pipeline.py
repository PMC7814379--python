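"""End-to-end orchestration: simulate -> calibrate -> map -> sort.

One YAML config drives every stage; every random draw takes a named
seed derived from a master seed via a fixed counter scheme (the
generator uses ``[seed, stage, ...]`` seed sequences, the pipeline
derives split/CV/sorting seeds as ``master + fixed offsets``), so a run
is reproducible stage by stage and byte-for-byte overall.  Logs are
key=value lines for easy grepping.
"""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .imaging import predict_per_bean, predict_pixelwise, render
from .pls import reports_to_frame, run_calibration
from .preprocessing import PRETREATMENTS
from .segmentation import extract_mean_spectra, segment_beans
from .sorting import compare_fractions, enrichment, select_fractions
from .synthetic import (SceneParams, StudyDesign, default_endmembers,
                        generate_study, render_scan, sample_beans)
from .wavelength_selection import refit_multispectral, select_top_bands

# seed offsets for the pipeline's own random stages
SEED_SPLIT, SEED_SORT = 101, 202


def describe_batches(table: pd.DataFrame, value_col: str = "fat_as_is",
                     batch_col: str = "batch") -> pd.DataFrame:
    """Per-batch descriptive statistics plus an overall row."""
    if len(table) == 0:
        raise ValueError("empty table")
    def _stats(v):
        v = np.asarray(v, dtype=float)
        return pd.Series({
            "n": v.size, "mean": v.mean(),
            "sd": v.std(ddof=1) if v.size > 1 else 0.0,
            "min": v.min(), "max": v.max(), "range": np.ptp(v),
        })
    per_batch = (table.groupby(batch_col)[value_col].apply(_stats).unstack()
                 .reset_index())
    overall = _stats(table[value_col])
    overall[batch_col] = "overall"
    return pd.concat([per_batch, overall.to_frame().T[per_batch.columns]],
                     ignore_index=True)


@dataclass
class PipelineConfig:
    design: StudyDesign = field(default_factory=StudyDesign)
    scene: SceneParams = field(default_factory=SceneParams)
    pretreatments: tuple = PRETREATMENTS
    bases: tuple = ("as_is", "dmb")
    presentations: tuple = ("shelled", "in_shell")
    ratio: float = 0.7
    folds: int = 10
    max_lv: int = 15
    n_select_bands: int = 4
    sort_k: int = 3
    out_dir: str = "run"
    seed: int = 0

    _KNOWN = {"design", "scene", "pretreatments", "bases", "presentations",
              "ratio", "folds", "max_lv", "n_select_bands", "sort_k",
              "out_dir", "seed"}

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bad = set(raw) - cls._KNOWN
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}", keys=bad)
        kwargs = dict(raw)
        if "design" in kwargs:
            kwargs["design"] = StudyDesign(**kwargs["design"])
        if "scene" in kwargs:
            kwargs["scene"] = SceneParams(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in kwargs["scene"].items()})
        for key in ("pretreatments", "bases", "presentations"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        unknown_pt = set(cfg.pretreatments) - set(PRETREATMENTS)
        if unknown_pt:
            raise ConfigError(f"unknown pretreatments: {sorted(unknown_pt)}",
                              keys=unknown_pt)
        if not (0 < cfg.ratio < 1):
            raise ConfigError("ratio must lie in (0, 1)", keys={"ratio"})
        return cfg


class _Log:
    def __init__(self, path):
        self.path = path
        self._fh = open(path, "w")

    def __call__(self, **kv):
        line = " ".join(f"{k}={v}" for k, v in kv.items())
        self._fh.write(line + "\n")
        self._fh.flush()

    def close(self):
        self._fh.close()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole study; writes models, reports and images to ``out_dir``.

    Returns a dict with the comparison table (one row per pre-treatment
    x presentation x basis), the batch descriptives, the sorting report
    and paths of everything written.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    log = _Log(os.path.join(cfg.out_dir, "run.log"))
    t0 = time.perf_counter()
    results: dict = {"paths": {}}
    try:
        truth = sample_beans(cfg.design)
        log(stage="truth", n_beans=len(truth.beans), seed=cfg.design.seed)

        desc = describe_batches(truth.beans.assign(
            fat_as_is=truth.beans["ref_fat_as_is"]))
        desc_path = os.path.join(cfg.out_dir, "batch_statistics.csv")
        desc.to_csv(desc_path, index=False)
        results["batch_statistics"] = desc
        results["paths"]["batch_statistics"] = desc_path

        reports = []
        tables = {}
        best = {}
        for presentation in cfg.presentations:
            design = StudyDesign(**{**cfg.design.__dict__,
                                    "presentation": presentation})
            t = time.perf_counter()
            _, table, _ = generate_study(design, cfg.scene, truth=truth,
                                         keep_scans=False)
            tables[presentation] = table
            log(stage="simulate", presentation=presentation,
                n_spectra=len(table), n_bands=table.wavelengths.size,
                seconds=f"{time.perf_counter() - t:.1f}")
            for basis in cfg.bases:
                for pt in cfg.pretreatments:
                    model, report, extras = run_calibration(
                        table, pretreatment=pt, basis=basis, ratio=cfg.ratio,
                        folds=cfg.folds, max_lv=cfg.max_lv,
                        seed=cfg.seed + SEED_SPLIT)
                    report.pretreatment = pt
                    reports.append((presentation, report, model, extras))
                    log(stage="calibrate", presentation=presentation,
                        basis=basis, pretreatment=pt, lv=report.n_lv,
                        n_cal=report.n_cal, n_val=report.n_val,
                        r2_p=f"{report.r2_p:.3f}", rmsep=f"{report.rmsep:.3f}")

        rows = []
        for presentation, report, _, _ in reports:
            row = report.as_row()
            row["Presentation"] = presentation
            rows.append(row)
        comparison = pd.DataFrame(rows)
        comp_path = os.path.join(cfg.out_dir, "model_comparison.csv")
        comparison.to_csv(comp_path, index=False, float_format="%.6f")
        results["comparison"] = comparison
        results["paths"]["comparison"] = comp_path

        # best shelled as-is model drives imaging, band selection, sorting
        shelled = [(rep, mod, ext) for pres, rep, mod, ext in reports
                   if pres == "shelled" and rep.basis == "as_is"]
        rep, model, extras = max(shelled, key=lambda t: t[0].r2_p)
        best["report"], best["model"] = rep, model
        log(stage="best_model", pretreatment=rep.pretreatment,
            r2_p=f"{rep.r2_p:.3f}", rpd_p=f"{rep.rpd_p:.2f}")
        model_path = os.path.join(cfg.out_dir, "best_model.yaml")
        model.to_yaml(model_path)
        results["paths"]["model"] = model_path

        # band selection (deployment mode: log1r only)
        table = tables["shelled"]
        bands = select_top_bands(model, cfg.n_select_bands)
        ms_model, ms_report, _ = refit_multispectral(
            table, bands, basis="as_is", ratio=cfg.ratio, folds=cfg.folds,
            seed=cfg.seed + SEED_SPLIT)
        ms_row = ms_report.as_row()
        ms_row["Presentation"] = "shelled"
        ms_path = os.path.join(cfg.out_dir, "multispectral.csv")
        pd.DataFrame([ms_row]).to_csv(ms_path, index=False, float_format="%.6f")
        results["multispectral"] = ms_report
        results["paths"]["multispectral"] = ms_path
        log(stage="select_bands", n_bands=len(bands),
            wavelengths=",".join(f"{model.wavelengths[j]:.0f}" for j in bands),
            r2_p=f"{ms_report.r2_p:.3f}")

        # chemical images: re-render the first shelled scan
        from .hypercube import calibrate_reflectance, exclude_bands
        endm = default_endmembers(cfg.scene.wavelengths)
        raw1, refs1, _ = render_scan(truth, endm, cfg.scene, batch=1, side=1,
                                     presentation="shelled")
        cube = exclude_bands(calibrate_reflectance(raw1, refs1),
                             cfg.scene.n_junk_bands)
        labels = segment_beans(cube)
        y_cal = table.y("as_is")
        limits = (float(y_cal.min()), float(y_cal.max()))
        chem_px = predict_pixelwise(cube, labels, model, scale_limits=limits)
        chem_bean = predict_per_bean(cube, labels, model, scale_limits=limits)
        px_path = os.path.join(cfg.out_dir, "chemical_image_pixel.png")
        bean_path = os.path.join(cfg.out_dir, "chemical_image_bean.png")
        render(chem_px, px_path, annotate=False)
        render(chem_bean, bean_path)
        chem_bean.per_bean.to_csv(
            os.path.join(cfg.out_dir, "per_bean_predictions.csv"), index=False)
        results["chemical_images"] = {"pixel": chem_px, "bean": chem_bean}
        results["paths"]["chemical_image_pixel"] = px_path
        results["paths"]["chemical_image_bean"] = bean_path
        log(stage="map", n_beans=labels.n_objects)

        # sorting trial on an extra batch
        sort_design = StudyDesign(
            n_batches=1, beans_per_batch=10, sides_per_bean=1,
            batch_fat_means=[float(np.mean(cfg.design.batch_fat_means))],
            batch_fat_sds=[3.0],
            reference_noise_sd=cfg.design.reference_noise_sd,
            seed=cfg.seed + SEED_SORT)
        sort_truth = sample_beans(sort_design)
        raw, refs, st = render_scan(sort_truth, endm, cfg.scene, batch=1, side=1,
                                    presentation="shelled")
        s_cube = exclude_bands(calibrate_reflectance(raw, refs),
                               cfg.scene.n_junk_bands)
        s_labels = segment_beans(s_cube)
        chem = predict_per_bean(s_cube, s_labels, model)
        per_bean = chem.per_bean.copy()
        per_bean["bean_id"] = st.bean_ids[:len(per_bean)]
        assignment = select_fractions(per_bean, cfg.sort_k, cfg.sort_k,
                                      cfg.sort_k, seed=cfg.seed + SEED_SORT)
        merged = assignment.merge(
            sort_truth.beans[["bean_id", "ref_fat_as_is"]], on="bean_id")
        merged = merged.rename(columns={"ref_fat_as_is": "fat_as_is"})
        comparison_sort = compare_fractions(merged)
        enrich = enrichment(merged)
        sort_path = os.path.join(cfg.out_dir, "sorting_report.csv")
        comparison_sort["summary"].to_csv(sort_path, index=False)
        results["sorting"] = {"summary": comparison_sort["summary"],
                              "p_values": comparison_sort["p_values"],
                              "enrichment": enrich}
        results["paths"]["sorting"] = sort_path
        log(stage="sort", high_minus_low=f"{enrich['high_minus_low']:.2f}",
            letters="".join(comparison_sort["letters"].values()))

        log(stage="done", seconds=f"{time.perf_counter() - t0:.1f}")
    finally:
        log.close()
    return results
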