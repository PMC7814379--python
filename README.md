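# cocoahsi

Hyperspectral chemical imaging of single cocoa beans: calibrate SWIR
(~980–2500 nm) hypercubes against per-bean total-fat references with
partial least squares, map fat at pixel and bean level, and sort beans
by predicted fat.

## The problem

Cocoa butter is roughly half of a bean's weight and the main driver of
its commercial value, yet fat content varies widely *within* commercial
batches — some batches span less than 4 % as-is, others more than 10 %.
Classical fat analysis (solvent extraction, NMR on ground nibs) is
destructive and batch-averaged, so it cannot see single-bean
variability, and it requires shelling and grinding. A pushbroom SWIR
imaging spectrograph scans ten beans at a time and yields a full
reflectance spectrum per pixel; chemometric calibration turns those
spectra into a per-bean (or per-pixel) fat prediction, non-destructively,
for shelled nibs and — with reduced accuracy — whole in-shell beans.

This package implements that workflow end to end for analysts and
method developers:

1. **hypercube_io** — ENVI raster I/O, dark/white radiometric
   calibration `R = (S − D)/(W − D)`, leading-band exclusion
   (256 → 240 useful bands), log(1/R) conversion.
2. **synthetic data** — a generator that renders multi-batch,
   two-sided scans of elliptical beans from a linear mixture model in
   absorbance with known fat truth, multiplicative+additive scatter,
   sensor noise, reference-measurement noise, and an in-shell variant
   with a physically motivated shell layer (see `docs/methods.md`).
3. **segmentation** — Otsu thresholding of the band-mean image,
   connected components, reading-order sample numbering, per-bean mean
   spectra, pairing of the two scanned sides.
4. **preprocessing** — the standard pre-treatment battery as fit/apply
   operators: log(1/R), unit-vector normalisation, MSC, SNV,
   Savitzky–Golay 1st/2nd derivatives, SNV + 1st derivative.
5. **pls_regression** — PLS1 by NIPALS with bean-grouped 70:30 holdout,
   bean-grouped 10-fold cross-validation, parsimonious latent-variable
   selection, and the usual metric suite
   (R², RMSEC/RMSECV/RMSEP, RPD = sd(reference)/RMSE, paired t-test).
6. **wavelength_selection** — reduction to a few bands for a
   multispectral instrument, ranked by sd-weighted |β|.
7. **chemical_imaging** — per-pixel and per-bean fat maps with rendered
   PNG output.
8. **sorting** — high/low/average fraction selection by predicted fat,
   Welch pairwise tests with compact letter display, enrichment.

The core statistic is the PLS1 regression vector **β**: a calibration
predicts fat as `ŷ = xᵀβ + β₀` from the pre-treated spectrum *x*,
with β assembled from the NIPALS weights as
`β = W(PᵀW)⁻¹q` and the centring absorbed into β₀.

## Worked example

```python
from cocoahsi import StudyDesign, generate_study, run_calibration

design = StudyDesign(seed=1)                    # 17 batches x 10 beans x 2 sides
_, table, _ = generate_study(design, keep_scans=False)
model, report, _ = run_calibration(table, pretreatment="snv", seed=42)
print(f"n={len(table)} cal={report.n_cal} val={report.n_val}")
print(f"LV={report.n_lv}  R2_p={report.r2_p:.3f}  "
      f"RMSEP={report.rmsep:.3f}  RPD_P={report.rpd_p:.2f}")
```

prints

```
n=340 cal=238 val=102
LV=3  R2_p=0.956  RMSEP=0.831  RPD_P=4.81
```

Reading: 340 mean spectra (170 beans, both sides) split bean-wise
70:30 into 238 calibration and 102 validation rows; an SNV + 3-latent-
variable model predicts held-out beans with R² = 0.956 and an error of
0.83 % fat — close to the 0.81 % repeatability of the simulated
reference method, i.e. the calibration is at the floor the reference
values permit. RPD ≈ 4.8 is comfortably above the ≈2.5 conventionally
required for quantification.

The same from the shell:

```
cocoahsi simulate --out sim --seed 1
cocoahsi calibrate --spectra sim/spectra.csv --pretreat snv --seed 42
cocoahsi run-all --out run --seed 1       # full comparison table + images
```

`run-all` writes `model_comparison.csv` (7 pre-treatments × shelled /
in-shell × as-is / dry-matter basis), the best model as YAML, chemical
images (PNG + ENVI), batch descriptive statistics and a sorting report.

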