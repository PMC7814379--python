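# Methods

This note records the models, numerical choices and limitations behind
`cocoahsi`, in the order data flows through the pipeline.

## Radiometric calibration and band management

Raw pushbroom counts S are converted per pixel and band to reflectance
R = (S − D)/(W − D), with D and W the frame-averaged dark (shutter
closed) and white (PTFE standard) references. References are reduced
over the frame axis by the mean; per-column reference arrays are
supported for pushbroom column effects, but the default — and what the
generator produces — is a single per-band vector. R is clipped to
[0, 1.5]: specular highlights can exceed the PTFE standard, and 1.5
retains them without destabilising the subsequent log. Absorbance is
A = log10(1/R) with a floor of 1e-4 under R so background pixels cannot
produce infinities. The leading 16 of 256 detector bands fall outside
the sensitive range and are dropped *after* calibration (the order is
mathematically immaterial; the cube metadata records the exclusion).

ENVI I/O is implemented in-package (ASCII header + headerless binary,
BIL/BIP/BSQ, little-endian float32/uint16/float64); unknown header keys
are preserved verbatim on write, and floats are written in shortest
round-trip representation so read(write(cube)) is bit-identical.

## The synthetic study

The generator emulates a 17-batch × 10-bean × 2-side design (340 mean
spectra from 170 beans). Its defaults are the study conditions every
test and the acceptance script run under:

* **Fat truth.** Bean fat (% as-is) ~ Normal(batch mean, batch sd)
  truncated to [40, 70]; batch means linspace 48–60 %, batch sds
  linspace 1–6 %, which makes at least one batch range < 4 % and at
  least one > 10 % — the within-batch spread the method exists to
  exploit. Moisture ~ Normal(6.5, 0.7) % truncated to [4, 9];
  fat_dmb = 100·fat/(100 − moisture) exactly.
* **Reference noise.** Reported reference values are truth plus
  Normal(0, 0.81) % for fat (the repeatability of an NMR/microwave
  reference method on ground nibs) and Normal(0, 0.2) % for moisture.
  0.81 % is therefore the irreducible RMSEP floor of any calibration
  trained and scored on these references.
* **Scenes.** 64×64 px, ten elliptical beans on a 2×5 grid
  (semi-axes ≈ 10×4.2 px, jitter 0.8 px — jitter is bounded so
  inter-bean gaps stay above the 2 px a closing radius of 1 can
  bridge), dark stage background at R = 0.05, 256 bands over
  980–2500 nm of which the first 16 are low-sensitivity "junk" bands
  with extra noise, exercising the exclusion path.
* **Spectra.** Per-pixel absorbance is a linear mixture
  A = (c/100)·ε_fat + (1 − c/100)·ε_matrix + (m/100)·ε_water + baseline
  with Gaussian-peak endmembers: fat at 1210, 1725, 1765, 2310,
  2345 nm; water at 1450, 1940 nm; a broad smooth matrix; baseline
  0.25. c is the pixel fat concentration — the bean value plus a
  zero-mean radial-dome-plus-tilt gradient of amplitude 2 % fat,
  re-drawn for the second side (the flip-and-rescan protocol).
* **Scatter and noise.** Per-pixel scatter is applied in absorbance as
  a·A + b with a ~ LogNormal(0, 0.10) and b ~ Normal(0, 0.04) —
  exactly the multiplicative+additive family SNV and MSC are defined
  to remove, which makes pre-treatment efficacy a testable exactness
  property rather than folklore. Reflectance then gains additive
  sensor noise Normal(0, 0.003). Raw counts are synthesised back
  through synthetic dark/white frames so the calibration path is
  exercised end to end; with noise off the calibrated cube equals the
  rendered reflectance to float precision.
* **In-shell variant.** The measured reflectance is composed in
  reflectance space: R = T²·R_nib + R_surf, with two-pass shell
  transmission T² = 10^(−2·t·0.25·(ε_shell + f·ε_fat)), per-bean
  thickness t ~ Normal(1, 0.35) truncated positive, a per-bean
  surface-reflection term R_surf ~ Normal(0.10, 0.03), and a per-bean
  lipid-like fraction f ~ Normal(0.15, 0.08) of the shell absorbance
  (testa carries residual lipid and adhering nib material). The sum in
  reflectance makes log(1/R) nonlinear in the nib absorbance, and the
  f·ε_fat term is collinear with the analyte signature while
  uncorrelated with nib fat — together these degrade every linear
  calibration, reproducing the robust shelled > in-shell performance
  ordering. This is deliberately not radiative transfer; it is the
  minimal model with the right qualitative failure mode. Earlier,
  simpler shell models (fixed-shape additive term; spectrally flat or
  smooth multiplicative attenuation in absorbance) were discarded
  because PLS removes one extra linear interferent with one extra
  latent variable, and SNV is exactly invariant to per-spectrum
  scaling — they produced no reliable degradation.

What the generator does *not* emulate: real cocoa optical constants,
touching or overlapping beans, shape/size phenotypes, fermentation or
drying chemistry, detector nonlinearity and stray light. Passing tests
therefore demonstrate the *pipeline's* correctness and the qualitative
orderings above, not instrument-level accuracy on real beans.

## Segmentation and spectrum extraction

Beans are detected by Otsu's threshold on the band-mean reflectance
image (parameter-free and invariant to global illumination scaling; a
single-band override exists), 8-connected components, and a minimum
area of 0.2× the median object area of that image. A morphological
closing of radius 1 defines *connectivity only* — it heals 1-px noise
gaps without admitting background pixels into an object's support,
which matters because a stage pixel at R ≈ 0.05 in a bean mean would
bias its spectrum badly. Sample numbers are assigned in reading order:
centroid rows binned at half the median object height, then sorted by
column — the positional numbering that lets several beans share a
hypercube. Side pairing matches reading-order ranks, with a
`mirror_flip` option that reverses within-row order for beans
overturned about the vertical axis.

Per-bean mean spectra are **geometric** means of reflectance, i.e.
arithmetic mean absorbance mapped back through 10^(−Ā). Under this
convention prediction from the bean's mean spectrum is *identical* (to
float precision) to the mean of pixel-level predictions whenever the
pre-treatment chain is linear in absorbance (log(1/R) alone), which is
both the algebraically honest reading of "apply β to the average
spectrum" and an acceptance-tested identity. Arithmetic averaging is
available by flag.

## Pre-treatments

All seven chains operate on absorbance by default (the baseline chain
is log(1/R) itself). SNV standardises each spectrum with the n−1 sd;
MSC regresses each spectrum on a reference and returns (x − a)/b, the
reference being the calibration-set mean spectrum, fitted once and
stored inside the chain so validation rows and single pixels are
corrected against the same reference (fit/apply separation is
enforced). Savitzky–Golay derivatives use window 11 with polynomial
degree 2 (1st) and 3 (2nd) — conventional for ~6 nm-resolution NIR and
config-exposed; derivatives are taken with respect to band index, since
the grid is near-uniform and regression is invariant to a global
spacing factor; edges come from the polynomial fitted to the first/last
full window (`mode="interp"`). "Normalisation" is ambiguous across
chemometrics packages; unit Euclidean norm is the default, switchable
to area or max. The composite chain applies SNV before the derivative,
reading the label "SNV + 1st derivative" left to right.

## PLS calibration and validation

NIPALS PLS1 with mean-centring only (no autoscaling — spectra share
units, and scaling noise-only bands up is counterproductive; an
autoscale flag is deliberately absent from the default path). Per
component: w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/(tᵀt), q = yᵀt/(tᵀt),
deflate X ← X − tpᵀ, y ← y − tq; β = W(PᵀW)⁻¹q with centring absorbed
into the intercept. β-prediction and the score recursion agree to
1e-8 by invariant test, and predictions match an independent SVD-based
PLS implementation to 1e-8 on 50 random problems. If deflation
exhausts the signal before the requested component count (low-rank
noise-free data), the strict API raises a rank error; the calibration
workflow instead truncates, and cross-validation carries the deepest
available prediction forward to higher LV — the honest continuation of
a flat error curve.

The holdout split samples *beans*, not rows: round-half-up of
0.7 × 170 = 119 beans → 238 calibration rows, 102 validation rows, and
no bean's two sides ever straddle the boundary. Cross-validation is
bean-grouped random 10-fold, seeded. The latent-variable count is the
smallest LV whose RMSECV is within 2 % of the curve minimum — a
parsimony rule standing in for a choice the original workflow makes by
eye. R² is 1 − SSE/SST throughout; RPD = sd(reference, n−1)/RMSE, so
RPD·RMSE equals the reference sd identically; the paired t-test on
prediction−reference differences reports p and the 95 % CI half-width.

## Wavelength selection

Band importance is |β_j|·sd(X_j) over the calibration set — the
sd-weighted reading of "weighted regression coefficients"; raw |β| is
available by flag. Selected bands closer than one instrument bandwidth
(6 nm) are merged, keeping the more important one, because physical
multispectral filters cannot sit that close. In deployment mode the
refit allows only per-band log(1/R): SNV, MSC, normalisation and
derivatives all need the full spectrum a filter instrument never
acquires. A non-deployment override exists for comparing against
full-spectrum pre-treatments on selected bands.

## Chemical images

Pixel-level maps pre-treat each foreground spectrum with the model's
stored chain and apply β; background stays NaN, never 0. Per-bean maps
default to predicting once from the bean's mean spectrum (the practical
mode); averaging the pixel map is the alternative, and the two agree
exactly only for absorbance-linear chains (see above — asserted both
ways in tests). Colour scale defaults to the calibration y-range so the
two sides of a bean render comparably; per-bean annotations are printed
to one decimal with round-half-even. Predictions outside 30–75 % fat
are rendered but flagged in a QC column, since the model is then
extrapolating.

## Sorting

Beans are ranked by predicted fat; the k highest and k lowest form the
high/low fractions and k more are sampled uniformly from the remainder
(ties at a boundary resolve toward the lower bean id). Fractions are
compared on *reference* values with pairwise Welch t-tests at α = 0.05
and no multiplicity correction (a Holm option exists); at n = 3 the
family-wise type-I rate of the uncorrected triple is ≈9 % by
simulation, below 10 %. The compact letter display is a clique cover
of the non-significance graph (exhaustive enumeration — group counts
are tiny). Enrichment is reported as high−low and high−overall mean
differences.

## Pipeline and reproducibility

One `PipelineConfig` (YAML-loadable, schema-checked) drives
simulate → calibrate (all pre-treatments × presentations × bases) →
band selection → chemical images → sorting. Every random draw is seeded
from named seed sequences: the generator uses `[seed, stage, batch,
side]` sequences, the pipeline derives split/CV and sorting seeds from
the master seed by fixed offsets. Two runs with the same config are
byte-identical (tested on the emitted CSVs). Logs are key=value lines.

Problem sizes were chosen so the full default study (34 scans of
64×64×256) generates in ~3 s and the complete pipeline comparison runs
in ~6 s, keeping property suites over 100 seeded replicates cheap.

## Known limitations

* The generator's bean-mean spectra are nearly noise-free after pixel
  averaging, so shelled validation metrics sit at the reference-noise
  floor and are *better* than typically achievable on real beans; only
  orderings and error floors, not absolute metric values, transfer.
* Segmentation assumes non-touching beans; there is no watershed
  splitting.
* Side pairing assumes beans keep their stage positions between flips.
* The reading-order sample numbering and the 2 % parsimony rule are
  reconstructions of steps the original workflow leaves unspecified.
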