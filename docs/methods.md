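# Methods

This document describes the physical model, algorithms, parameters and
numerical design choices in `dermoct`. Nothing here is tuned to a
particular dataset; defaults are stated with their rationale and every
quantitative behaviour is enforced by the test suite against synthetic
ground truth.

## 1. Physical model and assumptions

A swept-source OCT depth profile through weakly scattering tissue is
modelled by the single-scattering Beer–Lambert law

```
I(x) = I0 · ρ · exp(−2 μ x)
```

- `x` — depth below the skin surface [mm]
- `μ` — attenuation coefficient [mm⁻¹], the quantity of interest
- `ρ` — local backscattering fraction (dimensionless)
- `I0` — incident intensity

The factor 2 reflects the double pass of light in reflection-mode OCT.
Assumptions: single scattering dominates over the shallow (≤ 1.5 mm)
analysis depth; the confocal/roll-off envelope is either negligible over a
15-row fit window or pre-corrected; speckle is multiplicative with unit
mean, so averaging before the fit is unbiased in the linear domain.

Typical dermal attenuation values span roughly 0.5–8 mm⁻¹; melanoma tends
to lower and more homogeneous attenuation than benign nevi (loss of the
layered epidermal/dermal architecture, "effacement" of rete ridges), which
is the contrast the classifier exploits.

## 2. Attenuation-coefficient (AC) mapping

`dermoct.ac.ac_map` slides a kernel over the B-scan:

- **5 columns** of lateral averaging (speckle reduction; lateral pitch
  7.5 µm, so 5 columns ≈ 37.5 µm, below typical lesion feature scale);
- **15 rows** of depth (`fit_depth`) per fit (150 µm at 10 µm axial
  pitch — long enough to stabilise the slope, short enough to keep the
  single-μ assumption locally valid).

Within each window, `log I` is regressed on depth; `μ = −slope/2`. The
window is replicate-padded so the AC map has the same shape as the input.
Pixels are excluded where the image is masked invalid or non-positive; a
window needs ≥ `min_fit_samples = 4` usable samples and a non-degenerate
design, otherwise the output pixel is marked invalid.

**Intensity-weighted fitting.** An unweighted log-domain fit is dominated
by near-noise-floor tail samples, whose log values have inflated variance;
on noisy profiles this biases μ low by tens of percent. We weight each
sample by its intensity (`np.polyfit(..., w=I)`, i.e. I² weights on the
squared residuals), which is the standard first-order approximation to
linear-domain least squares. The acceptance tests verify that the fit
lands within one 0.001 mm⁻¹ grid step of a brute-force linear-domain SSE
minimiser on noiseless profiles, recovers μ to < 0.1 % noiseless and to a
median error < 10 % under σ = 0.2 log-normal speckle for μ ∈ [0.5, 8].

A single-profile variant, `fit_decay`, applies a 5-sample valid-mode
moving average before the weighted fit and additionally reports `I0·ρ` and
R².

## 3. Surface detection

`dermoct.segmentation.detect_surface` operates on the AC map: magnitudes
are smoothed laterally (Gaussian, σ = 1 column), differentiated axially,
and the first axial gradient exceeding an Otsu threshold (computed over
positive gradients) marks the dark→bright transition in each column.

**Surface-lead correction.** Because the AC window extends `fit_depth`
rows below its output pixel and the profile smoother spreads signal
`smooth_window//2` rows upward, the first valid AC response *leads* the
physical surface by

```
lead = fit_depth//2 + smooth_window//2 − (min_fit_samples − 1)   (= 6 rows at defaults)
```

This offset is carried on the `ACMap` object and added to the detected
crossing, rather than being an empirically fitted constant. Column gaps
(artifact strips) are filled by nearest neighbour and the profile is
median-filtered (width 9 columns ≈ 67 µm) to reject hair spikes. Accepted
accuracy: mean absolute error ≤ 2 rows on speckled sinusoidal-surface
phantoms (measured ≈ 1.1 rows).

## 4. ROI extraction

Fixed-size ROIs of **10 columns × 150 rows** (75 µm × 1.5 mm) are tiled
laterally with stride 10 (non-overlapping); one strip at each border is
trimmed (`border_trim = 1`) because edge strips suffer replicate-padding
and galvo-turnaround effects. Each ROI starts `entrance_band = 8` rows
below the maximum detected surface in its strip, excluding the specular
entrance line. ROIs extending past the image bottom are rejected, as are
ROIs whose valid-pixel fraction (artifact mask ∧ AC validity) falls below
0.7.

At these defaults an 800-column scan yields at most 78 ROIs; halving the
stride to 5 (50 % overlap) yields ~150 per image. ROI counts are therefore
a stride-dependent design choice, not a fixed property of the method.

## 5. Features

Each ROI is z-scored over its valid pixels and filtered with a Gabor
wavelet bank

```
g(x, y) = exp(−x′²/2σx² − y′²/2σy²) · exp(j 2π f x′) / (2π σx σy)
x′ = x cosθ + y sinθ,   y′ = −x sinθ + y cosθ
```

with **4 frequencies** (0.05, 0.1, 0.2, 0.3 cycles/pixel) × **6
orientations** (θ = kπ/6) and σx = σy = 0.56/f (≈ one-octave bandwidth).
This 24-filter bank spans periods of ~3–20 pixels, bracketing the visible
texture scales (speckle grain up to rete-ridge undulation) at the stated
pitches; it is the smallest bank that covers those scales at 30°
orientation resolution, and remains an open tuning axis
(`gabor_frequencies`, `gabor_orientations` in the config). Convolution
uses replicate edge padding (FFT-based, 'valid' on the padded array) so
border response is not contaminated by zeros.

Per filter, the **mean and standard deviation of the response magnitude**
over valid pixels are pooled (48 values). Seven depth-resolved mean-AC
features are appended: the 150 ROI rows are partitioned into bands of
(22, 22, 21, 21, 21, 21, 22) rows — the unique near-even 7-way split that
is symmetric and sums to 150 — loosely corresponding to epidermis through
superficial reticular dermis. Total: **55 features per ROI**.

## 6. Classification, voting and metrics

- **Per-ROI classifier:** RBF-kernel SVM (scikit-learn `SVC`, C = 1,
  γ = "scale"), features standardised by statistics of the *training* set
  only. Models serialise to JSON (scaler stats, support vectors, dual
  coefficients, intercept); deserialised models predict via the explicit
  kernel expansion, so no pickle files are involved.
- **Per-image decision:** majority vote over the image's ROI labels. Ties
  resolve to *melanoma* by default (`tie_break`), the clinically
  conservative direction for a triage tool.
- **Metrics:** confusion matrix with *benign* as positive class (the
  melanoma row swaps TP↔TN, FP↔FN); precision, recall and F1 reported as
  integer percent with half-up rounding (`floor(100x + 0.5)`), with
  zero-denominator cases flagged undefined rather than silently zeroed.
- **Leakage guard:** `run_pipeline` refuses any train/test split sharing
  an image id — all splits are grouped by image.

## 7. Synthetic phantom generator

`dermoct.synthetic` renders B-scans directly from the forward model so
that every pipeline stage can be validated against known ground truth:

- layered media with per-layer μ and backscatter ρ; optical depth uses an
  *exclusive* cumulative sum, so a single layer reproduces ρ·e^(−2μx)
  exactly (machine precision, tested);
- sinusoidal rete-ridge layer boundaries (benign preset) and an
  `effacement` parameter blending toward a homogeneous medium (melanoma
  preset, 0.9);
- a 2-row specular entrance line at 3× the sub-surface intensity;
- unit-mean log-normal speckle (σ = 0.2);
- artifact bands (×0.02 attenuation + boolean mask) emulating hairs and
  saturation stripes.

Presets: *benign nevus* (epidermis μ = 4.0 mm⁻¹ over dermis 2.5 mm⁻¹,
ridged) and *melanoma* (μ ≈ 1.4/1.15 mm⁻¹, effaced). `make_dataset`
jitters μ (±10 %), surface depth, ridge phase/amplitude and effacement per
image with per-image seeds derived from one master seed, so datasets are
fully reproducible.

What the generator does **not** emulate: multiple scattering, the confocal
PSF and sensitivity roll-off, refraction at the tilted surface, blood-flow
shadowing, and real melanocytic morphology. Phantom classification results
are therefore a *verification* of the pipeline's machinery, not a claim of
clinical performance.

## 8. Evaluation protocol and problem sizes

The default in-silico study — chosen as this package's own benchmark
size — uses 74 training images (37 per class) and 12 held-out test images
(6 per class) of 220 × 120 pixels (10 ROIs per image after border trim).
Across 5 master seeds the mean image-level test accuracy must be ≥ 0.9
(observed: 1.0).

To show the pipeline learns class structure rather than rendering
artefacts, two null controls are enforced:

- **Identical-physics null:** melanoma images rendered with benign physics
  give grouped CV accuracy statistically indistinguishable from chance.
- **Permutation null:** permuting image labels collapses grouped CV
  accuracy into [0.4, 0.6]. Cross-validation uses
  `StratifiedGroupKFold` — with plain grouped folds, per-fold class
  imbalance under permuted labels biases accuracy *below* chance (~0.38
  observed), which would make the band test fail for the wrong reason.
  Stratification centres the null at ~0.50.

Wall-clock on one desktop core: AC map of a 220 × 120 scan ≈ 60 ms; the
full 86-image study ≈ 25 s; the complete test suite ≈ 5 min.

## 9. Limitations

- The single-scattering model under-estimates μ in highly scattering or
  deep regions; no confocal/roll-off correction is applied.
- Surface detection assumes the entrance signal is the first strong
  axial gradient; thick gels or detached corneum can defeat it.
- Phantom realism is deliberately limited (see §7); reported accuracies
  on phantoms are upper bounds for machinery correctness only.
- Gabor bank size and ROI stride are open tuning choices; the defaults
  favour transparency and speed over exhaustive optimisation.
- The SVM is trained per-run without hyper-parameter search; C and γ are
  exposed in the config for users who need it.
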