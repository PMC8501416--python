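# Methods

This note records the models, parameter choices, and numerical decisions
behind `snapmsi`, and what the synthetic studies do and do not demonstrate.

## Instrument model

The simulated sensor is an 8-bit 1280×1024 detector with a 3×3 mosaic of
spectral filters: eight narrow bands (centers 553–829 nm, FWHM ≈ 30 nm)
and one broadband channel.  The default mosaic maps sensor position
(i, j) mod 3 to band 3·i + j; a configurable phase offset supports readout
windows that start mid-superpixel.  Light reaches the sensor through an
imaging fiber bundle modeled as a jittered hexagonal lattice of cores.
The lattice density defaults to 10,000 cores per full-frame area (pitch
≈ 12 px on the full sensor, matching a 10,000-fiberlet bundle); only cores
inside the circular bundle footprint (radius 0.47 × min frame dimension)
are kept.  Reduced frame sizes used in tests and in the acceptance script
(typically 256×320, ~625 cores) keep this density, so the comb geometry
per pixel is unchanged while simulation cost drops ~16×.

Each core transmits fully inside a flat top of radius 1.15 × core radius
(core radius = 0.4 × pitch) and falls off as a Gaussian of width
0.09 × pitch beyond it, so inter-core gaps are near dark and transmission
vanishes outside the bundle.  The flat top is deliberately wide enough
that bilinear demosaicing near a core center draws only on fully
transmitting pixels; this is what makes the restoration round trip exact
to better than 1% rather than biased by gap pixels.  Pixel values are

```
v = quantize8( dark + white_level · illum(x) · throughput(band) · T(x) · R )
```

with `dark = 8`, `white_level = 220` (white standard ≈ 200–220 counts,
comfortably below the 250 saturation threshold), a fixed smooth non-flat
spectral throughput (so white referencing is actually exercised), radial
illumination falloff of 35% at the bundle edge by default, and rounding
half away from zero with a clamp at 255.  Specular glare is injected as
saturated discs in ~30% of tissue frames.

## Tissue and chart reflectance models

Class mean spectra are synthetic smooth curves — a shared two-bump base
plus `separation` times a fixed, class-specific smooth unit direction —
**not** digitized tissue reflectances (none are published in tabular
form).  Pairwise L2 distance between class means scales linearly with
`separation`; `separation = 0` gives identical classes.  The variance
hierarchy is additive band-wise Gaussian noise on reflectance at three
levels, clipped to [0, 1]:

| parameter | default | role |
|---|---|---|
| `sigma_patient` | 0.04 | patient-to-patient offset, drawn once per patient |
| `sigma_image` | 0.03 | cube-to-cube offset within a region |
| `sigma_pixel` | 0.10 | per classification-pixel noise |
| `separation` | 0.25 | class-mean spacing (reflectance units) |
| counts | 15 × 2 × 24 | patients × regions × cubes (≈ the 727-cube study scale) |

The pixel-level term is drawn once per 32×32 cell of the raw frame
because that cell is the "per-pixel spectrum" unit downstream; drawing it
per sensor pixel would make it vanish under binning (averaging ~113
samples per band) and rob `sigma_pixel` of its meaning for classification
difficulty.  This is the simplest structure that reproduces the observed
ordering of variances (per-pixel > per-image > per-patient) and leaves
interpatient heterogeneity as the dominant obstacle to generalization.

The color-chart model has 24 patches: 18 chromatic (smooth one- or
two-bump reflectance curves with peaks spread over the narrow bands) and a
6-step neutral gray scale, flat across the narrow bands by construction.
The gray floor is 0.35 so the darkest patch stays above the low-signal
cutoff at nominal exposure — every patch of the physical chart was
classifiable.  Note a structural consequence of the processing chain:
max-normalization maps all perfectly neutral grays onto the same unit
spectrum, so the gray scale is intrinsically ambiguous to shape-based
classifiers and chart accuracy saturates below 100% no matter the method.
Real gray paints have slight spectral tilts; the synthetic ones do not,
so synthetic chart accuracies understate what is achievable on a physical
chart.

## Restoration

Stage order is demosaic **before** decomb, per band.  The alternative
order would interpolate across fiber cores on the raw mosaic and thereby
mix spectral bands; keeping bands separated first makes decombing a purely
spatial operation.  Decombing samples each core over a conservative
radius (0.35 × core radius, ≥ 1 px) so only the flat part of the core
profile contributes, and fills inter-core pixels by inverse-distance
weighting (power 2) over the 4 nearest cores, with the nearest core's
value at zero distance and nearest-core fallback at the bundle edge.
Core detection runs on the mean dark-subtracted white frame: Gaussian
smoothing (σ = 1 px), local maxima at least 5 px apart and above 25% of
the frame maximum, refined to sub-pixel precision by a 5×5 intensity
centroid.  On density-matched synthetic bundles this recovers the core
count exactly and centers to well under 1 px median error.

Masking is monotone: valid pixels can only be lost (saturated > 250,
low-signal max < 50, out-of-bundle), never regained, and every cube
carries a stage ledger asserting the canonical order saturation → dark →
demosaic → decomb → low-signal → white reference → binning →
max-normalization.

## Aggregation choices

* Binning averages post-reference-division, pre-normalization values;
  noise averaging only helps before per-spectrum rescaling.  Blocks with
  no valid pixel are excluded.
* The mean image spectrum averages un-normalized spectra over a central
  ROI and normalizes afterwards, so brighter pixels weigh more.  The ROI
  radius is not pinned down by the acquisition protocol; the default is
  0.5 × bundle radius around the detected bundle center, configurable.
* The white reference is the ROI average of the restored white-standard
  cubes, averaged over acquisitions; the number of white frames per
  procedure is a free parameter (default 10).
* Pooled σ uses the population divisor *n* exactly as defined, with the
  band sum inside the square root; the within-patient value is the plain
  unweighted mean of per-patient σ's.
* PCA components have a fixed sign convention (largest-magnitude loading
  positive) so scores and plots are reproducible.

## Classification

* Splits are unstratified uniform shuffles of cube ids (train =
  ⌊0.8 N⌋); at N = 727 this gives 581/146 cubes and at N = 568 (chart
  study size) 454/114.  The network's test cubes are split again, larger
  half to validation.
* KNN uses Euclidean distance; a tied vote resolves to the class of the
  single nearest neighbor — deterministic and standard.
* PCA-KNN keeps the smallest number of components explaining ≥ 99% of
  training variance (the count actually used in the original comparison
  is not recorded); with all 9 components it provably reproduces plain
  KNN, which is asserted exactly in tests.
* SAM references are the per-class mean training spectra only.
* LDA is the pooled-covariance linear discriminant (scikit-learn's SVD
  solver, priors = class frequencies), which is well-defined on collinear
  features without an explicit ridge.
* The network is 9 → 10 sigmoid → C linear, one-hot targets, MSE loss,
  full-batch Adam (lr 0.05), early stopping on the held-out validation
  cubes with patience 6 and a 50-epoch burn-in (the validation loss
  oscillates during the optimizer's initial transient; without the
  burn-in, patience 6 fires around epoch 14 at chance accuracy), max
  1000 epochs, argmax decision.  Weights are restored to the best
  validation epoch.  Validation data never enter a gradient step.
* Per-image-spectrum classifiers are trained on training-set mean image
  spectra, not reused pixel models.
* Two-way mode retrains every model from scratch on NDBE + neoplasia
  cubes only, with neoplasia as the positive class for sensitivity /
  specificity / PPV / NPV; a rate with an empty denominator is reported
  as undefined, never as 0.

## Maps and reporting

Classification maps at binned resolution mark masked/specular pixels
distinctly (rendered white).  The single-pass 4-neighbor mode filter
replaces a pixel only when *all* available valid neighbors disagree with
it, by their mode; mode ties resolve to the lowest class index
(squamous < NDBE < neoplasia) — the tie case is otherwise unspecified, and
this choice is deterministic.  False-RGB composites default to bands
3, 2, 1 → R, G, B with the bands 2, 3, broadband variant available
(both conventions are in circulation for this instrument; they are not
reconcilable, so both are provided).

Majority ties with three or more leaders also count as incorrect,
generalizing the two-class tie rule.  Images with zero valid pixels are
excluded from per-image metrics and counted in the report.

## Cohort bookkeeping

`snapmsi.cohort` ships the per-region acquisition log of the clinical
campaign the generator emulates (30 matched regions; LGD/HGD/IMC pooled
into neoplasia; one unconfirmed region analyzed as NDBE; 157 squamous
cubes from 9 regions recorded separately) and derives the study totals
and split counts from it.  These sums are the only clinical numbers the
package reproduces.

## What the synthetic studies show — and what they do not

Passing tests demonstrate that the implementation is faithful to its
stated contracts: artifacts are removed to within quantization error,
formulas match brute-force oracles, decision rules behave exactly as
defined, and classifiers recover planted class structure under the
generator's assumptions.  They do **not** demonstrate clinical
performance: real esophageal spectra have correlated, non-Gaussian,
physiology-driven variation, motion and moisture effects, and imperfect
histopathological coregistration, none of which the generator models.
Synthetic accuracies are therefore properties of the study conditions,
not estimates of in-vivo accuracy, and the headline clinical figures are
deliberately out of scope (the patient data are not public).

## Problem sizes

Tests and the acceptance script simulate 256×320 frames at full-sensor
fiber density, 18–48 cube tissue studies, 20-frame round-trip checks,
100-cube × 5-seed recovery runs, and a 192-cube chart study — sizes chosen
so the whole suite runs in well under a minute of simulation time per
study while exercising every stage at realistic per-pixel geometry.
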