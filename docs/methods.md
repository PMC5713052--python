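# Methods

`corneahsi` re-implements, as a tested pipeline, a hyperspectral-imaging
approach to detecting corneal epithelium abrasion without fluorescein
staining: flat-field calibration of visible–NIR cubes, an image-enhancement
chain that makes the unstained injury visible, first-order histogram
features of the enhanced image, and a Gaussian-RBF SVM classifier.  No
image set for this problem is publicly deposited, so the pipeline is
validated on synthetic cubes with the statistical structure the analysis
assumes, plus the published 25-eye feature table, which is packaged as a
CSV fixture.

## Calibration

Raw pushbroom counts are converted to relative reflectance per pixel and
band:

    R = (I_sample − I_dark) / (I_white − I_dark) × 100  [%]

with a capped dark frame and a Spectralon white frame (2-D band-broadcast
frames or per-band stacks are both accepted).  Pixels with no usable
dynamic range (`white − dark ≤ 1e−6` of the white dynamic range, tunable)
are flagged defective and returned as NaN rather than infinities.  Output
is clipped to [0, 150] % by default: specular glare legitimately exceeds
the diffuse white reference, and the cap keeps later 8-bit quantisation
well defined.  Clipping is configurable and disabled in the forward-model
inversion tests.

## Synthetic scenes

`SpectrumModel` + `make_scene` generate raw cubes with companion dark and
white frames and ground-truth masks.  The forward model per pixel/band is

    counts = dark + gain · (R/100) · (white − dark) + noise,

so flat-field correction inverts the generator exactly when noise is off.
Design choices, in the package's own terms:

* **Base spectrum** — cubic spline through eight control points
  (400→1000 nm: 18, 22, 38, 52, 60, 64, 66, 65 % reflectance): low in the
  blue, rising through 450–600 nm, NIR plateau.  Only the curve's shape
  matters downstream; no attempt is made to match absolute reflectances.
* **Injury offset** — a smooth negative bump, peak −6 % at 564 nm with a
  55 nm Gaussian scale, so it is concentrated in (and nonzero over) the
  503–625 nm window and stays below 20 % of the base curve (the injured
  spectrum has the same morphology as the healthy one with a subtle
  depression).  The magnitude is a free realism parameter; −6 % (~10 %
  relative) keeps the injury invisible to the eye in single raw bands at
  the default noise but recoverable by the pipeline.
* **Injury geometry** — one connected blob covering 5–20 % of the frame,
  with an irregular smoothed boundary, binary by construction so that the
  calibrated in-mask minus out-of-mask mean equals the injury offset
  exactly in the noise-free case.
* **Glare** — 2 saturated disks (radius 3–6 px) at the sensor maximum
  (4095 counts) in every band; glare is what the non-flat erosion is for.
* **Noise** — total amplitude `noise_sd` (default 0.8 % reflectance) split
  75/25 between a smooth band-varying illumination-drift field (common
  low-frequency field with band-varying strength plus a smooth per-band
  residual) and independent per-pixel noise.  After the heavy spatial
  binning typical of these acquisitions, systematic illumination drift —
  not shot noise — dominates; it is also the nuisance that buries the
  subtle injury in raw principal-component images.  `noise_sd = 0` turns
  everything off, preserving the exact-inversion contract.
* **Reference frames** — dark ≈ 96 counts, white ≈ 3072 counts, both with
  mild random column structure (slit-axis response variation); dark is
  strictly below white everywhere.
* **Seeds** — one master seed per cohort; scene *i* uses `master + i`;
  identical seeds give bit-identical scenes.

What the generator does **not** emulate: the curved specular cornea (no
surface shading or geometric distortion), fluorescein staining, scattering
from deeper layers, wavelength-dependent focus.  A passing synthetic suite
therefore shows the pipeline recovers a compact subtle spectral offset
under drift, glare and noise — not that it reproduces the optics of real
porcine eyes.

## Region of interest

The cornea is located in a single band image by FFT-based normalised
cross-correlation against a user-supplied template (zero-mean, unit-norm
per window; ties broken to the smallest row, then column), then the cube
is cropped and resampled to 100 × 100 per band.  Resampling is bilinear on
a corner-aligned grid — the crop's corner samples map exactly onto the
output corners — so an already-100×100 crop passes through unchanged and
ramps keep their endpoints.

## Enhancement chain

Stages in order, all deterministic:

1. **Band-group selection.**  Candidate groups (bands 0–50, …, 200–250 on
   a 256-band cube; five equal groups on coarser grids) are scored by the
   mean mutual information between each band image and the group-mean
   image (joint 64×64-bin histogram, natural log); the argmax wins, ties
   to the earliest group.  On corneal spectra this selects the ~503–625 nm
   window, where the injury offset lives.
2. **Gamma adjustment** of each selected band: linear rescale to [0, 1]
   between the 1st and 99th percentile (the configurable "clip pixel
   level"), raise to γ (default 0.7 — the acquisitions are dark, so γ < 1
   brightens), map back to the clipped range.
3. **Non-flat erosion** with a ball structuring element,
   `out(x) = min_u img(x+u) − b(u)`, `b(u) = h·sqrt(1 − |u|²/r²)` on the
   discrete disk.  Defaults r = h = 25: the printed 50×50 SE extent is
   read as the ball's bounding box, since a radius-50 ball (101×101
   support) cannot fit the 100×100 ROI the same procedure prescribes, and
   the bracket notation parallels the 9×9 filter-size notation.  Erosion
   removes saturated glare blobs up to the ball's size at the cost of
   widening dark regions by up to ~r (the enhanced injury reads slightly
   larger than truth).  Border policy: reflect (default) or `omit`
   (minimum restricted to in-image offsets).  The kernel is an exact
   minimum over the support, numba-compiled; `scipy.ndimage.grey_erosion`
   computes the identical quantity and serves as an independent oracle in
   the tests.
4. **Laplacian-of-Gaussian filtering**, kernel sampled from
   `((x²+y²−2σ²)/σ⁴)·exp(−(x²+y²)/2σ²)` on the centred integer grid and
   shifted to zero sum (guaranteeing exactly zero response on flat
   regions, which the continuous form only attains in the infinite limit).
   Default 9×9, σ = 0.1: at this σ the Gaussian is sub-pixel and the
   kernel acts as an aggressive centre-minus-local-mean high-pass.
5. **PCA** over the processed bands of the single cube: pixels are
   observations, bands variables; covariance with the 1/M normalisation;
   eigenpairs sorted descending; components with eigenvalue ≤ 1e−12 of
   the leading one dropped; at most 10 retained; eigenvector signs fixed
   so the largest-magnitude entry is positive.
6. **PC subtraction**: score image 2 minus score image 1 (1-based,
   configurable), min–max rescaled to 8-bit [0, 255]; a constant
   difference maps to all zeros.

First-order histogram features (mean, std, skewness, kurtosis) are then
computed from the 256-level gray histogram of the enhanced image.
Skewness and kurtosis are the standardised ratios µ₃/µ₂^1.5 and µ₄/µ₂²
(kurtosis non-excess, Gaussian → 3): the published feature magnitudes
(skewness 0.27–1.43 and kurtosis 4.6–9.7 at std ≈ 20–29) are only
consistent with the standardised forms, not the raw central moments.
Degenerate distributions (µ₂ = 0) report skewness = kurtosis = 0.

## Classifier

A from-scratch binary soft-margin SVM.  The dual is solved by SMO with
maximal-violating-pair working-set selection to a KKT gap of 1e−6;
iteration counts are recorded but are solver-specific and not comparable
across implementations.  The Gaussian kernel is parameterised by its width
σ, `K = exp(−‖u−v‖²/2σ²)` (precision form γ = 1/2σ²).  Feature columns
are normalised to unit Euclidean norm; by default norms are fitted on the
training part of each fold and applied to the held-out part, with a
joint-normalisation switch that scales the full table once (the historical
convention for the published grid, which normalised training and testing
sets together).  Evaluation: stratified k-fold (fold assignment seeded;
k = n degenerates to deterministic leave-one-out), pooled out-of-fold
decision values scored as ROC AUC by threshold sweep + trapezoid rule
(equal to the Mann–Whitney statistic with ties at ½), plus fraction
correct, out-of-sample MSE on {0,1}-coded labels, and the confusion matrix
with healthy = negative, injured = positive.

## Reproduction of the published classification grid — negative result

Under this protocol the published accuracies for the (mean, skewness)
pair on the printed 25-eye table are **not reproducible**: computed mean
pooled AUCs over 20 fold seeds are ≈ 0.67 (C=500, σ=2.658; published
1.00), ≈ 0.74 (C=500, σ=1.658; published 0.9583) and ≈ 0.64 (C=1, σ=1;
published 0.8333).  The solver is not the cause — on identical folds a
reference SVM implementation agrees with ours to ≤ 0.002 — and no
protocol variant closes the gap: per-fold versus joint versus per-set
column normalisation, per-sample normalisation, no normalisation,
σ-as-precision conventions, and fold-averaged instead of pooled AUC were
all tried, and even resubstitution (train on all 25, score all 25) tops
out at AUC ≈ 0.82.  Two structural observations explain this.  First,
healthy eye 2 (97.23, 0.92) and injured eye 22 (96.72, 0.94) nearly
coincide in the (mean, skewness) plane, so no smooth decision function
ranks the printed points perfectly.  Second, every published accuracy in
the grid is an integer multiple of 1/48, which cannot arise from any
pooled cross-validation of an 11/14 split (multiples of 1/154) but is
consistent with an AUC over a single undocumented test split with
6 × 8 = 48 positive–negative pairs.  The package reports its honestly
computed values; the corresponding acceptance tests fail and are left
failing.

## CNR comparison — negative result

The contrast-to-noise ratio is `|mean(roi) − mean(bg)| / std(bg)`
(population std); it is scale-invariant, so the published CNR magnitudes
(computed with an unprinted formula on unavailable images) cannot be
targeted, only the qualitative claim that enhancement raises CNR over
plain PC subtraction.  In this synthetic world the claim does not hold
under any region convention tried (ROI = injury mask with the complement,
glare excluded or included, morphologically dilated ROI, fixed central
ROI): the zero-sum LoG stage removes region fill, leaving boundary
responses plus erosion-ridge texture, while plain PC subtraction — whose
input retains the spectrally coherent injury offset — keeps a clean filled
region and scores region CNR an order of magnitude higher.  The
corresponding acceptance test is implemented exactly as stated (50 injured
scenes, default generator and chain, ROI = true injury mask) and left
failing; `analysis/03_cnr_study.py` reproduces the distribution.

## Problem sizes and numerical choices

* Heavy synthetic runs use the default scientific conditions on coarser
  spectral grids — 48–64 bands for the CNR study, 24 bands for the
  end-to-end cohorts, with band groups scaling as five equal partitions —
  and 100 × 100 frames.  These sizes are the package's own choice for the
  routine test suite; the generator accepts full 256-band grids.
* The end-to-end recovery study (ten master seeds × 40-scene cohorts,
  (mean, skewness), C = 500, σ = 2.658) is summarised by the mean pooled
  CV AUC across the master seeds (≈ 0.93 at these conditions, per-seed
  range ≈ 0.89–1.0).
* Erosion/LoG/PCA are exact; no approximate SE decompositions are used.
* PCA drops sub-1e−12-relative eigenvalues to avoid sign-noise in
  zero-variance components; `pc_subtract` on fewer than two retained
  components is an error, and the chain falls back to (2, 1) if a
  configured pair exceeds the retained count.
* SMO uses a 1e−12 numerical guard on the curvature of the two-variable
  subproblem; the bias is the midpoint of the final KKT bounds.
* Ties: template-matching peaks and band-group scores resolve to the
  first (row-major / lowest-index) maximum; SVM decision value 0 labels
  positive.

## Known limitations

* The synthetic generator is a statistical, not optical, model of corneal
  acquisitions (no curvature shading, no staining channel).
* Published iteration counts are solver-specific and not comparable.
* The published grid accuracies and CNR values are not recoverable from
  the data the publication itself prints (see the two negative-result
  sections above); the package documents and tests its own protocol
  instead.
* The LoG stage at σ = 0.1 is effectively a high-pass delta-minus-mean
  filter; users wanting scale-space behaviour should raise σ and size
  together.
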