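# Methods

## The measurement model

Three-compartment breast (3CB) imaging decomposes each pixel of a compressed
2D mammogram into thicknesses (cm) of three basis materials: lipid, water,
and protein.  The inputs per pixel are the low-energy (LE) attenuation, the
high-energy (HE) attenuation — each the negative log of the transmitted
X-ray fraction — and the local compressed-breast thickness `T`.  Under a
monoenergetic approximation (one effective linear attenuation coefficient per
material and beam; no scatter or beam hardening), these satisfy a linear
3×3 system per pixel:

```
mu_l,LE t_l + mu_w,LE t_w + mu_p,LE t_p = A_LE
mu_l,HE t_l + mu_w,HE t_w + mu_p,HE t_p = A_HE
      t_l +        t_w +        t_p     = T
```

The coefficients are spatially constant, so `solve_lwp` applies one
precomputed matrix inverse to every pixel.  Consequences worth knowing:

* The third equation makes lipid+water+protein equal the thickness map
  *exactly* on solved pixels, with or without noise.
* The solve is unconstrained, so attenuation noise can produce negative
  component thicknesses.  The default keeps the raw solutions (clipping
  biases region medians, which downstream statistics rely on) and reports a
  negativity fraction; an optional clip-and-rescale mode zeroes negatives and
  rescales the remainder to preserve `T`.
* The system is moderately ill-conditioned (condition number ≈ 670 for the
  default coefficients): attenuation noise is amplified ≈ 120–240× into
  per-pixel component error.  Region medians over hundreds of pixels bring
  this back down to the 0.005–0.01 cm scale.
* A condition-number ceiling (default 1e8) turns degenerate calibrations into
  a loud error instead of a silent pseudo-inverse.

Default coefficients (cm⁻¹) are effective values assembled from standard
attenuation tables at ≈19 keV (clinical mammographic beam) and ≈31 keV
(39 kVp with 3 mm added aluminium), with protein at density 1.35 g/cm³:

| energy | lipid | water | protein |
|--------|-------|-------|---------|
| LE     | 0.511 | 0.795 | 1.070   |
| HE     | 0.266 | 0.367 | 0.456   |

Nothing downstream depends on these specific values — calibration fitting,
the round-trip identity, and all statistics are checked for model
*consistency*, not for particular coefficients.

`fit_attenuation_model` recovers the coefficient matrix from calibration
phantom steps (known LWP triples with measured attenuations) by per-energy
ordinary least squares without intercept; a rank-deficient step design is an
error, a negative fitted coefficient a flagged warning.

## The synthetic cohort

Real 3CB patient images are identifiable and not publicly available, so the
package ships a generator that emulates the cohort structure the analysis
assumes.  What it does model:

* **Geometry** — an elliptical compressed breast on a 256×256 grid at 0.2 mm
  pitch (~5 cm field); thickness is a flat plateau (patient-level mean 4.5 cm,
  sd 0.5 cm) with a cosine edge rolloff.  Lesions and their rings are placed
  on the plateau so ring statistics are not confounded by the edge taper.
* **Composition** — background lipid/water/protein fractions 0.40/0.45/0.15
  with patient-level jitter (sd 0.04) and smooth within-breast texture
  (Gaussian random fields, 14 mm correlation scale, sd 0.005 in fraction
  units).  The texture amplitude was set so the cohort's within-class
  signature dispersion (~0.015–0.02 cm) matches the dispersion implied by
  reported clinical signature statistics; with markedly stronger mm-scale
  texture the documented gradients would be undetectable at this cohort size,
  with none the ring statistics would be degenerate.
* **Lesions** — irregular 4-connected blobs (thresholded filtered noise),
  radius 2–4.5 mm, pathology drawn as BN:FA:DCIS:IDC = 409:116:61:103
  (≈24 % malignant); invasive lesions carry a hormone-receptor label.
* **Compositional gradients** — each lesion adds a piecewise-constant offset
  per component: one value inside the lesion and one per 2-mm band outside,
  zero beyond 6 mm.  The offsets are parametrized by the target
  lesion-minus-ring median signatures `S_k` (core = `S_3`, band k =
  `S_3 − S_k`), so the expected measured signature at ring k is exactly
  `S_k`.  Defaults are the clinically reported malignant and benign median
  signatures (lipid deficit widening with distance; protein excess widening;
  the malignant-minus-benign water contrast positive and widening).  Each
  lesion scales its profile by a truncated N(1, 0.25) factor
  (lesion-to-lesion heterogeneity with mean one).  Triple-negative invasive
  lesions deepen their lipid gradient by a factor 1.3, reflecting reported
  peripheral lipid depletion around such tumors.
* **Acquisition** — exact forward projection plus i.i.d. Gaussian attenuation
  noise, default sigma 1e-3 (after the ≈120–240× decomposition amplification
  this leaves region-median noise at the 0.01 cm scale — see above).  The
  thickness map is treated as known exactly (the paddle-calibration step that
  estimates it clinically is out of scope).
* **CAD surrogate** — lesion malignancy scores from a binormal model:
  benign scores standard normal, malignant shifted by `√2·Φ⁻¹(AUC)`, mapped
  through the normal CDF, so the expected AUC equals the configured operating
  point (default 0.69, the reported clinical CAD operating point).  Detected
  lesions yield mask proposals with ±2 px shift/dilation jitter;
  per-pathology miss rates default to the reported miss fractions (DCIS 4/61,
  IDC 18/103; benign lesions are not missed — only the malignant miss rule is
  documented clinically).  Unmatched false proposals (Poisson, 1.2/image) are
  placed in normal tissue and later removed by the 25 % overlap filter.

What it does *not* model: polyenergetic spectra, scatter, detector blur,
compression-paddle warp, anatomic ductal structure, microcalcification
physics, multi-view correlation (each patient contributes one view), and any
dependence of CAD scores on lesion appearance (scores are conditionally
independent of the compositional features given the label).  Passing tests
therefore demonstrate that the *pipeline* recovers what the generator put in
at realistic noise levels — not that real tissue behaves this way.

## Feature extraction

For each lesion ROI the Euclidean distance transform of the lesion complement
defines three concentric outer rings at (0, 2], (2, 4], (4, 6] mm from the
border — half-open bins guarantee disjoint, exhaustive rings; rings are
clipped to the breast mask and exclude pixels of other lesions.  Nine
statistics per region and component give 9 × 4 × 3 = 108 named features
(`comp_region_stat`).  Conventions pinned for reproducibility: sample (n−1)
standard deviation, Fisher excess kurtosis and adjusted Fisher–Pearson skew
(both bias-corrected, zero with a degenerate flag for constant or
single-pixel regions), `total` the pixel sum, and `percentage` the
region-level share of the component in the summed lipid+water+protein
thickness of that region (the three percentages sum to 100).

CAD proposals join the analysis when at least 25 % of the proposal's own area
overlaps a radiologist ROI (inclusive threshold; best match by overlap
fraction, ties by larger intersection then lower index); they inherit that
ROI's pathology.  Calcification clusters are represented by the filled convex
hull of their member calcifications.

## Malignancy model

Records are split 60/20/20 by patient (all ROIs of a patient stay together;
the test partition holds 20 % of patients).  ROIs the CAD surrogate missed
get probability zero and stay in the training partition only.

The classifier is a small feed-forward network (1–3 ReLU hidden layers of
{16, 32, 64} units, logistic output) over the 108 features plus the CAD
probability.  Input normalization is per-feature standardization with
training-partition statistics followed by ZCA whitening with a Ledoit–Wolf
shrinkage covariance estimate.  The whitening matters: region statistics are
strongly collinear (a lesion median and its ring medians share almost all
their variance across patients), so the discriminative lesion-minus-ring
contrast directions carry a tiny share of raw variance; gradient-trained
networks reliably miss them without whitening, while the shrinkage keeps the
transform near the identity when samples are scarce.

Training is Adam with early stopping on validation log-loss (patience 20
evaluations, epoch cap 400); hyperparameters (hidden layout, L2 weight decay
in {1e-6, 1e-5, 1e-4}, learning rate log-uniform on [3e-4, 3e-2]) are chosen
by seeded random search (default budget 20; the bundled experiments use 6–8
to keep a 10-seed study desk-scale) with the best configuration by validation
AUC retained.  Weight decay stands in for dropout as the regularization axis,
and class imbalance (~24 % malignant) is handled by seeded balanced
oversampling of the training partition.  Because balanced training skews raw
output probabilities away from the cohort prevalence, the selected model's
output is recalibrated with a Platt (monotone logistic) map fitted on the
validation partition; this leaves rankings and AUC untouched but makes the
predicted probabilities interpretable as risks.  Inference is a pure numpy
forward pass over the stored weights, so JSON-serialized models reload
bit-exactly.

## Added-value metrics

* **AUC** by the rank method with ties counted ½; bootstrap mean and 2.5–97.5
  percentile CI from 1000 seeded ROI-level resamples (resamples lacking a
  class are redrawn; patient-level resampling is available behind a flag as
  the correlation-aware alternative).
* **IDI = IS + IP**, in percentage points: IS is the change (new − reference)
  in mean predicted risk among events, IP the change (reference − new) among
  non-events.
* **Categorical NRI** over BI-RADS bins 3 / 4a / 4b / 4c&5 with
  upper-inclusive intervals at 2, 10, 50 % (probability 0 maps to category 3):
  events NRI = (up − down)/events, non-events NRI = (down − up)/non-events,
  total their sum.  **Binary NRI** dichotomizes both models at each border
  threshold {2, 10, 50, 95 %}; the 95 % border appears only in the binary
  analysis since the categorical table merges 4c and 5.

  A scale caveat for the synthetic study: the CAD surrogate's probabilities
  are by construction normal-CDF-mapped scores (uniformly distributed over
  benign lesions, mean 0.5), while the trained network outputs calibrated
  risks near the 24 % prevalence.  IS and IP therefore each carry a large
  systematic offset from this scale difference that mostly cancels in their
  sum, so the IDI is the interpretable quantity, and the categorical NRI
  shows bulk downward reclassification of non-events (strongly positive
  non-events component, negative events component).

## Lesion signatures

A lesion's signature for ring k and component c is
`median(c over lesion) − median(c over ring k)` in cm, computed on raw
(unclipped) maps; medians damp microcalcification-like outliers.  Only
radiologist-delineated ROIs enter this analysis.  Group contrasts
(malignant DCIS+IDC vs benign BN+FA; triple-negative vs receptor-positive
within invasive) report group medians, their difference, and Welch's
unequal-variance t-test with Welch–Satterthwaite degrees of freedom, applied
to per-lesion signature values — lesions, not pixels, are the independent
units.  "Average" signatures are medians throughout, matching the reported
quantities.

## Numerical and design choices

* One shared 3×3 inverse for the decomposition (coefficients are spatially
  constant); per-pixel iterative solvers were rejected for exactness/speed.
* Distance bins half-open `(2(k−1), 2k]`; a pixel belongs to at most one ring.
* Degenerate Welch inputs: two zero-variance samples with equal means return
  t = 0, p = 1; with unequal means, ±inf and the smallest positive p.
* Binary NRI accepts threshold 0 as a degenerate case (nothing can cross).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; identical (config, seed) pairs
  are bit-reproducible.
* Problem sizes in the bundled experiments — 350-patient cohorts (~800 ROIs)
  for the added-value study, 600 patients (~160 malignant lesions) for the
  signature analysis, 512² grids for the round-trip identity — were chosen as
  the package's desk-scale defaults.

## Known limitations

* The generator's piecewise-constant lesion offsets make ring medians
  estimate the configured signatures exactly in expectation; smooth radial
  gradients would shift ring medians slightly off the band centers.
* CAD-score independence from composition means combining the two information
  sources is easier here than clinically, where morphology and composition
  correlate; the added-value experiment demonstrates pipeline sensitivity,
  not a clinical effect size.
* Units of the configured signature medians are taken as cm of component
  thickness (the natural unit of the maps).
* Reported per-border NRI percentages and the published cross-table are not
  jointly consistent in the source material; the implementation reports the
  component sum and asserts only the events-table worked example.
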