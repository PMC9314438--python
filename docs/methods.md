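# Methods

## Signal model and parametric images

Between crossed linear polarizers rotated together through 90° in 5°
steps, a birefringent structure with in-plane orientation φ transmits

    y(θ) = A · sin²(2(θ − φ)) + c,

a 90°-periodic modulation of the polarizer angle θ; non-birefringent
material yields a flat dark signal. From the 18-frame stack the package
derives three maps whose values do not depend on where the sweep
started (geometry independence is a tested property):

* **Intensity (MIR).** The per-pixel sample standard deviation of
  brightness across the 18 frames (divisor Z−1 = 17). The name "maximum
  intensity range" is historical; the implemented statistic is the
  sample SD, whose closed form on a pure sin²(2θ) pixel is
  √(2.25/17) ≈ 0.3638 (the harmonic sums Σsin⁴ = 27/4 and ȳ = ½ make
  the centered sum of squares exactly 9/4).
* **Orientation (B).** The acquisition angle at which the signal peaks,
  taken as the discrete argmax over the 18 angles with ties broken to
  the smallest angle. The model peaks where θ − φ = ±45°, so B is the
  wrapped φ ± 45°, quantized to the 5° grid.
* **Alignment (MAD).** In a sliding 5×5 window (≈ 4 µm at 0.8 µm/px),
  the mean over all 300 unordered pixel pairs of the wrapped absolute
  angular difference d(a,b) = min(|a−b|, 90−|a−b|). Orientations are
  equivalence classes mod 90°, so d ∈ [0, 45]; the printed-formula
  variant without absolute values averages to ≈ 0 and contradicts the
  quantity's meaning, so the absolute, wrapped form is used. MAD is
  computed only where the full window fits (`valid_mask`); ROI
  summaries use valid pixels only.
* **Abundance (R²).** The per-pixel fit of y(θ) to the model family.
  Because A·sin²(2(θ−φ)) + c ≡ a₀ + a₁cos4θ + a₂sin4θ, the fit is
  ordinary least squares on the harmonic design at frequency 4θ —
  closed-form, deterministic, no iterative optimizer. R² is clamped to
  [0, 1] and defined as 0 on zero-variance pixels; the collagen mask is
  R² > 0.75, and an ROI's abundance ratio is the masked-pixel fraction.

Flood-field correction divides each frame by its no-sample reference
frame normalized to unit mean, removing multiplicative illumination
structure while preserving brightness scale. Reference pixels at or
below the floor abort with a count of offending pixels.

## Texture features

Each parametric image patch is min–max quantized to 8 gray levels
(constant patches map to level 1), co-occurrence matrices are built at
distance 1 px along 0°, 45°, 90° and 135° (symmetric, normalized; the
45° offset is the up-right anti-diagonal, Haralick's convention), and
contrast, correlation, energy, homogeneity (inverse-difference form
Σp/(1+|i−j|)) and entropy are averaged over the four directions.
Choices the underlying sources leave open, fixed here: quantization is
per-ROI (keeps features dimensionless and affine-invariant), entropy is
base 2, and the correlation of a zero-variance matrix is defined as 0
so degenerate patches propagate finite values. Alignment-image patches
are cropped to their valid-pixel bounding box before quantization.

## Feature vector and normalization

Each ROI yields 18 features: median MIR, median MAD, abundance ratio,
plus the 5 texture features of each of the 3 parametric images. Before
clustering, each feature column is log-transformed and Z-scored.
Columns that reach zero or negative values (GLCM correlation can be
negative) are shifted by s = 1 − min(x) so the minimum maps to 1; the
shift, post-log mean and SD are stored, and patient-averaged vectors
are projected with the stored parameters rather than refitted, since
the cluster models live in the cohort-normalized space. Z-scoring uses
the population SD (ddof 0); any fixed convention only rescales columns
uniformly.

## Clustering and patient aggregation

K-means (scikit-learn, k-means++ with 20 restarts), Fuzzy C-means
(implemented here: Bezdek's alternating updates, fuzzifier m = 2,
tolerance 1e-6, 20 random restarts, with the singularity rule that a
point on a centroid has membership 1), and a full-covariance Gaussian
mixture (scikit-learn EM, ridge 1e-6, 20 restarts) are fitted with
k = 2 on the normalized ROI table. Labels are canonicalized so Cluster
1 is the larger cluster (tie → smaller centroid norm), matching the
convention that the survivor-enriched cluster is the majority one.

Patient assignment: *majority vote* takes a strict majority of hard
ROI labels and leaves exact ties unassigned; *feature averaging* means
the patient's normalized ROI vectors and assigns the average by the
fitted model (nearest centroid / fuzzy membership / posterior), so
every patient is assigned. Ties in the aggregated membership (exactly
0.5) resolve to Cluster 1.

## Survival association

Assigned patients are cross-tabulated as cluster (2 vs 1) against
5-year survival (no vs yes) with cells a, b, c, d = non-survivors in
Cluster 2 and 1, survivors in Cluster 2 and 1; unassigned patients are
excluded (hence majority-vote denominators below the cohort size).
Association uses the two-tailed Fisher exact test (point-probability
convention); performance is summarized by sensitivity, specificity,
accuracy, PPV and NPV (positive = Cluster 2, i.e. predicted
non-survivor), with zero-denominator ratios flagged rather than
coerced to 0. The odds ratio is the plain cross-product ad/bc with no
continuity correction — a zero in b or c leaves it undefined — and its
95% CI is the Woolf log interval exp(ln OR ± 1.96·√(Σ1/cell)),
reported only when all four cells are positive. The CI method is a
documented choice; published intervals for such tables are sometimes
produced by other (occasionally inconsistent) methods.

The package ships six reference contingency tables
(`outcome.REFERENCE_TABLES`) for a 32-patient stage III colorectal
cancer cohort (23 survivors / 9 non-survivors), reconstructed uniquely
from each model/rule's reported diagnostic ratios and sample size.
They reproduce every reported p-value to four decimals and the
combined-feature odds ratios exactly, and serve as fixed inputs to
`scripts/acceptance.py`. Two reported diagnostic cells in the original
summary are internally inconsistent with their own rows (the
fuzzy-C-means feature-average specificity and the K-means majority
accuracy); the reconstructed tables — confirmed by the p-values and
odds ratios — are authoritative here.

## Synthetic data

**Phantoms** are anti-aliased straight fiber segments (width 3 px,
length 0.3–0.7 of the image side) with uniform random centers,
von Mises orientations wrapped onto the 90° period (concentration 0 =
disordered), and per-fiber amplitudes; overlaps keep the larger
amplitude and the stronger fiber's orientation so the truth stays
single-valued. Frames follow the signal model exactly, optionally
multiplied by a smooth random gain field (coarse 6×6 Gaussian field,
cubic-upsampled, mean 1) and perturbed by per-frame additive Gaussian
noise clipped at 0. Defaults — dark offset 0.02, noise SD 0.01 in
amplitude units of order 1 — are conventions chosen to be realistic
for a cooled-camera widefield acquisition, not measured values. When a
coverage fraction is requested, fibers are added until the fiber-mask
fraction reaches the target (each fiber adds well under 1% of the
image, so overshoot is negligible). Phantoms do not model full Mueller
polarimetry, wavelength dependence or scattering; passing tests show
the pipeline recovers the sinusoid-squared contract, not tissue
realism.

**Cohorts** are feature-space simulations of the study design: 32
patients, 3–14 ROIs each (~300 ROIs), ~72% of patients in phenotype 1,
survival probabilities (0.9, 0.3) by phenotype, and a 10% chance an
ROI's phenotype differs from its patient's. Raw features are
log-normal — exp of Gaussian draws around phenotype-specific log-space
means — so that the pipeline's log step Gaussianizes them, which is
exactly the skewed-feature setting the normalization is designed for;
column f02 is shifted by −1.5 to straddle zero and exercise the
shifted-log branch. "Separation k·SD" means each log-feature mean
differs by k within-phenotype SDs with alternating sign; in the
degenerate zero-noise limit the unit scale is used so class means stay
distinct. Real cohorts differ in ways this generator ignores:
feature correlations, patient-level random effects, and
phenotype-survival links weaker than the planted Bernoulli gap.

## Problem sizes and numerics

Unit and property tests run on small images (48–256 px) and cohorts of
a few hundred ROIs; parameter-recovery checks use 512×512 phantoms and
brute-force oracles on ≤16×16 patches, 9×9 orientation fields and 2×2
tables with N ≤ 40 — sizes at which exhaustive enumeration is exact
and the whole suite completes in well under a minute of compute.
Degenerate inputs are handled by explicit rules stated above
(zero-variance pixels, constant patches, empty margins, ties); all
randomness descends from explicit integer seeds, and fixed seeds give
bit-identical stacks, cohorts and reports.
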