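# Methods

`mucotex` quantifies the textural difference between normal oral mucosa and
leukoplakia lesions on standardized photographic regions of interest (ROIs)
and classifies individual images with a probabilistic neural network (PNN).
Because no public photograph collection exists for this problem, the package
ships a synthetic texture generator that reproduces the *qualitative* contrast
between the two tissue classes; everything downstream of image loading is
identical for real and synthetic inputs.

## Preprocessing

Photographs pass through a fixed chain before any feature is computed:

1. **ROI crop** — a 300 × 300-pixel window centred on the lesion (or a matched
   healthy site). All coordinates are 0-based, row-major, origin top-left.
2. **Grey conversion** — Rec. 601 luma, `round(0.299 R + 0.587 G + 0.114 B)`.
3. **High-pass filter** — the unsharp-style residual
   `clip(img − gaussian_blur(img, σ=radius) + 128)` with default radius 10 px.
   This construction keeps the operation parameterized and testable: a
   constant image maps exactly to mid-grey 128, and the output of any texture
   stays centred near 128.
4. **Level equalization** — a linear contrast stretch mapping the observed
   minimum to 0 and maximum to 255. A monotone linear map unifies contrast
   across images while preserving the grey-level ordering that the texture
   matrices depend on; classical rank-based histogram equalization is
   available behind `equalize_mode="rank"` but is not the default because it
   rewrites the grey-level *spacing* as well.
5. **Quantization** — uniform binning to 4-bit grey,
   `level' = floor(level · 16 / 256)`, giving the 16-level images on which all
   texture matrices are built.

The high-pass radius and equalization mode are deliberately configuration,
not constants: neither is uniquely determined by the preprocessing goal, and
both materially change feature magnitudes (see *Limitations*).

## Texture features

Six features per image, all computed on the 16-level preprocessed ROI. The
matrix features are averaged over the four principal directions
(0°, 45°, 90°, 135°), which removes orientation dependence; per-direction
values remain accessible.

**Run-length matrix (RLM).** `p(i, j)` counts maximal runs of grey level `i`
and length `j` along a scan direction; `C = Σ p(i, j)` is the number of runs
and `N_r` (the matrix width) is the maximum possible run length,
`max(H, W)`. The two inverse-moment emphasis statistics are

    LngREmph = Σ_ij j² p(i,j) / C ≥ 1,
    ShrtREmph = Σ_ij p(i,j)/j² / C ∈ (0, 1],

with both equal to 1 exactly when every run has length 1. Fine chaotic
texture (many short runs) pushes ShrtREmph toward 1; homogeneous plates pull
it down.

**Co-occurrence matrix (GLCM).** The symmetric, normalized joint distribution
`p(i, j)` of grey pairs at inter-pixel distance 5. Diagonal displacements use
chessboard geometry (45° at distance d pairs pixels offset (−d, +d)); borders
are skipped, not padded, and the normalizer is the realized pair count.
Entropy `−Σ p log p` (in nats; range `[0, 2 ln 16]`) and difference entropy,
the entropy of the `|i − j|` marginal (range `[0, ln 16]`), measure pair
disorder. Natural logarithms are used throughout — with 16 grey levels this
puts entropy on the familiar ~0–5.5 nat scale. The row/column marginal
moments (μ_x, μ_y, σ_x, σ_y) are computed and stored for extension
(correlation-type features) but no shipped feature consumes them.

**Haar wavelet energy.** Orthonormal 2-D Haar analysis
(`L = [1/√2, 1/√2]`, `H = [1/√2, −1/√2]`), recursing on the LL band. The
orthonormal normalization is chosen so each analysis step conserves energy
(Parseval) and constant images obey the exact closed form
`E(LL, s) = c²·4^s`. Odd subband dimensions are truncated to even before
pairing — floor halving, so a 300-pixel side decomposes
300 → 150 → 75 → 37 → 18 → 9 → 4 and scale 6 is feasible on the standard ROI;
the discarded last row/column costs a negligible energy fraction at the sizes
involved. The reported features are `E = Σ d²/n` for the LL band at scales 5
and 6, which respond to brightness organization at the 32–64-pixel scale.
Energies are reported raw in squared grey-level units; no rescaling to any
external convention is attempted.

## Group statistics

Each feature is summarized per class as mean ± sample SD (n−1 denominator),
screened with the Shapiro–Wilk test (flag at p < 0.05), and compared across
classes with a one-way ANOVA. With two groups F has df (1, n_A + n_B − 2) and
equals the squared pooled two-sample t — an identity the tests exploit as an
oracle. The normality flag is reported but never gates the ANOVA; features
flagged non-normal are still tested, matching how such feature tables are
conventionally reported. Both scipy routines are used behind the module's
own validation and degenerate-input contracts.

## PNN classifier

Specht's classical probabilistic neural network on three inputs: ShrtREmph,
Entropy and WavEnLL at scale 5. Features are z-scored with training-set
statistics; each class stores its training vectors verbatim; the class score
of a query is `prior · mean exp(−‖z − z_i‖²/(2σ²))`. Design choices:

* **Single isotropic σ in standardized units**, tuned by maximizing
  leave-one-out (LOO) accuracy over a geometric grid (0.05–3, 25 points);
  ties resolve to the smallest candidate.
* **Evaluation is leave-one-out**, with standardization re-estimated inside
  every fold. LOO is the defensible protocol at n = 70; resubstitution is
  additionally available behind `report_resubstitution` for comparison. A
  consequence of per-fold standardization is exact invariance of the
  evaluated metrics to affine rescaling of any input column.
* **Ties predict the lesion class.** In a screening instrument false
  negatives are costlier than false positives; the rule is configurable.
* **Priors default to empirical class frequencies** (0.5/0.5 in the balanced
  designs used here).

Consistency is checked against the analytic Bayes error: for two
unit-variance isotropic Gaussian classes with mean separation 2, the Bayes
error is Φ(−1) ≈ 15.87%, and the tuned PNN's LOO error at n = 200/class lands
within about 2 percentage points of it (seed-to-seed spread of a few points
is expected at this sample size).

## Synthetic textures

The generator emulates the two texture classes described for this screening
problem:

* **normal** — Gaussian white noise smoothed with correlation length 1 px and
  rescaled to the full 8-bit range: fine, chaotic, spatially even texture.
* **lesion** — noise smoothed with correlation length 12 px, thresholded at
  the 0.15 quantile into dark foci set in a bright surround; each of the two
  plate sets is filled with its mean level plus 4 grey levels of within-plate
  noise. This mirrors the clinical description of lesions as dark low-entropy
  foci mixed with homogeneous bright plates.

Both classes share one code path, so matching the lesion parameters to the
normal ones (correlation length 1, plates off) reproduces the normal texture
bit-for-bit — a built-in null for the downstream statistics. Cohorts derive
per-image seeds from a master seed via `numpy.random.SeedSequence`, making
them reproducible across platforms.

The defaults were fixed once, during generator design, to realize the
documented class contrast after the *full* preprocessing chain: lesions score
lower on ShrtREmph, entropy and difference entropy, and higher on LL wavelet
energy at scales 5 and 6. The wavelet direction deserves comment, because the
high-pass stage removes most brightness structure at the 32–64-pixel scales
those features see. Two surviving mechanisms carry it: the partial
transmission of plate contrast in the band where the high-pass and the
scale-5 block average overlap, and — dominantly — the brightness asymmetry of
the thresholded texture: small dark foci produce deep negative high-pass
excursions, so the subsequent min/max stretch shifts the bulk of the lesion
image above mid-grey, raising its deep-scale LL energy relative to the
symmetric normal texture. A symmetric equal-band plate design, by contrast,
cannot produce this separation at all once the high-pass is applied.

What the generator does **not** emulate: colour and vascular patterns,
specular reflections, illumination gradients, lens geometry, or any
histological ground truth. Passing the synthetic end-to-end experiment shows
that the pipeline's machinery is correct and sensitive to the documented
direction of each contrast — it says nothing about clinical accuracy on real
photographs.

## Problem sizes and numerics

The default end-to-end experiment uses 35 images per class (the size of the
motivating clinical cohort) at 300 × 300 pixels; the statistical calibration
checks use 2 000 null replicates (ANOVA type-I error) and 200 cases per class
(PNN versus Bayes error). These sizes give the quoted checks comfortable
statistical resolution while keeping a full run on one CPU core in the
tens-of-seconds range.

Numerical conventions: 0·log 0 = 0 in all entropies; GLCM normalization is
validated to 1e−8 before an entropy is computed; Parseval holds to 1e−9
relative; feature values are float64 end to end. Degenerate inputs (constant
images, zero-variance features, empty run sets) raise typed errors rather
than returning NaNs.

## Limitations

* Feature magnitudes depend on the preprocessing parameters (high-pass
  radius, equalization mode, bit depth); published magnitude tables for this
  problem are not reproducible without the original software's undocumented
  internal scaling, so only effect *directions* are validated.
* The GLCM direction policy (average over four directions) and the diagonal
  chessboard geometry are conventions; single-direction values are exposed
  for sensitivity analysis.
* σ selection and evaluation share the same LOO loop, a mild optimism at
  small n; the Bayes-consistency check bounds its practical effect.
* The sliding-window feature maps are reference implementations (quadratic in
  image size) intended for figures, not throughput.
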