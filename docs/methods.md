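# Methods

This note records the models, conventions and numerical choices behind
`gelcorr`, in the order the pipeline applies them.

## Input model

A study is a CSV manifest (one row per sample: `sample_id`, `signal_path`,
optional `standard_path`, `include`, then variable columns) referencing 8- or
16-bit grayscale PNGs. Stored intensities are preserved at load — an 8-bit
image yields 0..255, a 16-bit one 0..65535, with no rescaling — so raw units
remain inspectable; per-image normalization (below) is the only intensity
adjustment. RGB images are averaged to gray with a logged warning. Excluded
samples (`include = false/0`) are dropped before any computation.

External variables must be numeric or *ordered* categories. Ordered
categories are encoded as 0-based consecutive ranks; because every statistic
downstream is rank-based, any monotone encoding would give identical results
(this is tested as a property).

## Alignment

Each image carries a 4-parameter similarity transform to the reference:

    F(p) = s · R(θ) · (p − c) + c + t

with p = (x, y) (x = column rightward, y = row downward), pivot
c = ((W−1)/2, (H−1)/2) at the image center, θ in degrees counter-clockwise
on screen, uniform scale s > 0 and translation t in pixels. The order
scale→rotate→translate and the center pivot are conventions: any similarity
is expressible in this form, and fixing one makes alignment files portable.
The family is deliberately *not* extended to warping: a non-rigid fit could
manufacture or destroy spot shapes, the very signal the analysis reads.

Resampling is done once per image by inverse mapping (bilinear by default,
nearest available for exactness). An output pixel whose source coordinate
falls outside [0, W−1] × [0, H−1] (tolerance 1e−9 for border grid points)
becomes *missing data*: masked, excluded from every downstream statistic.
Feeding zeros instead would fabricate border anti-correlations.

Headless parameter sources: alignment JSON/CSV files, or a least-squares
(Umeyama) similarity fit to landmark pairs. The fit needs the pivot to
express its result in the center-pivot parameterization, so
`estimate_from_landmarks` takes a `center` argument (default (0, 0); pass
the image center for image landmarks). Transforms estimated on alignment-
standard images are applied unchanged to the signal images — same camera
geometry — so alignment stays blind to biology.

## Normalization

Per-image, over valid pixels only: `mean` (divide by mean), `median`
(divide by median; the default — robust to a few saturated spots), `zscore`
(subtract mean, divide by population σ, divisor N), or `none`. There is no
grand-reference rescaling afterwards and no background subtraction.
Degenerate images (zero scale statistic, constant image under z-score) raise
rather than silently producing infinities.

One real subtlety, visible in the test suite: the per-image median is
*estimated* from a noisy image, and on a skewed intensity distribution the
sample median carries a small bias that scales with relative noise. When
per-image noise-to-scale ratios differ systematically across the series (as
with strong exposure jitter), this injects a small common-mode trend into
all normalized pixels. On 96×96 images at 5% noise the effect on the mean
correlation is ≈ 0.05; it shrinks with image area. This is a property of
any per-image scale estimate, not an implementation artifact.

## Correlation and significance

For each pixel, Spearman rho is the Pearson correlation of midranks
(average ranks for ties) of the valid samples at that pixel against the
corresponding variable values. Pixels with fewer than `min_valid` valid
samples (default: all n, relaxable to ≥ 3) or a constant intensity column
are masked. Pixels are grouped by validity pattern and processed vectorized
per group.

Significance is two-sided throughout (both induction and suppression are
meaningful):

- **t-test**: t = rho·√((n−2)/(1−rho²)), Student-t with n−2 df; requires
  n ≥ 4. |rho| = 1 clamps p to the smallest positive double, and every p is
  clamped into [tiny, 1], so significance factors never round to exactly 1.
- **permutation**: the variable's rank vector is permuted; with average
  ranks this equals re-ranking permuted values, so ties travel correctly.
  When n! ≤ `exhaustive_limit` (default 40320 = 8!), all orderings are
  enumerated and p = #{|rho_perm| ≥ |rho_obs|}/n! is exact (the identity
  permutation makes p ≥ 1/n!). Otherwise `n_permutations` seeded Monte-Carlo
  draws give p = (b+1)/(m+1). The ≥ comparison uses a 1e−12 slack so
  floating-point ties count as ties.

`sigma_norm` is the per-pixel sample standard deviation (divisor n−1) of
the *normalized* intensities, divided by its global maximum over valid
pixels, mapping the map into [0, 1] with the most variable pixel at exactly
1. This makes the product maps dimensionless and bounded. The alternative
normalizer (coefficient of variation) was considered and rejected as
unstable where the mean is near zero (z-score scheme).

Product maps combine the three: `CS = rho·(1−p)`, `CV = rho·sigma_norm`,
`CSD = rho·(1−p)·sigma_norm`. The significance factor defaults to 1−p so
all factors lie in [0, 1] (−log10 p is available but unbounded). CV/CSD
suppress regions where correlation is strong but intensity variation is
negligible. NaN (masked) propagates through all products.

No multiple-testing correction is applied in the core maps — p is a
per-pixel raw value used as a weighting factor, not a family-wise decision
rule.

## Synthetic data generator

The generator states a world with the phenomenology the method targets:

- anisotropic Gaussian spots with amplitude `base + slope·v`, clamped ≥ 0,
  optionally gated to a covariate window (`appear_at`/`disappear_at`) to
  emulate transient spots;
- single-row horizontal streaks (laddering) with their own slope;
- constant background, additive Gaussian noise, per-image exposure scale,
  and per-image misalignment (applied last, bilinear), final clamp at 0;
- fully deterministic given the spec seed (per-image child seeds).

The `p53_timecourse` preset fixes the stated conditions: five 96×96 images
at 0, 2, 4, 6, 8 hours; a five-spot chain (base 300, slope 120/h, so peak
amplitude runs 300→1260 counts); two growing high-pI streaks; one spot
appearing mid-series; two weak short-isoform spots; exposure scales
0.92–1.15; noise σ = 48 counts = 5% of the 960-count peak modulation depth;
misalignments up to 1.4° rotation, 0.6% scale, 2.5 px translation.

Ground truth accompanies every stack: the exact misalignments and their
correcting inverses, a *responsive mask* (pixels whose noise-free modulation
depth across the series is ≥ half the maximum depth — the analogue of
thresholding a result map at half max), spot-core masks (1σ ellipses of
slope-positive spots) and a background mask (depth < 1% of max).

What the generator does **not** emulate: irregular spot shapes, spatially
correlated backgrounds, saturation, blotting artifacts, camera PSF. The
pipeline is shape-agnostic by construction, so Gaussian spots suffice to
test localization; a green localization test establishes that the pipeline
recovers where and with which sign a known monotone modulation occurred, not
that it would quantify real chemiluminescence accurately.

The generated stack's validity mask is all-true, mirroring freshly loaded
camera images; the fabricated zero-fill border that misalignment leaves is
indistinguishable from data until the correcting alignment masks it, exactly
as with real images. Interior comparisons after a misalign + correct
roundtrip tolerate two bilinear passes (error ∝ spot curvature).

## Statistical facts worth remembering when reading results

- With n = 5 samples the null expectation of |rho| is ≈ 0.45 — a pixel map
  of pure noise is *not* pale. Judge maps by coherent regions, the signed
  mean over regions, and the CSD product, not by scattered high-|rho|
  pixels.
- Exhaustive permutation p is discrete: with n = 5 the smallest attainable
  two-sided p is 2/120 ≈ 0.0167; "p = 0.03" class statements are at the
  resolution limit of such a design.

## Determinism and provenance

Every stochastic step (noise, Monte-Carlo permutations) flows from explicit
seeds; two runs with the same manifest, config and seed produce byte-
identical text exports. `analyze` writes a run log with SHA-256 checksums of
the manifest and every image, the full config, and library versions.

## Known limitations

- Alignment parameters must come from files or landmarks; there is no
  intensity-based automatic registration (by design — standards-based manual
  alignment avoids biasing on biological signal).
- No background correction is implemented; images are assumed
  background-comparable after per-image normalization.
- ROIs are axis-aligned rectangles.
- The permutation map enumerates up to 8! orderings per validity group;
  beyond that Monte-Carlo sampling bounds p away from 0 at 1/(m+1).
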