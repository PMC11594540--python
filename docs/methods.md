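# Methods

`exmplate` implements two quantitative analyses for expansion microscopy
(ExM) performed in 96-well plates, together with a synthetic-image generator
that provides ground truth for every stage.

## 1. Nuclear-periphery ring profiling

### Procedure

For each imaged field the analysis works on a single optical slice — the
**midplane**, the z-plane whose largest thresholded component has maximal
cross-sectional area (ties break to the lowest index). The nucleus is
segmented on that plane by thresholding (Otsu by default; fixed-value and
quantile thresholds are available), keeping the largest 8-connected
component and filling interior holes. Explicit quality-control rules replace
manual curation: a mask is rejected if its area is below `min_area`
(default 500 px²), if its solidity (area / convex-hull area) is below
`min_solidity` (default 0.85), or if it touches the image border. The mask
is then dilated with the 4-neighborhood (cross) structuring element —
`max(3, round(0.1 × equivalent radius))` iterations by default — so the
profile includes a background reference just outside the nuclear periphery.

Because nuclei are irregular, radial structure is measured with an
**onion-peel ring decomposition** rather than circular annuli: the mask
pixels 4-adjacent to the outside (or on the image border) form ring 0, the
boundary of the remainder ring 1, and so on until every pixel is grouped.
A pixel's ring index equals its city-block distance to the mask complement
minus one; the implementation peels iteratively, and the test suite checks
it against an independent chamfer-distance oracle. Mean intensity per ring,
read edge → center, is linearly interpolated onto exactly **500 samples**
at positions u = i/499 ∈ [0, 1] (0 = dilated-mask edge, 1 = innermost
ring) and normalized, by default so the maximum is 1 ("relative
intensity"); an alternative maps the background (outer 2% of positions) to
0 and the maximum to 1.

Three scalar **edge metrics** summarize the peripheral peak via finite
differences (central in the interior, one-sided at the endpoints, step
h = 1/499 in normalized units; the second derivative applies the scheme
twice):

* `outer_slope` — global maximum of dI/du (background → peak rise);
* `inner_slope` — minimum of dI/du over u ∈ [0, 0.4] (peak → nucleoplasm
  descent);
* `peak_curvature` — minimum of d²I/du² over u ∈ [0, 0.4].

The cap at u = 0.4 (inclusive) keeps the restricted extrema at the
periphery. No smoothing is applied before differentiation by default; an
optional moving-average width exists for noisy single-nucleus profiles and
is recorded in all outputs. Note that on a piecewise-linear interpolated
profile the second derivative concentrates at ring knots, so per-nucleus
curvature values are much larger in magnitude than those of smooth
condition-mean curves; comparisons are only ever made between groups
processed identically.

### Statistics

Profiles are aggregated per condition with pointwise mean and SEM across a
chosen unit of replication: individual nuclei (suited to pre-expansion
data, where each nucleus is an independent image) or replicates (expanded
plates, where the replicate mean over its nuclei is the independent unit).
Each treated condition is compared to control by a two-sided independent
two-sample t-test per metric — Student's pooled-variance by default, Welch
optional — at α = 0.05, with no multiplicity correction by default
(a Benjamini–Hochberg option exists and is off by default). Two groups with
zero variance and equal means report t = 0, p = 1 rather than an error.

## 2. Expansion-quality metrics

### Expansion factor

The expansion factor of a gel is the mean over landmark pairs of the ratio
(post-expansion distance) / (pre-expansion distance). Landmarks may be
supplied (e.g. manually measured pairs) or detected as centroids of
thresholded objects; detected objects touching the image border are dropped
because clipping biases centroids inward. Detected landmark sets are
matched across the unknown isotropic scaling by predicting positions with a
first-pass scale (ratio of RMS distances to the landmark centroid) and
pairing nearest predictions first.

### Non-rigid registration and error curves

Distortion between a matched pre/post field pair (nominally 400×400 px) is
the smooth residual displacement left after the best similarity transform:

1. rotation and isotropic scale are estimated from the log-polar transform
   of the FFT magnitude spectra (Fourier–Mellin, phase-normalized
   correlation; rotation is disambiguated mod 180° by trying both
   candidates), translation by phase correlation; the expansion factor can
   be read off this similarity scale;
2. the aligned pre image is histogram-matched to the post image
   (normalizing first would scramble the images, because the two fields
   contain very different foreground fractions);
3. a feature mask excludes regions featureless in either image
   (Gaussian blur at σ = 8 px, keep pixels above the 0.6 intensity
   quantile in both);
4. a coarse node grid (spacing 24 px) is block-matched by upsampled phase
   correlation; any residual similarity component of the node field is
   re-fit by least squares and folded back into the similarity transform;
   the nodes are interpolated to a full-resolution smooth field (bivariate
   spline) with zero mean over the feature mask.

The field is summarized as an **error curve**: seeded random point pairs
(p, q) are drawn within the feature mask; the measurement length is
ℓ = |p − q| (post-expansion µm) and the pair error |d(p) − d(q)| (a
relative measure — any uniform translation drops out). Pairs are binned by
ℓ (bin width 2 µm, ~2000 pairs per bin by default); each bin reports the
RMS error against the quadratic-mean length, a pairing under which an
affine field d(x) = A·x satisfies rmse(ℓ) = |A|·ℓ exactly. The scalar
summary is the **average percent error**: the mean over curve points with
ℓ ≤ 40 µm of rmse(ℓ)/ℓ, × 100. Plates are compared by one-way ANOVA on
per-gel values with post-hoc Tukey HSD at α = 0.05.

The registration backend is deliberately replaceable: correctness is
defined by recovery of known synthetic deformation fields (mean endpoint
error < 0.5 px at peak SNR ≈ 10), not by equivalence to any external
B-spline implementation.

## 3. Synthetic-image generator

The generator emulates Hoechst-stained nuclei with analytic ground truth.

* **Shape**: star-convex boundary r(θ) = R·(1 + Σₖ aₖ cos(kθ + φₖ)),
  harmonic orders ≥ 2, Σ|aₖ| < 0.5 (bounded by the `irregularity`
  parameter, typically 0.05–0.25).
* **Radial intensity**: g(u) = B + (P − B)·S((u − u₀)/w) +
  A·exp(−(u − u₀)²/2σ²), with S the logistic sigmoid and u the normalized
  inward distance from the analytic boundary (0 just outside, 1 at the
  center). Rendering evaluates g from the exact boundary, never from a
  pixelated distance transform, keeping ground truth independent of the
  pipeline under test. Defaults, read off the shape of measured
  dose-series curves: background B = 0.10, nucleoplasm plateau P = 0.40,
  peripheral peak A = 0.50 at u₀ = 0.08 with width σ = 0.06 and rise
  width w = 0.05 (relative units).
* **z structure**: the boundary radius scales as the ellipse cap
  √(1 − (Δz/z_half)²), giving a unique largest cross-section at the
  recorded midplane.
* **Noise**: Poisson on scaled intensity plus additive zero-mean Gaussian
  (the standard fluorescence camera model). Defaults
  (poisson_scale = 150 photons per intensity unit, σ_read = 0.02) give a
  peak SNR near 10.
* **Dose model**: the dose series control / 1 nM / 10 nM / 100 nM / 1 µM
  maps to multiplicative effects on the peripheral peak, default
  amplitudes (1, 1, 1.5, 2, 2) and widths (1, 1, 0.8, 0.7, 0.7). The
  width (sharpness) component is deliberate: the phenotype of interest is
  a sharper edge-to-background transition, and under max-normalization a
  pure amplitude change would barely move the slope metrics. Per-nucleus
  biological variability is multiplicative with mean 1 (CV 0.10 on the
  amplitude), so specified means are preserved. The Gaussian-peak form of
  the dose effect is a modelling choice for testing, not a claim about
  chromatin biology.
* **Expansion pairs**: the post image is the pre image resampled under
  x → c + s·(x − c) + d(x), with s the expansion factor (~4.2 in this
  application) and d a smooth random field (Gaussian-filtered white noise,
  rescaled to a maximum amplitude, discrete gradient ≲ amplitude /
  smoothness-length) or any supplied field; the map is inverted by fixed-
  point iteration for resampling. The ground truth (s, d) is retained.

What the generator does **not** emulate: optics (no PSF beyond the smooth
profile), spectral crosstalk, uneven illumination, out-of-focus signal,
touching/overlapping nuclei, gel-specific artifacts (tears, debris,
residual undigested signal), or microtubule-like filament texture — real
registration inputs are far richer in features than these blob fields.
Passing tests therefore demonstrate the correctness and calibration of the
computations, not performance claims on real microscopy data.

## Numerical and design notes

* Connectivity: 8-connectivity for component labelling; the 4-neighborhood
  everywhere in peeling and dilation (the decomposition's defining
  connectivity).
* Ring abscissa: ring j is placed at u = j/(n_rings − 1). When comparing
  a measured profile to analytic ground truth on a disk, note a geometric
  subtlety of the city-block metric: a taxicab layer at depth c has mean
  Euclidean depth (4/π)·sin(π/4)·c ≈ 0.90·c, because layers run deeper
  along diagonals. The fidelity tests use this mapping; agreement is
  within 0.02 of normalized intensity at radius 60 px.
* Degenerate inputs: empty masks, all-zero profiles, single-ring masks,
  empty restricted metric domains and zero-length manifests raise
  immediately with specific errors; an unregistrable field pair (alignment
  correlation below 0.1) is flagged and excluded, and the distortion
  pipeline continues.
* Determinism: every simulation and sampling step takes an explicit seed;
  pipelines re-run from a serialized `RunConfig` reproduce outputs byte for
  byte.
* Problem sizes for the statistical studies: simulated plates use
  112×112 px fields with base radius 22 px; the null calibration runs 200
  plates of 5 conditions × 4 replicates × 6 nuclei (the type-I rate does
  not depend on the per-replicate count), and the power study runs 50
  simulations at 4 replicates × 25 nuclei per condition with a 1.5×
  amplitude / 0.8× width effect, the generator's 10 nM-like dose.
* The t-test operates on replicate means (df = 6 at 4 vs 4), which are
  close enough to normal for nominal calibration; the measured null
  significance rate over 200 plates is 0.04–0.06.

## Known limitations

* The block-matching registration assumes locally near-constant
  displacement within a patch; deformations with wavelength below ~4× the
  grid spacing are attenuated. The similarity re-fit absorbs any global
  affine leakage but not higher-order trends.
* Expansion factors from detected landmarks need at least two well-
  separated objects fully inside both fields.
* QC thresholds are stand-ins for expert curation and should be reviewed
  per dataset; they are configurable and serialized with every run.
* Second-derivative (curvature) values on interpolated per-nucleus
  profiles are knot-dominated (see above); treat them as comparative
  statistics, not as estimates of the true curve's curvature.
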