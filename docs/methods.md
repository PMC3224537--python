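# Methods

## Pipeline model

A sample is a 32 × 32 grayscale patch x (row-major vector, ℝ¹⁰²⁴)
obtained by discrete histogram equalization followed by bilinear
resizing. Equalization maps level v through the empirical CDF,
`out(v) = round(255·(cdf(v) − cdf_min)/(N − cdf_min))`, with N the
pixel count; a constant image (cdf_min = N) is returned unchanged.
Equalization runs *before* resizing. Resizing samples the input at
half-pixel-centered coordinates with bilinear weights; the scheme and
the 256-level bin count are package conventions — nothing in the
problem fixes them — and both are pinned by brute-force oracles in the
tests.

Three linear representations of x are implemented:

**PCA.** Covariance of the mean-centered training columns with
1/(n−1) normalization, eigendecomposed via the thin SVD of the
centered data matrix; eigenpairs sorted by decreasing variance, signs
fixed so the largest-magnitude entry of each component is positive.
Held-out data are centered with the *training* mean — the only
leakage-safe choice. Components for classification are used in
variance order; no wrapper selection.

**Efficient coding / FastICA.** Training columns are centered and
sphered through the same SVD (directions below `var_floor = 1e-10`
relative variance dropped). The parallel fixed-point update
`w ← E[z·g(wᵀz)] − E[g′(wᵀz)]·w` runs on all rows with symmetric
decorrelation each sweep; convergence is `max_row(1 − |cosΔ|) < 1e-4`
within 200 sweeps by default. The contrast is G(u) = log cosh u
(g = tanh), the standard robust choice; `exp` and `cube` are also
available. E[G(ν)] for Gaussian ν is computed once by 201-point
Gauss–Hermite quadrature. A non-converged fit (e.g. on Gaussian data,
where independent directions are unidentifiable) is returned flagged
with its convergence log, never raised. The input-space filters are
W·K (K the whitening map) and the basis images A = K⁺·Wᵀ, so
filters·basis = I on the retained subspace.

**Gabor bank.** Mother kernel
g(x, y) = exp(−½(x²/σx² + y²/σy²))·cos(2πF·x) rendered on the centered
grid; member (m, n) uses coordinates rotated by θ = nπ/k and shrunk by
a^(m−1), giving carrier frequency F·a^−(m−1). Defaults: F = 0.4
cycles/pixel at m = 1, a chosen so 10 scales tile down to 0.05
cycles/pixel, σx = σy = 1.5 px (≈1 octave bandwidth at F). None of
these numbers is externally prescribed; they are package defaults
exposed in `GaborParams`. Every kernel is DC-corrected to exactly zero
mean and L2-normalized, which makes projections invariant to additive
intensity offsets. Features are single inner products on the grid —
deliberately parallel to the PCA/ICA projections, not convolution +
pooling.

## Selection and classification

The greedy wrapper grows a subspace Ψ from an empty set: each step
refits Fisher LDA on the training coefficients of [Ψ; candidate] for
every remaining candidate, scores *training-set* accuracy, and keeps
the argmax; ties break to the lowest candidate index, making the
procedure fully deterministic. Training-set accuracy (not an internal
validation split) is the faithful default criterion; the greedy order
is prefix-consistent, which the component sweep exploits by selecting
once per fold up to the largest requested count.

Fisher LDA uses B = Σᵢ nᵢ(x̄ᵢ − x̄)(x̄ᵢ − x̄)ᵀ and the pooled
within-class scatter W (nᵢ-weighted, i.e. raw sums of squared
deviations). β is the top generalized eigenvector of (B, W),
unit-normalized and oriented so the disease class has the larger
projected mean; the threshold is the midpoint of the projected class
means (equal priors), and exact-threshold scores go to the negative
class. A singular W receives a ridge λ·tr(W)/p with λ = 1e-6 so the
wrapper can probe near-degenerate subspaces without crashing. The
benign/malignant task reuses the identical binary machinery with
"malignant" as the positive class.

Cross-validation is stratified: each class is independently permuted
by the seeded generator and split into k nearly-equal runs, so
per-class fold counts differ by at most one (3240 + 1850 samples at
k = 10 give exactly 324 + 185 = 509 per test fold). Extractor,
selection and LDA see only the training folds; metric means are
unweighted fold averages. The operational leak detector is the
permuted-label null: any train/test leakage through the wrapper would
lift held-out accuracy above the majority-class rate.

## Synthetic data

Non-mass patches are a stationary Gaussian random field (white noise
smoothed by an isotropic Gaussian of the configured correlation
length, normalized to unit variance) scaled to texture SD 30 around a
base level of 100, plus white pixel noise (SD 10); intensities are
clipped to [0, 255] and stored 8-bit, the digitized-film convention
the equalization step expects. Mass patches add a bright blob
amp·exp(−(d/R)^p) with amp = blob_contrast × 2.5 × texture SD, radius
R ~ U(6, 8) px, center jittered ±5 % of the patch. Malignant masses
(spiculation s ∈ [0,1], default 0.6) get an irregular contour (random
angular harmonics 3–6 modulating R by ±35 %·s), a size lift
(+40 %·s), a sharper profile (p = 2 + 2s) and a log-normal contrast
jitter — a caricature of margin/shape lexicon descriptors, with no
claim of radiographic realism.

The texture law and the blob gain are calibrated to the generator's
contract: `blob_contrast = 0` makes the class laws identical,
≈0.3 is near chance, and ≈1.5 yields ≥95 % CV accuracy for all three
pipelines at 400 samples. Because equalization preserves only rank
information, raising the blob amplitude saturates; the correlation
length (1.5 px) is what controls the matched-filter ceiling, and was
set with that in mind. What passing tests on this generator show is
that the *pipeline machinery* (whitening, FastICA, selection, LDA, CV
bookkeeping) behaves correctly and that accuracy responds
monotonically to separability — not that any particular accuracy would
transfer to real screen-film mammograms, whose texture statistics,
lesion morphology and label noise the generator does not model.

## Problem sizes and defaults

- End-to-end evaluations and the acceptance script run at 400 samples
  (200/200) for the mass task and 324 (154/170, preserving the
  1540:1700 ratio) for the benign/malignant task — the package's desk
  scale for simulation studies.
- The full-rank efficient-coding fit (1024 basis functions) is
  demonstrated on 1100 synthetic ROIs with 20 fixed-point sweeps; at
  that dimensionality the fit is reported with its honest convergence
  flag, since the shape of the model (basis count, W·A = I) is the
  property of interest.
- Inside cross-validation the ICA candidate pool defaults to the
  requested component count. A pool of whitened, unit-variance
  directions much larger than the training support makes the
  training-accuracy wrapper prefer overfitted directions (measured:
  pool 60 → 0.80 held-out accuracy where pool 20 → 0.965 on identical
  data); matching the pool to the budget lets FastICA do the
  compression while the wrapper orders its output. Explicit larger
  pools remain available via `MethodConfig.ica_candidates`.
- Default component counts elsewhere follow the 30–50 regime the
  component sweeps favor; `sweep` exists precisely to choose this
  per dataset.

## Known limitations

- Binary tasks only; the two clinical questions are run as separate
  binary problems, not one three-way classifier.
- The benign/malignant synthetic encoding is mostly a second-moment
  difference; a linear discriminant on equalized patches caps out
  around 0.65 accuracy there (matched-filter ceiling ≈ d′ 0.9 before
  the shape lift). That ceiling is a property of the synthetic law,
  reported as-is.
- Gabor features are plain projections; energy/texture statistics
  (magnitude pooling) would be stronger in practice but are out of
  scope by design.
- FastICA determinism holds for fixed seed, data and BLAS; across
  BLAS builds low-order sign/permutation differences are possible
  (the Amari-index tests are invariant to these).
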