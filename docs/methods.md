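# Methods

This note documents the models implemented in `btfsc`, the assumptions
behind them, the defaults that matter, and the design choices made where
the design was genuinely open.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and data model

The pipeline operates on pairs of co-registered 2-D grayscale images
(MRI + CT; color PET/SPECT inputs are reduced to Rec. 601 luminance).
Registration is assumed, not performed.  All stages exchange float arrays
normalized to [0, 1], row-major (row, col), at least 8×8.  Binary tumor
masks share the image grid.  3-D volumes are handled only by slicing
(NIfTI inputs require a slice index).

## Synthetic phantoms: what they emulate and what they do not

The generator produces the complementary contrast that makes multimodal
fusion worthwhile: MRI shows soft tissue (background 0.05, brain 0.55 with
a ±0.04 low-frequency modulation, tumor 0.85) while CT shows bone (skull
ring 0.95, brain 0.35, tumor 0.55).  The class distinction uses two
clinically motivated surrogates: malignant tumors get a radially perturbed
boundary (relative amplitude 0.35, smooth harmonics 2–6) and i.i.d.
interior speckle (σ = 0.15); benign tumors are smooth ellipses whose axes
r·u and r/u (u ∈ [0.9, 1.1]) keep the analytic area πr² exact.  Tumor
radii span 6–18 % of the image side (default 128 px).  Sensor noise is
i.i.d. additive Gaussian, clipped to [0, 1]; the ground-truth mask marks
exactly the pixels assigned tumor intensity before noise, making the
generator usable as a pixel-exact oracle.

What the phantoms do *not* model: anatomy (gyri, ventricles, tissue
classes), MRI sequence physics (T1/T2/FLAIR contrast, Rician noise, bias
fields), partial-volume effects, 3-D structure, or registration error.
Passing tests on phantoms therefore demonstrates algorithmic correctness
and the intended interplay of the stages — not clinical performance.

## HPWF denoising

Assumes X = O + G with i.i.d. Gaussian G.  σ̂ is the Immerkær estimator:
σ̂ = √(π/2)·Σ|X ∗ L| / (6(W−2)(H−2)) with the 3×3 Laplacian-difference
mask L, evaluated on the interior so padding never contributes; it is
exact-zero on constant and affine images.  For each mask size w ∈ {3, 5}
(odd, ≥ 3): local box mean and population variance with symmetric
(reflect) padding — chosen to avoid dark halos at the skull edge — then
the Wiener gain g = max(0, σ²_w − σ̂²)/max(σ²_w, ε), ε = 1e-8, and
output mean + g·(X − mean).  The per-window outputs are averaged with
equal weights and clipped.  g ∈ [0, 1) makes the filter a contraction
toward the local mean; it is not idempotent.  Non-Gaussian (Rician) noise
is out of scope.

## REA edge/slope decomposition

The edge-with-slope layer R minimizes the quadratic
E = ξ(|ψR − (M−C)′|² + |ψR − (M+C)′|²), where (·)′ subtracts the image
mean and ψ is the discrete 5-point Laplacian applied with periodic
boundary, which makes ψ self-adjoint so the analytic gradient
2ξ·ψ(2ψR − t₁ − t₂) is exact.  ψ is pluggable.  The two-term objective has
the same minimizer as the single-term objective with the averaged target
(the mean-subtracted M); the test suite verifies this against a
closed-form FFT-diagonalization solution.

Solver: gradient descent from R = 0, step size starting at 1.0 and halved
under an Armijo condition, so the energy trace is non-increasing on every
input.  Stopping: relative energy decrease < tol (default 1e-4) or
max_iter (default 100); hitting the cap returns the best iterate flagged
unconverged.  Defaults ξ = 1.0.

Two numerical facts shape how R behaves.  First, the fully converged
minimizer is a Poisson-smoothed field: the edge *response* spreads as
iterations accumulate, because the Laplacian's small eigenvalues converge
last.  Early-stopped descent fits the high-frequency components first, so
with a small iteration budget |R| concentrates within ~2 px of intensity
discontinuities; the iteration budget is thus the localization
regularizer, and the default budget trades localization for energy
reduction.  Second, with the relative-energy stopping rule the gradient
norm at exit is not guaranteed to be a fixed small multiple of its initial
value; convergence to the true minimizer is instead verified at tight
tolerances against the FFT oracle.

## Fusion

Default ("activity") weights: w_a = (v_a + τ)/(v_a + v_b + 2τ), where
v are 7×7 local variances, optionally Gaussian-smoothed (σ = 2 px), and
τ = 3e-3 is a variance floor.  The floor matters: without it, residual
noise variance in flat regions makes the ratio v_a/(v_a+v_b) essentially
random pixel to pixel, and the fused image inherits that chatter; with it,
flat regions fall back smoothly to the 0.5/0.5 tie value while genuinely
textured regions still win decisively (a checkerboard against a constant
gets weight > 0.95).  Weights always sum to 1 per pixel.

The fused image is w·MRI + (1−w)·CT + γ·R, clipped, with edge-gain
γ = 0.25 re-injecting the REA edge layer.

The alternative "cnn" mode is a small fully convolutional weight branch:
a shared 3×3/64-channel stage applied to each modality, a 2×2/128-channel
stage with 2×2 max-pool (applied to the channel-sum of the two feature
stacks, making the network symmetric under swapping the modalities),
nearest upsampling, and a 3×3 head reducing the concatenation to two
channels with a per-pixel softmax.  Feature-map sizes follow the input
(the network is fully convolutional).  It runs forward-only with seeded
random initialization; no trained weights ship with the package and
training is out of scope, so the deterministic activity mode is the
default everywhere.

## HFCMIK segmentation

Per-pixel attributes: intensity and its 3×3 box mean (d = 2).  Attribute
weights are normalized inverse attribute ranges (uniform when an attribute
is constant), entering the distance d²(x, v) = Σᵢ Wᵢ(xᵢ − vᵢ)².

Initialization by weighted ranking: score every point by Σᵢ WᵢXᵢ, sort
(raw attributes as tie-breakers, making the result permutation-invariant),
split into k contiguous near-equal sets — remainder spread over the first
sets — and take each set's attribute-wise mean ("mean" rather than
"median" for determinism on even set sizes).  Fuzzy c-means then
alternates the closed-form membership and centroid updates, so the
objective Σ u^m d² never increases; points exactly on a centroid get crisp
membership (lowest index on ties).  Defaults: k = 4 (background, tissue,
skull, tumor), fuzzifier m = 2, tol = 1e-5 on the max centroid shift,
max_iter = 100.  A Gaussian-kernel-induced distance
2(1 − exp(−d²/2s²)) is available behind a flag but plain weighted
Euclidean is the default.

Tumor read-out: the cluster with the highest centroid intensity is the
candidate.  On fused head images the skull ring is as bright as the tumor
and frequently shares that cluster, and the ring can be the *larger*
connected component — selecting by size alone segments the skull.  The
tumor component is therefore the connected component maximizing the
compactness-weighted area 4π·area²/perimeter²: a compact blob beats a
thin ring of any size, for irregular (malignant) boundaries included.
Holes are filled.  This read-out is the one genuinely open design point of
the stage and is deliberately geometric rather than learned.

## Hybrid features (13, fixed order)

* GLCM (masked region): intensities quantized to 16 uniform bins; pair
  counts pooled over offsets {(0,1), (1,0), (1,1), (1,−1)} with symmetric
  accumulation, both pixels inside the mask, normalized to probabilities.
  Features: contrast Σ S_ab(a−b)², homogeneity Σ S_ab/(1+(a−b)²),
  correlation with marginal moments (defined as 1 when a marginal variance
  vanishes: a constant region is perfectly correlated with itself),
  ASM Σ S², energy √ASM.
* RDWT (whole fused image): two-level stationary (undecimated) wavelet
  transform, Haar by default, level 2 applied to LL1; all bands keep the
  input size, so band energies are circular-shift invariant and the
  inverse reconstructs to ~1e-8.  Image sides must be divisible by 4.
  Per LL band: energy (mean squared coefficient), Shannon entropy (bits,
  256-bin histogram of min-max-normalized coefficients; 0 for a constant
  band), Pearson correlation with the fused image (0 when either side has
  zero variance — no signal, unlike the GLCM convention; the asymmetry is
  intentional).
* Intensity statistics (masked region): mean and population standard
  deviation (divisor = pixel count).  On grayscale fused images these are
  intensity statistics; true per-channel color statistics would apply only
  to RGB input.

Whether features come from the lesion mask or the whole image is
configurable; the masked region is the default because the class signal
(speckle, boundary texture) lives inside the lesion.

## Feature selection (GAOM)

A genetic algorithm over binary inclusion masks: population 20,
30 generations, tournament selection (size 3), uniform crossover at rate
0.8, per-bit mutation at 0.05, elitism 2, empty masks repaired to a random
singleton.  Fitness = stratified 5-fold cross-validated PNN accuracy
− 0.01·(subset size/d), so accuracy ties resolve toward smaller subsets.
Fitness values are cached per mask; the whole search is deterministic
under its seed and never returns an empty set.

## PNN classification

Features are z-scored from the training set; constant columns are dropped
with a warning.  Every training vector is a pattern unit; class scores are
s_c = prior_c · mean_{p∈c} exp(−‖z(x) − z(p)‖²/2σ²) with priors from class
frequencies, normalized to posteriors.  As σ → 0 the posterior
concentrates on the nearest pattern's class; as σ → ∞ it converges to the
priors; a query so remote that every kernel underflows falls back to the
priors explicitly.  Prediction is argmax posterior, ties to the lower
class index.  σ is selected from {0.05, 0.1, 0.2, 0.5, 1, 2} by stratified
10-fold cross-validation (ties to the smaller σ).  The "deep" feature
learning lives in the feature extractor; the classifier itself is the
classical Specht architecture, kept shallow on purpose so that its
decision function can be verified exactly against a brute-force
kernel-density Bayes oracle.

## Evaluation metrics

Histogram-based metrics use 256 bins on [0, 1]: entropy −Σ p log₂ p,
mutual information from the 256×256 joint histogram (MI(x, x) = H(x) by
construction).  PSNR = 10 log₁₀(peak²/MSE), +∞ when MSE = 0.  SSIM uses
the standard 11×11 Gaussian window, σ = 1.5, K₁ = 0.01, K₂ = 0.03
(delegated to scikit-image).  The ten confusion metrics (accuracy,
sensitivity, specificity, precision, NPV, FPR, FDR, FNR, F1, MCC) define
any 0/0 ratio as 0 with a warning so batch evaluation never aborts.
ROC/AUC uses a threshold sweep with trapezoidal integration, equivalent to
the Mann–Whitney statistic with half-credit for ties.

## Problem sizes and determinism

Default experiment sizes — 128×128 phantoms, 50-image denoising/fusion
batches, 20-image segmentation batches, 60-image balanced classification
runs with 10-fold cross-validation — were chosen so a full end-to-end run
completes in well under a minute on one CPU while keeping the statistics
stable across seeds.  Every stochastic component (phantom geometry, noise,
GA search, CV folds, network initialization) draws from seeds derived
deterministically from a single master seed; rerunning a pipeline with the
same configuration reproduces its output tables byte for byte, and the run
manifest (config + seed + version) suffices to reproduce any run.

## Known limitations

* Phantom realism as described above; reported accuracies characterize
  the pipeline's internal consistency, not clinical performance.
* The CNN fusion branch is untrained (forward-only); the activity rule is
  the operative fusion mode.
* Segmentation emits a single binary tumor mask (no tissue labeling,
  no 3-D clustering).
* The undecimated wavelet stage requires image sides divisible by 4.
* DICOM, registration, and pseudo-color PET/SPECT re-injection are out of
  scope.
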