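# btfsc — multimodal brain-tumor fusion, segmentation and classification

`btfsc` is a Python implementation of a complete computer-aided diagnosis
pipeline for paired brain images: it denoises co-registered MRI and CT
slices, fuses them into a single image that keeps the informative detail of
both modalities, segments the tumor with a hybrid fuzzy clustering scheme,
extracts texture/wavelet/intensity features from the lesion, and classifies
it as benign or malignant with a probabilistic neural network.  It is aimed
at medical-image-analysis researchers who want a reproducible, fully tested
reference for this class of fusion-driven pipelines, exercisable end to end
on built-in synthetic head phantoms with no external data.

## The pipeline

1. **HPWF denoising.** Additive-Gaussian model X = O + G.  The noise level
   σ̂ comes from the Immerkær Laplacian-difference estimator; each pixel is
   shrunk toward its local mean with gain g = max(0, σ²_w − σ̂²)/σ²_w over
   3×3 and 5×5 masks, and the two outputs are averaged.
2. **REA edge/slope decomposition.** The signed edge layer R minimizes
   E = ξ(|ψR − (M−C)′|² + |ψR − (M+C)′|²), ψ the discrete Laplacian and
   (·)′ mean subtraction, by backtracking gradient descent (monotone energy
   trace by construction).
3. **Fusion.** Per-pixel weight maps w_MRI + w_CT = 1 from local-variance
   competition (default) or a small convolutional weight branch with a
   softmax head; fused = w·MRI + (1−w)·CT + γ·R with edge gain γ = 0.25.
4. **HFCMIK segmentation.** Pixels become (intensity, 3×3 mean) vectors
   with inverse-range attribute weights; initial centroids come from
   weighted ranking (sort by Σᵢ WᵢXᵢ, split into k equal sets, average),
   then weighted-Euclidean fuzzy c-means with memberships
   u_jc = 1/Σ_c′ (d_jc/d_jc′)^{2/(m−1)} refines them.  The tumor is the
   most compact component of the brightest cluster.
5. **Hybrid features.** Five co-occurrence statistics (contrast,
   homogeneity, correlation, ASM, energy = √ASM) on the masked lesion, the
   energy/entropy/correlation of the LL1 and LL2 bands of a two-level
   undecimated wavelet transform, and the masked intensity mean/standard
   deviation — 13 named features, optionally pruned by a genetic algorithm
   whose fitness is cross-validated classifier accuracy.
6. **PNN classification.** A Gaussian-kernel probabilistic neural network:
   per class c, s_c ∝ prior_c · mean_p exp(−‖z(x) − z(p)‖²/2σ²) over stored
   standardized patterns, with σ selected by stratified cross-validation.

## Worked example

```python
from btfsc import (PhantomSpec, generate_phantom_pair, hpwf_denoise,
                   fuse, segment_tumor, hybrid_features, dice, psnr)

noisy = generate_phantom_pair(PhantomSpec(seed=7, noise_sigma=0.05,
                                          class_label="malignant"))
clean = generate_phantom_pair(PhantomSpec(seed=7, noise_sigma=0.0,
                                          class_label="malignant"))

den = hpwf_denoise(noisy.mri)
print(f"PSNR before/after denoising: {psnr(noisy.mri, clean.mri):.2f} / "
      f"{psnr(den, clean.mri):.2f} dB")

fused = fuse(noisy.mri, noisy.ct)          # denoise -> REA -> weighted fuse
mask, model = segment_tumor(fused, k=4)    # HFCMIK + compact-component rule
print(f"Dice vs ground truth: {dice(mask, noisy.mask):.3f}")

vec = hybrid_features(fused, mask)         # 13 named features
print("glcm_contrast =", round(vec[0], 3), " color_std =", round(vec[12], 3))
```

Output:

```
PSNR before/after denoising: 26.85 / 34.23 dB
Dice vs ground truth: 0.994
glcm_contrast = 3.94  color_std = 0.086
```

The denoiser buys ~7 dB at this noise level; the segmented lesion overlaps
the ground-truth mask almost perfectly; the malignant phantom's speckled
interior shows up as high co-occurrence contrast and intensity spread,
which is what the classifier keys on.

The same stages are available from the shell:

```bash
btfsc phantom --n 60 --noise-sigma 0.05 --seed 0 --out data/
btfsc fuse data/mri_000.png data/ct_000.png --out fused.png
btfsc segment fused.png --out mask.png --k 4
btfsc features fused.png mask.png --out features.csv
btfsc pipeline --n 60 --out run/        # full end-to-end run
```

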