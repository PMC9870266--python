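"""Hybrid feature extraction: GLCM texture, two-level RDWT low-level
features, intensity statistics, and genetic-algorithm feature selection.

The 13-component hybrid vector concatenates, in fixed order:
five co-occurrence (GLCM) texture features computed on the masked region,
energy/entropy/correlation of the level-1 and level-2 approximation bands
of an undecimated wavelet transform of the fused image, and the mean and
population standard deviation of the masked intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pywt
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

from .pnn import PNNClassifier

DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

#: Fixed hybrid-vector schema (CSV column order).
FEATURE_NAMES: List[str] = [
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_correlation",
    "glcm_asm",
    "glcm_energy",
    "ll1_energy",
    "ll1_entropy",
    "ll1_correlation",
    "ll2_energy",
    "ll2_entropy",
    "ll2_correlation",
    "color_mean",
    "color_std",
]


@dataclass
class GLCMMatrix:
    """Normalized gray-level co-occurrence matrix pooled over offsets."""

    S: np.ndarray
    levels: int
    offsets: Tuple[Tuple[int, int], ...]
    symmetric: bool = True

    def __post_init__(self) -> None:
        if not np.isclose(self.S.sum(), 1.0, atol=1e-12):
            raise ValueError("GLCM must be normalized to sum 1")
        if (self.S < 0).any():
            raise ValueError("GLCM entries must be nonnegative")


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of [0, 1] intensities into ``levels`` bins."""
    return np.minimum((np.asarray(img) * levels).astype(np.int64), levels - 1)


def compute_glcm(
    img: np.ndarray,
    mask: Optional[np.ndarray] = None,
    levels: int = 16,
    offsets: Iterable[Tuple[int, int]] = DEFAULT_OFFSETS,
    symmetric: bool = True,
) -> GLCMMatrix:
    """Co-occurrence matrix of quantized intensities.

    Pairs at each offset are counted only where both pixels fall inside
    the mask (whole image when no mask is given); with ``symmetric`` each
    pair is accumulated in both orientations.  Counts are pooled over all
    offsets and normalized to probabilities.
    """
    offsets = tuple(offsets)
    if levels < 2:
        raise ValueError("need at least 2 gray levels")
    if not offsets:
        raise ValueError("need at least one offset")
    q = quantize(img, levels)
    h, w = q.shape
    if mask is None:
        inside = np.ones((h, w), dtype=bool)
    else:
        if mask.shape != q.shape:
            raise ValueError("mask shape must match image")
        inside = np.asarray(mask).astype(bool)
    counts = np.zeros((levels, levels), dtype=np.float64)
    n_pairs = 0
    for dr, dc in offsets:
        r0 = max(0, -dr)
        r1 = min(h, h - dr)
        c0 = max(0, -dc)
        c1 = min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        src = q[r0:r1, c0:c1]
        dst = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = inside[r0:r1, c0:c1] & inside[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a = src[ok]
        b = dst[ok]
        n_pairs += a.size
        np.add.at(counts, (a, b), 1.0)
    if n_pairs < 2:
        raise ValueError("fewer than 2 admissible pixel pairs in the mask")
    if symmetric:
        counts = counts + counts.T
    return GLCMMatrix(
        S=counts / counts.sum(), levels=levels, offsets=offsets, symmetric=symmetric
    )


def glcm_features(g: GLCMMatrix) -> Tuple[float, float, float, float, float]:
    """Contrast, homogeneity, correlation, angular second moment, energy.

    correlation uses the marginal means/stds of the matrix itself; a
    constant region (zero marginal variance) is perfectly correlated with
    itself, so that degenerate case returns 1.
    """
    S = g.S
    n = g.levels
    a = np.arange(n, dtype=np.float64)
    A, B = np.meshgrid(a, a, indexing="ij")
    contrast = float(np.sum(S * (A - B) ** 2))
    homogeneity = float(np.sum(S / (1.0 + (A - B) ** 2)))
    asm = float(np.sum(S * S))
    energy = float(np.sqrt(asm))
    mu_a = float(np.sum(S * A))
    mu_b = float(np.sum(S * B))
    var_a = float(np.sum(S * (A - mu_a) ** 2))
    var_b = float(np.sum(S * (B - mu_b) ** 2))
    if var_a * var_b <= 0.0:
        correlation = 1.0
    else:
        correlation = float(
            np.sum(S * (A - mu_a) * (B - mu_b)) / np.sqrt(var_a * var_b)
        )
    return contrast, homogeneity, correlation, asm, energy


# ---------------------------------------------------------------------------
# Redundant (undecimated / stationary) wavelet transform
# ---------------------------------------------------------------------------


@dataclass
class WaveletBands:
    """Two-level undecimated wavelet bands, each the size of the input."""

    LL1: np.ndarray
    LH1: np.ndarray
    HL1: np.ndarray
    HH1: np.ndarray
    LL2: np.ndarray
    LH2: np.ndarray
    HL2: np.ndarray
    HH2: np.ndarray
    wavelet: str = "db1"


def rdwt2(img: np.ndarray, wavelet: str = "db1", levels: int = 2) -> WaveletBands:
    """Two-level undecimated 2-D wavelet transform (periodic boundary).

    Level 1 acts on the image, level 2 on the level-1 approximation band;
    all bands keep the input size, making band energies invariant to
    circular shifts.  Image dimensions must be divisible by 2**levels.
    """
    if levels != 2:
        raise ValueError("exactly two decomposition levels are supported")
    img = np.asarray(img, dtype=np.float64)
    if min(img.shape) < 2**levels:
        raise ValueError("image dimensions must be at least 2**levels")
    if img.shape[0] % 2**levels or img.shape[1] % 2**levels:
        raise ValueError(
            f"image dimensions must be divisible by {2 ** levels} "
            f"for the undecimated transform, got {img.shape}"
        )
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet!r}")
    coeffs = pywt.swt2(img, wavelet, level=levels)
    # pywt returns coarsest level first: [(cA2,(cH2,cV2,cD2)), (cA1,...)].
    (ca2, (ch2, cv2, cd2)), (ca1, (ch1, cv1, cd1)) = coeffs
    return WaveletBands(
        LL1=ca1, LH1=ch1, HL1=cv1, HH1=cd1,
        LL2=ca2, LH2=ch2, HL2=cv2, HH2=cd2,
        wavelet=wavelet,
    )


def irdwt2(bands: WaveletBands) -> np.ndarray:
    """Inverse of :func:`rdwt2`; reconstructs the input to ~1e-8."""
    coeffs = [
        (bands.LL2, (bands.LH2, bands.HL2, bands.HH2)),
        (bands.LL1, (bands.LH1, bands.HL1, bands.HH1)),
    ]
    return pywt.iswt2(coeffs, bands.wavelet)


def band_features(
    band: np.ndarray, reference: np.ndarray
) -> Tuple[float, float, float]:
    """(energy, entropy, correlation) of one wavelet band.

    energy: mean squared coefficient.  entropy: Shannon entropy (bits) of
    the 256-bin histogram of min-max-normalized coefficients (a degenerate
    constant band has entropy 0).  correlation: Pearson correlation with
    the reference image (0 when either side has zero variance).
    """
    band = np.asarray(band, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if band.shape != reference.shape:
        raise ValueError("band and reference must share a shape")
    energy = float(np.mean(band * band))
    rng = band.max() - band.min()
    if rng <= 0:
        entropy = 0.0
    else:
        norm = (band - band.min()) / rng
        hist, _ = np.histogram(norm, bins=256, range=(0.0, 1.0))
        p = hist[hist > 0] / hist.sum()
        entropy = float(-np.sum(p * np.log2(p)))
    if band.std() == 0.0 or reference.std() == 0.0:
        correlation = 0.0
    else:
        correlation = float(np.corrcoef(band.ravel(), reference.ravel())[0, 1])
    return energy, entropy, correlation


def color_stats(img: np.ndarray, mask: np.ndarray) -> Tuple[float, float]:
    """Masked intensity mean and population standard deviation.

    The divisor is the masked pixel count (population convention).  On a
    grayscale fused image these are the intensity statistics; per-channel
    extension applies only to genuinely RGB input.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    vals = np.asarray(img, dtype=np.float64)[mask]
    return float(vals.mean()), float(vals.std())


@dataclass
class FeatureConfig:
    """Hybrid feature extraction settings."""

    levels: int = 16
    offsets: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS
    wavelet: str = "db1"
    use_mask: bool = True  # extract from the segmented region (default)


def hybrid_features(
    fused: np.ndarray,
    mask: np.ndarray,
    config: Optional[FeatureConfig] = None,
) -> np.ndarray:
    """Concatenated 13-component hybrid feature vector (FEATURE_NAMES order).

    GLCM texture and intensity statistics come from the masked region
    (whole image when ``use_mask`` is off); wavelet approximation-band
    features are computed on the full fused image.
    """
    if config is None:
        config = FeatureConfig()
    region = mask if config.use_mask else None
    g = compute_glcm(fused, mask=region, levels=config.levels, offsets=config.offsets)
    contrast, homogeneity, correlation, asm, energy = glcm_features(g)
    bands = rdwt2(fused, wavelet=config.wavelet)
    ll1 = band_features(bands.LL1, fused)
    ll2 = band_features(bands.LL2, fused)
    stat_mask = mask if config.use_mask else np.ones_like(fused, dtype=np.int64)
    mean, std = color_stats(fused, stat_mask)
    return np.array(
        [contrast, homogeneity, correlation, asm, energy, *ll1, *ll2, mean, std]
    )


# ---------------------------------------------------------------------------
# GAOM: genetic-algorithm feature selection
# ---------------------------------------------------------------------------


@dataclass
class GASettings:
    """Genetic-algorithm hyperparameters for feature-subset search."""

    population: int = 20
    generations: int = 30
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    elitism: int = 2
    cv_folds: int = 5
    size_penalty: float = 0.01
    pnn_sigma: float = 0.5


def _subset_fitness(
    F: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    settings: GASettings,
    splits,
) -> float:
    """Stratified CV accuracy of a PNN on the subset, minus a size penalty."""
    cols = np.flatnonzero(mask)
    accs = []
    for train_idx, test_idx in splits:
        model = PNNClassifier(sigma=settings.pnn_sigma).fit(
            F[np.ix_(train_idx, cols)], y[train_idx]
        )
        accs.append(float(np.mean(model.predict(F[np.ix_(test_idx, cols)]) == y[test_idx])))
    return float(np.mean(accs)) - settings.size_penalty * cols.size / F.shape[1]


def gaom_select(
    F: np.ndarray,
    y: Sequence,
    settings: Optional[GASettings] = None,
    seed: int = 0,
) -> np.ndarray:
    """Genetic-algorithm feature selection over binary inclusion masks.

    Tournament selection, uniform crossover, bit-flip mutation and elitism
    evolve subsets whose fitness is the stratified cross-validated PNN
    accuracy penalized by subset size, so accuracy ties resolve toward
    smaller subsets.  Deterministic under the seed; never returns an empty
    set.  Returns the selected feature indices (sorted).
    """
    if settings is None:
        settings = GASettings()
    F = np.asarray(F, dtype=np.float64)
    y = np.asarray(y)
    if F.shape[0] < 10:
        raise ValueError("need at least 10 samples")
    d = F.shape[1]
    if d < 2:
        raise ValueError("need at least 2 features")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain at least 2 classes")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=settings.cv_folds, shuffle=True, random_state=int(seed) % (2**31)
    )
    splits = list(skf.split(F, y))

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(d)] = True
        return mask

    cache: dict = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _subset_fitness(F, y, mask, settings, splits)
        return cache[key]

    pop = [repair(rng.random(d) < 0.5) for _ in range(settings.population)]
    fits = np.array([fitness(m) for m in pop])
    best_mask = pop[int(np.argmax(fits))].copy()
    best_fit = float(fits.max())
    for _ in range(settings.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: settings.elitism]]
        while len(new_pop) < settings.population:
            # Tournament selection of two parents.
            parents = []
            for _ in range(2):
                idx = rng.integers(0, settings.population, size=3)
                parents.append(pop[idx[np.argmax(fits[idx])]])
            if rng.random() < settings.crossover_rate:
                swap = rng.random(d) < 0.5
                child = np.where(swap, parents[0], parents[1])
            else:
                child = parents[0].copy()
            flip = rng.random(d) < settings.mutation_rate
            child = repair(child ^ flip)
            new_pop.append(child)
        pop = new_pop
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()
    return np.flatnonzero(best_mask)


class GAOMFeatureSelector(BaseEstimator):
    """Scikit-learn style selector wrapping :func:`gaom_select`.

    After ``fit``: ``support_`` (boolean mask), ``selected_indices_``;
    ``transform`` keeps the selected columns.
    """

    def __init__(self, settings: Optional[GASettings] = None, seed: int = 0) -> None:
        self.settings = settings
        self.seed = seed

    def fit(self, X: np.ndarray, y: Sequence) -> "GAOMFeatureSelector":
        X = np.asarray(X, dtype=np.float64)
        idx = gaom_select(X, y, settings=self.settings, seed=self.seed)
        self.selected_indices_ = idx
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[idx] = True
        return self

    def get_support(self) -> np.ndarray:
        if not hasattr(self, "support_"):
            raise RuntimeError("selector is not fitted")
        return self.support_

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X)[:, self.get_support()]

    def fit_transform(self, X: np.ndarray, y: Sequence) -> np.ndarray:
        return self.fit(X, y).transform(X)
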