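"""Fusion-quality, segmentation and classification metrics.

Image metrics (entropy, mutual information, PSNR, SSIM, standard
deviation) quantify how much source information a fused image retains.
Confusion-matrix metrics cover both segmentation (pixel-level) and
classification (sample-level) evaluation; ROC/AUC summarizes score
rankings.  All histogram-based quantities use 256 bins over [0, 1] and
report bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from skimage.metrics import structural_similarity

_BINS = 256


def image_entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    hist, _ = np.histogram(np.asarray(img), bins=_BINS, range=(0.0, 1.0))
    p = hist[hist > 0] / hist.sum()
    return float(-np.sum(p * np.log2(p)))


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (bits) from the 256x256 joint intensity histogram."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    joint, _, _ = np.histogram2d(
        a.ravel(), b.ravel(), bins=_BINS, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    outer = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))


def image_std(img: np.ndarray) -> float:
    """Population standard deviation of the intensities."""
    return float(np.asarray(img, dtype=np.float64).std())


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images report +inf."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float(np.inf)
    return float(10.0 * np.log10(peak * peak / mse))


def ssim(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Structural similarity with the standard 11x11 Gaussian window
    (sigma 1.5) and stabilizers K1=0.01, K2=0.03."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            np.asarray(a, dtype=np.float64),
            np.asarray(b, dtype=np.float64),
            data_range=peak,
            gaussian_weights=True,
            sigma=1.5,
            win_size=11,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


# ---------------------------------------------------------------------------
# Confusion-matrix metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    """Binary confusion-table counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("at least one count must be positive")


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name}: 0/0 encountered, reporting 0", stacklevel=3)
        return 0.0
    return num / den


def confusion_metrics(c: ConfusionCounts) -> Dict[str, float]:
    """The ten confusion metrics: accuracy, sensitivity, specificity,
    precision, NPV, FPR, FDR, FNR, F1 and Matthews correlation.  Any 0/0
    ratio reports 0 with a warning so batch evaluation never aborts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    total = tp + fp + tn + fn
    acc = (tp + tn) / total
    sen = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    pr = _ratio(tp, tp + fp, "precision")
    npv = _ratio(tn, tn + fn, "npv")
    f1 = _ratio(2.0 * pr * sen, pr + sen, "f1")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _ratio(float(tp) * tn - float(fp) * fn, mcc_den, "mcc")
    return {
        "accuracy": acc,
        "sensitivity": sen,
        "specificity": spec,
        "precision": pr,
        "npv": npv,
        "fpr": 1.0 - spec,
        "fdr": 1.0 - pr,
        "fnr": 1.0 - sen,
        "f1": f1,
        "mcc": mcc,
    }


def mask_confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-level confusion counts between two binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        tn=int(np.sum(~pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks score 1."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(pred & truth) / denom)


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> Tuple[np.ndarray, float]:
    """ROC points from a threshold sweep and the trapezoidal AUC.

    The AUC equals the Mann-Whitney statistic: concordant score pairs over
    all positive/negative pairs, with ties counted half (rank averaging).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    points = []
    for t in thresholds:
        predicted = scores >= t
        tpr = np.sum(predicted & (labels == 1)) / n_pos
        fpr = np.sum(predicted & (labels == 0)) / n_neg
        points.append((fpr, tpr))
    points = np.asarray(points)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return points, auc
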