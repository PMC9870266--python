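"""Hybrid probabilistic Wiener filter (HPWF) preprocessing.

Assumes the additive model X = O + G with i.i.d. Gaussian noise G.  The
noise level is estimated once per image with the Immerkaer 3x3
Laplacian-difference estimator, then locally adaptive Wiener shrinkage
(local mean + variance-driven gain toward the observed pixel) is computed
for each mask size and the per-window outputs are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import convolve, uniform_filter

#: Immerkaer's noise-estimation kernel: a difference of Laplacians that
#: annihilates affine image content and responds only to noise.
_IMMERKAER_KERNEL = np.array(
    [[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]]
)


@dataclass
class HPWFParams:
    """Configuration of the denoiser: mask sizes and numerical floors."""

    windows: List[int] = field(default_factory=lambda: [3, 5])
    epsilon: float = 1e-8
    sigma_override: Optional[float] = None

    def __post_init__(self) -> None:
        for w in self.windows:
            if w < 3 or w % 2 == 0:
                raise ValueError(f"window sizes must be odd and >= 3, got {w}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def estimate_noise_sigma(img: np.ndarray) -> float:
    """Estimate the Gaussian noise standard deviation of an image.

    Uses sigma_hat = sqrt(pi/2) / (6 (W-2)(H-2)) * sum |img * L| with L the
    3x3 Laplacian-difference mask, evaluated on the interior so border
    padding never contributes.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"need a 2-D image of at least 3x3, got shape {img.shape}")
    h, w = img.shape
    response = convolve(img, _IMMERKAER_KERNEL, mode="reflect")
    interior = response[1:-1, 1:-1]
    sigma = np.sqrt(np.pi / 2.0) * np.abs(interior).sum() / (6.0 * (w - 2) * (h - 2))
    return float(sigma)


def local_moments(img: np.ndarray, window: int) -> Tuple[np.ndarray, np.ndarray]:
    """Per-pixel box-filter mean and population variance over a square window.

    Borders are handled by reflect padding; the variance is clamped at zero
    to absorb floating-point cancellation.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    img = np.asarray(img, dtype=np.float64)
    if window > min(img.shape):
        raise ValueError(f"window {window} exceeds image extent {img.shape}")
    mean = uniform_filter(img, size=window, mode="reflect")
    mean_sq = uniform_filter(img * img, size=window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, var


def hpwf_denoise(img: np.ndarray, params: Optional[HPWFParams] = None) -> np.ndarray:
    """Denoise an image by multi-window adaptive Wiener shrinkage.

    For each window size: D = X - local mean, gain
    g = max(0, var - sigma^2) / max(var, eps), output = mean + g * D.
    The final image is the equal-weight average over the configured window
    sizes, clipped to [0, 1].  Where the local variance falls below the
    noise power the gain clamps to zero and the output is the local mean;
    on a noiseless image the gain approaches one and the input passes
    through (up to border effects).
    """
    if params is None:
        params = HPWFParams()
    img = np.asarray(img, dtype=np.float64)
    sigma = (
        params.sigma_override
        if params.sigma_override is not None
        else estimate_noise_sigma(img)
    )
    noise_power = sigma * sigma
    outputs = []
    for w in params.windows:
        mean, var = local_moments(img, w)
        gain = np.maximum(var - noise_power, 0.0) / np.maximum(var, params.epsilon)
        outputs.append(mean + gain * (img - mean))
    return np.clip(np.mean(outputs, axis=0), 0.0, 1.0)
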