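"""Fusion-Net: weighted-mean fusion of denoised MRI and CT.

Per-pixel weight maps come either from a deterministic local-activity rule
(default — local variance competition between the two modalities) or from
a small fully convolutional network with shared first-stage weights,
rectifier activations, a 2x2 max-pool stage and a softmax weight head.
The fused image is the weighted mean of the two sources with the REA edge
layer re-injected at a configurable gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from scipy.ndimage import gaussian_filter

from .hpwf import HPWFParams, hpwf_denoise, local_moments
from .rea import rea_decompose


@dataclass
class WeightMaps:
    """Per-pixel fusion weights; w_mri + w_ct = 1 everywhere."""

    w_mri: np.ndarray
    w_ct: np.ndarray

    def __post_init__(self) -> None:
        if self.w_mri.shape != self.w_ct.shape:
            raise ValueError("weight maps must share a shape")
        if not np.allclose(self.w_mri + self.w_ct, 1.0, atol=1e-9):
            raise ValueError("weight maps must sum to 1 per pixel")
        if (self.w_mri < 0).any() or (self.w_ct < 0).any():
            raise ValueError("weights must be nonnegative")


def activity_weight_map(
    a: np.ndarray,
    b: np.ndarray,
    window: int = 7,
    floor: float = 3e-3,
    smooth_sigma: float = 2.0,
) -> WeightMaps:
    """Local-variance competition weights.

    w_a = (var_w(a) + floor) / (var_w(a) + var_w(b) + 2*floor): where one
    source carries far more local detail its weight approaches 1, equal
    detail (including the both-flat tie) gives exactly 0.5/0.5.  The
    variance floor keeps residual-noise fluctuations in flat regions from
    flipping the weights, and a light Gaussian smoothing of the variance
    maps (``smooth_sigma`` pixels, 0 disables) suppresses blocky weight
    transitions.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    _, va = local_moments(a, window)
    _, vb = local_moments(b, window)
    if smooth_sigma > 0:
        va = gaussian_filter(va, smooth_sigma)
        vb = gaussian_filter(vb, smooth_sigma)
    w_a = (va + floor) / (va + vb + 2.0 * floor)
    return WeightMaps(w_mri=w_a, w_ct=1.0 - w_a)


# ---------------------------------------------------------------------------
# CNN weight branch (forward only, fully convolutional)
# ---------------------------------------------------------------------------


def _conv_stack(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'Same' multi-channel 2-D correlation: x (C,H,W), w (O,C,kh,kw)."""
    _, kh, kw = w.shape[1], w.shape[2], w.shape[3]
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xp = np.pad(x, ((0, 0), (ph, kh - 1 - ph), (pw, kw - 1 - pw)), mode="reflect")
    patches = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    out = np.einsum("chwij,ocij->ohw", patches, w, optimize=True)
    return out + b[:, None, None]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool_upsample(x: np.ndarray) -> np.ndarray:
    """2x2 stride-2 max pooling followed by nearest upsampling to input size."""
    c, h, w = x.shape
    hp, wp = h + h % 2, w + w % 2
    xp = np.full((c, hp, wp), -np.inf)
    xp[:, :h, :w] = x
    pooled = xp.reshape(c, hp // 2, 2, wp // 2, 2).max(axis=(2, 4))
    up = pooled.repeat(2, axis=1).repeat(2, axis=2)
    return up[:, :h, :w]


@dataclass
class FusionNetParams:
    """Weights of the convolutional weight-map branch.

    Stage 1: shared 3x3 conv, 64 channels, applied to each modality.
    Stage 2: 2x2 conv + max-pool, 128 channels, on the channel-summed
    features (symmetric in the two modalities by construction).
    Head: 3x3 conv reducing the concatenated stage-2 maps to 2 channels,
    followed by a per-pixel softmax.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    w3: np.ndarray
    b3: np.ndarray

    @classmethod
    def random(cls, seed: int = 0, channels: Tuple[int, int] = (64, 128)) -> "FusionNetParams":
        """He-style seeded random initialization."""
        c1, c2 = channels
        rng = np.random.default_rng(seed)

        def he(shape):
            fan_in = int(np.prod(shape[1:]))
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return cls(
            w1=he((c1, 1, 3, 3)),
            b1=np.zeros(c1),
            w2=he((c2, c1, 2, 2)),
            b2=np.zeros(c2),
            w3=he((2, 2 * c2, 3, 3)),
            b3=np.zeros(2),
        )


def fusion_net_forward(
    mri: np.ndarray, ct: np.ndarray, params: FusionNetParams
) -> WeightMaps:
    """Forward pass of the weight branch.

    F1/F2 share the first-stage kernel; the second stage acts on F1+F2 so
    the network is symmetric under swapping the modalities, and the head's
    softmax guarantees simplex-valued weights at every pixel.
    """
    if mri.shape != ct.shape:
        raise ValueError(f"shape mismatch: {mri.shape} vs {ct.shape}")
    if params is None:
        raise RuntimeError("fusion network parameters are not initialized")
    f1 = _relu(_conv_stack(mri[None], params.w1, params.b1))
    f2 = _relu(_conv_stack(ct[None], params.w1, params.b1))
    f3 = _maxpool_upsample(_relu(_conv_stack(f1 + f2, params.w2, params.b2)))
    f4 = _maxpool_upsample(_relu(_conv_stack(f2 + f1, params.w2, params.b2)))
    fr = _conv_stack(np.concatenate([f3, f4], axis=0), params.w3, params.b3)
    fr -= fr.max(axis=0, keepdims=True)
    expfr = np.exp(fr)
    soft = expfr / expfr.sum(axis=0, keepdims=True)
    return WeightMaps(w_mri=soft[0], w_ct=soft[1])


def weighted_mean_fuse(
    a: np.ndarray,
    b: np.ndarray,
    w: WeightMaps,
    edge: Optional[np.ndarray] = None,
    edge_gain: float = 0.25,
) -> np.ndarray:
    """Weighted-mean fusion rule with optional edge re-injection, clipped."""
    if a.shape != b.shape or a.shape != w.w_mri.shape:
        raise ValueError("images and weight maps must share a shape")
    fused = w.w_mri * a + w.w_ct * b
    if edge is not None:
        if edge.shape != a.shape:
            raise ValueError("edge layer shape mismatch")
        fused = fused + edge_gain * edge
    return np.clip(fused, 0.0, 1.0)


@dataclass
class FuseConfig:
    """End-to-end fusion settings (denoise -> decompose -> weight -> fuse)."""

    mode: str = "activity"
    edge_gain: float = 0.25
    activity_window: int = 7
    rea_xi: float = 1.0
    rea_tol: float = 1e-4
    rea_max_iter: int = 100
    hpwf: HPWFParams = field(default_factory=HPWFParams)
    cnn_seed: int = 0
    cnn_params: Optional[FusionNetParams] = None

    def __post_init__(self) -> None:
        if self.mode not in ("activity", "cnn"):
            raise ValueError(f"mode must be 'activity' or 'cnn', got {self.mode!r}")


def fuse(
    mri: np.ndarray, ct: np.ndarray, config: Optional[FuseConfig] = None
) -> np.ndarray:
    """Full fusion pipeline: HPWF denoise both modalities, REA-decompose,
    derive weight maps per the configured mode, and apply the weighted-mean
    rule with edge re-injection."""
    if config is None:
        config = FuseConfig()
    if mri.shape != ct.shape:
        raise ValueError("inputs must be co-registered (same shape)")
    d_mri = hpwf_denoise(mri, config.hpwf)
    d_ct = hpwf_denoise(ct, config.hpwf)
    decomp = rea_decompose(
        d_mri, d_ct, xi=config.rea_xi, tol=config.rea_tol,
        max_iter=config.rea_max_iter,
    )
    if config.mode == "activity":
        w = activity_weight_map(d_mri, d_ct, window=config.activity_window)
    else:
        params = config.cnn_params or FusionNetParams.random(config.cnn_seed)
        w = fusion_net_forward(d_mri, d_ct, params)
    return weighted_mean_fuse(d_mri, d_ct, w, edge=decomp.edge, edge_gain=config.edge_gain)
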