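"""Image, mask and table I/O plus the shared domain types.

Every pipeline stage exchanges 2-D float arrays ("gray images") with
intensities in [0, 1], row-major (row, col) indexing.  This module owns the
conversion between that convention and the on-disk formats (PNG/TIFF,
NIfTI-1, CSV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

#: Rec. 601 luma weights for RGB -> grayscale reduction.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def normalize_intensity(pixels: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a zero-dynamic-range image maps to all zeros."""
    pixels = np.asarray(pixels, dtype=np.float64)
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi - lo == 0.0:
        warnings.warn(
            "image has zero dynamic range; normalized output is all zeros",
            stacklevel=2,
        )
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def rgb_to_luminance(pixels: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3[+alpha]) array to luminance with Rec. 601 weights."""
    return np.asarray(pixels, dtype=np.float64)[..., :3] @ _LUMA_WEIGHTS


def as_gray_image(pixels: np.ndarray) -> np.ndarray:
    """Validate and return a float64 gray image in [0, 1]."""
    img = np.asarray(pixels, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError(f"image must be at least 8x8, got {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]; normalize first")
    return img


@dataclass
class LabeledSample:
    """A co-registered MRI/CT pair with optional ground truth.

    ``mask`` is a binary {0,1} array of the same shape; ``label`` is
    "benign" or "malignant" when known.
    """

    mri: np.ndarray
    ct: np.ndarray
    mask: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mri.shape != self.ct.shape:
            raise ValueError(
                f"MRI and CT must be co-registered (same shape); "
                f"got {self.mri.shape} vs {self.ct.shape}"
            )
        if self.mask is not None:
            if self.mask.shape != self.mri.shape:
                raise ValueError("mask shape must match the image pair")
            vals = np.unique(self.mask)
            if not np.all(np.isin(vals, [0, 1])):
                raise ValueError("mask must be strictly binary {0,1}")
        if self.label is not None and self.label not in ("benign", "malignant"):
            raise ValueError(f"label must be 'benign' or 'malignant', got {self.label!r}")


def load_image(
    path: str | Path,
    normalize: bool = True,
    slice_index: Optional[int] = None,
) -> np.ndarray:
    """Load a grayscale image from PNG/TIFF or NIfTI.

    Color inputs are reduced to luminance (Rec. 601).  NIfTI volumes require
    ``slice_index`` selecting one axial slice.  With ``normalize`` the result
    is min-max scaled to [0, 1]; otherwise raw intensities are returned.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if _is_nifti(path):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if vol.ndim == 2:
            img = vol
        elif vol.ndim >= 3:
            if slice_index is None:
                raise ValueError("NIfTI volume requires a slice_index")
            img = vol[..., slice_index] if vol.ndim == 3 else vol[..., slice_index, 0]
        else:
            raise IOError(f"unsupported NIfTI dimensionality: {vol.ndim}")
    else:
        try:
            img = np.asarray(iio.imread(path), dtype=np.float64)
        except Exception as exc:  # pragma: no cover - backend specific
            raise IOError(f"unreadable image file {path}: {exc}") from exc
        if img.ndim == 3:
            img = rgb_to_luminance(img)
    if img.ndim != 2:
        raise IOError(f"could not reduce {path} to a 2-D image (shape {img.shape})")
    if normalize:
        img = normalize_intensity(img)
    return img


def save_image(img: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0, 1] gray image as an 8- or 16-bit PNG/TIFF.

    The round trip load(save(x)) is exact to within 1/(2**bit_depth - 1)
    per pixel.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1] before saving")
    peak = 2**bit_depth - 1
    quantized = np.rint(img * peak).astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    try:
        iio.imwrite(path, quantized)
    except Exception as exc:
        raise IOError(f"cannot write image to {path}: {exc}") from exc


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as an 8-bit {0, 255} PNG."""
    mask = np.asarray(mask)
    save_image(mask.astype(np.float64), path, bit_depth=8)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask written by :func:`save_mask` (values > 0.5 -> 1)."""
    img = load_image(path, normalize=False)
    peak = img.max()
    if peak > 1.0:
        img = img / 255.0
    return (img > 0.5).astype(np.int64)
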