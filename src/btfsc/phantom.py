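"""Seeded synthetic MRI/CT head phantoms with ground-truth tumor masks.

The generator emulates the complementary contrast of the two modalities:
soft tissue is bright in MRI (brain 0.55, tumor 0.85 on a 0.05 background)
while bone dominates CT (skull ring 0.95 over brain 0.35, tumor 0.55).
Benign tumors are smooth ellipses; malignant tumors get a radially
perturbed boundary (relative amplitude 0.35) and i.i.d. interior speckle
(std 0.15), the image-level surrogates for shape irregularity and texture
heterogeneity.  Additive Gaussian noise of a chosen sigma is applied to
both channels and clipped to [0, 1].  The mask marks exactly the pixels
assigned tumor intensity before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from .io import LabeledSample

# Intensity levels per modality (background, brain, tumor, skull).
MRI_BACKGROUND = 0.05
MRI_BRAIN = 0.55
MRI_TUMOR = 0.85
CT_BACKGROUND = 0.05
CT_BRAIN = 0.35
CT_TUMOR = 0.55
CT_SKULL = 0.95

#: Relative radial amplitude of the malignant boundary perturbation.
MALIGNANT_BOUNDARY_AMPLITUDE = 0.35
#: Standard deviation of the malignant interior speckle texture.
MALIGNANT_SPECKLE_STD = 0.15
#: Peak amplitude of the smooth low-frequency modulation of MRI brain tissue.
MRI_MODULATION_AMPLITUDE = 0.04


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head phantom."""

    size: int = 128
    tumor_radius_range: Tuple[float, float] = (0.06, 0.18)
    noise_sigma: float = 0.0
    class_label: str = "benign"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be at least 32 pixels")
        lo, hi = self.tumor_radius_range
        if not (0.0 < lo <= hi < 0.25):
            raise ValueError(
                f"tumor radius range must satisfy 0 < lo <= hi < 0.25 of the "
                f"image size, got {self.tumor_radius_range}"
            )
        if not (0.0 <= self.noise_sigma < 0.5):
            raise ValueError("noise_sigma must lie in [0, 0.5)")
        if self.class_label not in ("benign", "malignant"):
            raise ValueError(f"unknown class_label {self.class_label!r}")


def _brain_geometry(size: int) -> Tuple[np.ndarray, np.ndarray, float, float]:
    """Row/col grids centred on the head plus brain semi-axes (rows, cols)."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    rr -= (size - 1) / 2.0
    cc -= (size - 1) / 2.0
    semi_r = 0.38 * size
    semi_c = 0.31 * size
    return rr, cc, semi_r, semi_c


def _smooth_periodic_profile(rng: np.random.Generator, harmonics=range(2, 7)) -> np.ndarray:
    """Coefficients (amplitude, phase) of a smooth zero-mean angular profile."""
    amps = rng.uniform(0.3, 1.0, size=len(list(harmonics)))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=amps.size)
    return np.stack([amps, phases])


def _eval_profile(coeffs: np.ndarray, phi: np.ndarray, harmonics=range(2, 7)) -> np.ndarray:
    amps, phases = coeffs

    def raw(p: np.ndarray) -> np.ndarray:
        out = np.zeros_like(p)
        for k, a, ph in zip(harmonics, amps, phases):
            out += a * np.cos(k * p + ph)
        return out

    # Normalize so the extreme radial excursion equals the stated amplitude.
    dense = np.linspace(0.0, 2.0 * np.pi, 720)
    peak = max(float(np.abs(raw(dense)).max()), 1e-12)
    return raw(phi) / peak


def generate_phantom_pair(spec: PhantomSpec) -> LabeledSample:
    """Generate one co-registered MRI/CT pair with mask and label."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    rr, cc, semi_r, semi_c = _brain_geometry(size)

    brain = (rr / semi_r) ** 2 + (cc / semi_c) ** 2 <= 1.0
    skull = ((rr / (1.10 * semi_r)) ** 2 + (cc / (1.10 * semi_c)) ** 2 <= 1.0) & ~brain

    # Tumor placement: radius as a fraction of the image, centre kept inside
    # the brain ellipse with margin for the perturbed boundary.
    r_frac = rng.uniform(*spec.tumor_radius_range)
    radius = r_frac * size
    max_reach = radius * (1.0 + MALIGNANT_BOUNDARY_AMPLITUDE) * 1.15 + 2.0
    rho = np.sqrt(rng.uniform(0.0, 1.0))
    ang = rng.uniform(0.0, 2.0 * np.pi)
    cr = rho * max(semi_r - max_reach, 0.0) * np.sin(ang)
    ccol = rho * max(semi_c - max_reach, 0.0) * np.cos(ang)

    dr = rr - cr
    dc = cc - ccol
    phi = np.arctan2(dr, dc)
    dist = np.hypot(dr, dc)

    if spec.class_label == "benign":
        # Near-circular ellipse with axes r*u, r/u: area is pi*r^2 exactly.
        u = rng.uniform(0.9, 1.1)
        theta = rng.uniform(0.0, np.pi)
        x = dc * np.cos(theta) + dr * np.sin(theta)
        y = -dc * np.sin(theta) + dr * np.cos(theta)
        tumor = (x / (radius * u)) ** 2 + (y / (radius / u)) ** 2 <= 1.0
    else:
        coeffs = _smooth_periodic_profile(rng)
        s = _eval_profile(coeffs, phi)
        tumor = dist <= radius * (1.0 + MALIGNANT_BOUNDARY_AMPLITUDE * s)

    # Smooth low-frequency modulation of MRI brain tissue (zero-mean field).
    fr = rng.uniform(1.0, 2.5, size=2)
    ph = rng.uniform(0.0, 2.0 * np.pi, size=2)
    modulation = MRI_MODULATION_AMPLITUDE * (
        np.sin(2.0 * np.pi * fr[0] * rr / size + ph[0])
        * np.cos(2.0 * np.pi * fr[1] * cc / size + ph[1])
    )

    mri = np.full((size, size), MRI_BACKGROUND)
    mri[brain] = MRI_BRAIN + modulation[brain]
    mri[tumor] = MRI_TUMOR

    ct = np.full((size, size), CT_BACKGROUND)
    ct[brain] = CT_BRAIN
    ct[skull] = CT_SKULL
    ct[tumor] = CT_TUMOR

    if spec.class_label == "malignant":
        n_tumor = int(tumor.sum())
        mri[tumor] += rng.normal(0.0, MALIGNANT_SPECKLE_STD, size=n_tumor)
        ct[tumor] += rng.normal(0.0, MALIGNANT_SPECKLE_STD, size=n_tumor)

    if spec.noise_sigma > 0.0:
        mri = mri + rng.normal(0.0, spec.noise_sigma, size=mri.shape)
        ct = ct + rng.normal(0.0, spec.noise_sigma, size=ct.shape)

    mri = np.clip(mri, 0.0, 1.0)
    ct = np.clip(ct, 0.0, 1.0)
    return LabeledSample(
        mri=mri,
        ct=ct,
        mask=tumor.astype(np.int64),
        label=spec.class_label,
    )


def generate_dataset(
    n: int,
    balance: float = 0.5,
    noise_sigma: float = 0.05,
    seed: int = 0,
    size: int = 128,
) -> List[LabeledSample]:
    """Generate a balanced, seeded phantom dataset.

    Exactly ``round(n * balance)`` samples are malignant; per-sample seeds
    derive deterministically from the master seed, so the same master seed
    always yields the identical dataset.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 <= balance <= 1.0):
        raise ValueError(f"balance must lie in [0, 1], got {balance}")
    n_mal = int(round(n * balance))
    labels = ["malignant"] * n_mal + ["benign"] * (n - n_mal)
    master = np.random.default_rng(seed)
    order = master.permutation(n)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    samples = []
    for i in range(n):
        spec = PhantomSpec(
            size=size,
            noise_sigma=noise_sigma,
            class_label=labels[order[i]],
            seed=int(child_seeds[i]),
        )
        samples.append(generate_phantom_pair(spec))
    return samples
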