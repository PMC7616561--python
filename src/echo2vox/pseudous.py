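"""Pseudo-ultrasound synthesis: tissue masks degraded by noise and blur.

Emulates the pre-style-transfer stage of echo simulation: a segmentation
mask is mapped to base intensities, then multiplicative speckle
(mean-one lognormal), additive Gaussian noise, and a normalized Gaussian
blur are applied — in a configurable order — without any geometric
transform of the anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .viewslice import SegmentationImage

__all__ = ["NoiseConfig", "make_pseudo_us"]


class NoiseConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseConfig:
    """Knobs of the pseudo-ultrasound degradation.

    ``speckle_sd`` is the standard deviation of the mean-one lognormal
    multiplicative field; ``additive_sd`` of the additive Gaussian field
    (intensity units); ``blur_kernel_px`` an odd Gaussian kernel width
    (sigma = width / 4).  ``order`` selects whether noise is applied before
    or after the blur.
    """

    speckle_sd: float = 0.3
    additive_sd: float = 0.05
    blur_kernel_px: int = 5
    order: str = "noise_then_blur"  # or "blur_then_noise"
    tissue_intensity: float = 0.7
    background_intensity: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.blur_kernel_px < 1 or self.blur_kernel_px % 2 == 0:
            raise NoiseConfigError("blur_kernel_px must be odd and >= 1")
        if self.speckle_sd < 0 or self.additive_sd < 0:
            raise NoiseConfigError("noise standard deviations must be >= 0")
        for name in ("tissue_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise NoiseConfigError(f"{name} must be in [0, 1]")
        if self.order not in ("noise_then_blur", "blur_then_noise"):
            raise NoiseConfigError(f"unknown order {self.order!r}")


def _gaussian_blur(img: np.ndarray, kernel_px: int) -> np.ndarray:
    """Separable normalized Gaussian of odd width ``kernel_px`` (reflect pad)."""
    if kernel_px == 1:
        return img
    half = kernel_px // 2
    sigma = kernel_px / 4.0
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    k /= k.sum()
    out = ndimage.convolve1d(img, k, axis=0, mode="reflect")
    return ndimage.convolve1d(out, k, axis=1, mode="reflect")


def _apply_noise(img: np.ndarray, cfg: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    out = img
    if cfg.speckle_sd > 0:
        # lognormal with unit mean and sd ~= speckle_sd
        s2 = np.log1p(cfg.speckle_sd**2)
        field = rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=img.shape)
        out = out * field
    if cfg.additive_sd > 0:
        out = out + rng.normal(0.0, cfg.additive_sd, size=img.shape)
    return out


def make_pseudo_us(mask: SegmentationImage | np.ndarray, cfg: NoiseConfig, clip: bool = True) -> np.ndarray:
    """Pseudo-ultrasound intensity image (H, W) in [0, 1] from a mask.

    ``clip=False`` skips the final clamp, exposing the raw noise statistics.
    """
    cfg.validate()
    pixels = mask.pixels if isinstance(mask, SegmentationImage) else np.asarray(mask)
    img = np.where(pixels > 0, cfg.tissue_intensity, cfg.background_intensity).astype(np.float64)
    rng = np.random.default_rng(cfg.seed)
    if cfg.order == "noise_then_blur":
        img = _apply_noise(img, cfg, rng)
        img = _gaussian_blur(img, cfg.blur_kernel_px)
    else:
        img = _gaussian_blur(img, cfg.blur_kernel_px)
        img = _apply_noise(img, cfg, rng)
    if clip:
        img = np.clip(img, 0.0, 1.0)
    return img
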