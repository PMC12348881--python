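"""Stromal scaffold segmentation: 3D filtering, contrast, threshold, cleanup.

The stromal (BMSC) scaffold is segmented from the combined structural
channels (phalloidin / CD90 / nuclear stain) by a fixed pipeline: voxelwise
channel combination, a 3D median filter of radius 1, saturation-quantile
contrast enhancement to 8 bit, a strict fixed threshold (foreground iff
intensity > T, default T = 16), and morphological cleanup (closing followed
by small-object removal). The 3D variance filter used to texture-enhance
nuclei before instance segmentation also lives here.

All neighborhood filters use cubic (2r+1)^3 windows with reflect padding;
component operations use 26-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import ball, closing

from .stack import ImageStack3D

__all__ = [
    "FilterParams",
    "combine_channels",
    "median_filter_3d",
    "variance_filter_3d",
    "enhance_contrast",
    "threshold_fixed",
    "morphological_cleanup",
    "segment_scaffold",
]


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the scaffold segmentation pipeline.

    ``threshold_T`` lives on the 8-bit scale produced by contrast
    enhancement and is applied strictly (foreground iff value > T).
    ``saturation_fraction`` is the fraction of voxels clipped at each
    intensity tail during contrast enhancement (0.35% per tail by default,
    the common Fiji behavior).
    """

    median_radius: int = 1
    variance_radius: int = 1
    threshold_T: int = 16
    saturation_fraction: float = 0.0035
    min_object_voxels: int = 64
    closing_radius: int = 1
    channels: tuple[str, ...] = ("CD90",)

    def validate(self) -> None:
        if self.median_radius < 1 or self.variance_radius < 1:
            raise ValueError("filter radii must be >= 1")
        if not 0 <= self.threshold_T <= 255:
            raise ValueError("threshold_T must be on the 8-bit scale [0, 255]")
        if not 0.0 <= self.saturation_fraction < 0.5:
            raise ValueError("saturation_fraction must be in [0, 0.5)")
        if self.min_object_voxels < 0 or self.closing_radius < 0:
            raise ValueError("cleanup parameters must be >= 0")


def combine_channels(stack: ImageStack3D, channel_names: list[str]) -> np.ndarray:
    """Voxelwise maximum of the named channels after per-channel min-max rescale.

    Each channel is rescaled to [0, 1] over its own range (a constant channel
    maps to 0) so that channels recorded at different gains contribute
    comparably; the combined volume is their voxelwise maximum.
    """
    if not channel_names:
        raise ValueError("need at least one channel name")
    missing = [n for n in channel_names if n not in stack]
    if missing:
        raise KeyError(
            f"unknown channel(s) {missing}; available: {stack.channel_names}"
        )
    out = None
    for name in channel_names:
        vol = stack[name].astype(np.float64)
        lo, hi = vol.min(), vol.max()
        scaled = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
        out = scaled if out is None else np.maximum(out, scaled)
    return out


def median_filter_3d(volume: np.ndarray, radius: int = 1) -> np.ndarray:
    """Cubic median filter: each voxel becomes the median of its (2r+1)^3 cube."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndi.median_filter(volume, size=2 * radius + 1, mode="reflect")


def variance_filter_3d(volume: np.ndarray, radius: int = 1) -> np.ndarray:
    """Cubic population-variance filter over (2r+1)^3 neighborhoods.

    Computed as E[x^2] - E[x]^2 on a mean-shifted copy to limit cancellation
    error; output is clipped at zero.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    v = np.asarray(volume, dtype=np.float64)
    v = v - v.mean()
    size = 2 * radius + 1
    mean = ndi.uniform_filter(v, size=size, mode="reflect")
    mean_sq = ndi.uniform_filter(v * v, size=size, mode="reflect")
    return np.clip(mean_sq - mean * mean, 0.0, None)


def enhance_contrast(volume: np.ndarray, saturation_fraction: float = 0.0035) -> np.ndarray:
    """Linear rescale to 8 bit, saturating `saturation_fraction` per tail.

    The saturation_fraction and 1 - saturation_fraction intensity quantiles
    map to 0 and 255; values outside are clipped. A constant volume maps to
    all zeros.
    """
    if not 0.0 <= saturation_fraction < 0.5:
        raise ValueError("saturation_fraction must be in [0, 0.5)")
    v = np.asarray(volume, dtype=np.float64)
    lo, hi = np.quantile(v, [saturation_fraction, 1.0 - saturation_fraction])
    if hi <= lo:
        return np.zeros(v.shape, dtype=np.uint8)
    scaled = np.clip((v - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return np.rint(scaled).astype(np.uint8)


def threshold_fixed(volume: np.ndarray, threshold: int = 16) -> np.ndarray:
    """Binary foreground mask: voxel is foreground iff intensity > T (strict)."""
    return np.asarray(volume) > threshold


def morphological_cleanup(
    binary: np.ndarray, min_object_voxels: int = 64, closing_radius: int = 1
) -> np.ndarray:
    """Morphological closing, then removal of small 26-connected components.

    Components with fewer than ``min_object_voxels`` voxels are removed;
    a component of exactly that size is kept.
    """
    mask = np.asarray(binary, dtype=bool)
    if closing_radius > 0:
        mask = closing(mask, ball(closing_radius))
    if min_object_voxels > 1 and mask.any():
        labeled, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(labeled.ravel())
        keep = sizes >= min_object_voxels
        keep[0] = False
        mask = keep[labeled]
    return mask


def segment_scaffold(stack: ImageStack3D, params: FilterParams) -> np.ndarray:
    """Full scaffold pipeline: combine, median, enhance, threshold, cleanup."""
    params.validate()
    combined = combine_channels(stack, list(params.channels))
    filtered = median_filter_3d(combined, params.median_radius)
    enhanced = enhance_contrast(filtered, params.saturation_fraction)
    mask = threshold_fixed(enhanced, params.threshold_T)
    return morphological_cleanup(mask, params.min_object_voxels, params.closing_radius)
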