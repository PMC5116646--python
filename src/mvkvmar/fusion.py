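"""Weighted kV/MV image fusion and prior-image construction.

The prior image used for sinogram surrogacy is built by blending the
artifact-bearing kV slice with the (calibrated, registered) MV slice:

    I_fused = w_d * [ w * I_MV + (1 - w) * I_KV ] + (1 - w_d) * I_KV

so the per-pixel MV share is w_d * w. Two weights steer the blend:

* the deviation weight w grows with the relative deviation
  R = |I_KV - I_MV| / |I_KV + I_MV| between the two modalities — where they
  disagree strongly the kV value is presumed artifact-corrupted and the MV
  value is trusted;
* the distance weight w_d is a Gaussian low-pass of the metal mask,
  normalized to 1 on the metal — artifacts concentrate near metal, so the
  MV share decays with distance from it and the fused image returns to the
  sharper, quieter kV image in the far field.

The prior is the fused image with metal pixels replaced by water (0 HU);
its forward projection supplies the surrogate data inside the metal trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import morphology

from .grid import ImageGrid, require_same_grid
from .physics import METAL_THRESHOLD_HU

DEFAULT_R_LO = 0.05
DEFAULT_R_HI = 0.40
DEFAULT_SIGMA_MM = 60.0


@dataclass
class MetalMask:
    """Binary metal segmentation aligned with an image grid."""

    mask: np.ndarray
    threshold_hu: float = METAL_THRESHOLD_HU

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class WeightMaps:
    """Per-pixel fusion coefficients, both in [0, 1]."""

    w: np.ndarray
    w_d: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in (("w", self.w), ("w_d", self.w_d)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")


def segment_metal(
    image: ImageGrid,
    threshold_hu: float = METAL_THRESHOLD_HU,
    min_area_px: int = 0,
) -> MetalMask:
    """Threshold segmentation of metal (HU >= threshold).

    min_area_px > 0 removes connected components smaller than that many
    pixels (noise spikes in the MV image can exceed the threshold).
    """
    mask = image.values >= threshold_hu
    if min_area_px > 0:
        mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    return MetalMask(mask=mask, threshold_hu=threshold_hu)


def relative_deviation(i_kv: ImageGrid, i_mv: ImageGrid) -> np.ndarray:
    """R = |kV - MV| / |kV + MV|, with zero denominators replaced by 1."""
    require_same_grid(i_kv, i_mv)
    num = np.abs(i_kv.values - i_mv.values)
    den = np.abs(i_kv.values + i_mv.values)
    den = np.where(den == 0.0, 1.0, den)
    return num / den


def deviation_weight(
    r: np.ndarray, r_lo: float = DEFAULT_R_LO, r_hi: float = DEFAULT_R_HI
) -> np.ndarray:
    """Clamped linear ramp: 0 below r_lo, 1 above r_hi, linear between."""
    if not (0 <= r_lo < r_hi):
        raise ValueError("need 0 <= r_lo < r_hi")
    return np.clip((np.asarray(r, dtype=float) - r_lo) / (r_hi - r_lo), 0.0, 1.0)


def distance_weight(
    metal: MetalMask,
    pixel_spacing_mm: tuple[float, float],
    sigma_mm: float = DEFAULT_SIGMA_MM,
) -> np.ndarray:
    """Gaussian low-pass of the metal indicator, rescaled to 1 on metal.

    A plain Gaussian blur of a thin mask never reaches 1, so the map is
    rescaled by its maximum over metal pixels; values elsewhere decay with
    distance from the metal. An empty mask yields an all-zero map (with a
    warning), which makes fusion degenerate to the kV image.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be > 0")
    if metal.empty:
        warnings.warn("empty metal mask: distance weight is identically zero")
        return np.zeros(metal.mask.shape)
    sigma_px = (sigma_mm / pixel_spacing_mm[0], sigma_mm / pixel_spacing_mm[1])
    blurred = gaussian_filter(metal.mask.astype(float), sigma=sigma_px)
    w_d = blurred / blurred[metal.mask].max()
    return np.clip(w_d, 0.0, 1.0)


def fuse(i_kv: ImageGrid, i_mv_pseudo: ImageGrid, weights: WeightMaps) -> ImageGrid:
    """Blend the kV and pseudo-kV MV images with the fusion weights."""
    require_same_grid(i_kv, i_mv_pseudo)
    w, w_d = weights.w, weights.w_d
    inner = w * i_mv_pseudo.values + (1.0 - w) * i_kv.values
    fused = w_d * inner + (1.0 - w_d) * i_kv.values
    return i_kv.with_values(fused)


def compute_weights(
    i_kv: ImageGrid,
    i_mv_pseudo: ImageGrid,
    metal: MetalMask,
    r_lo: float = DEFAULT_R_LO,
    r_hi: float = DEFAULT_R_HI,
    sigma_mm: float = DEFAULT_SIGMA_MM,
) -> WeightMaps:
    """Both weight maps for a co-registered kV / pseudo-kV MV pair."""
    r = relative_deviation(i_kv, i_mv_pseudo)
    w = deviation_weight(r, r_lo, r_hi)
    w_d = distance_weight(metal, i_kv.pixel_spacing, sigma_mm)
    return WeightMaps(
        w=w, w_d=w_d,
        params={"r_lo": r_lo, "r_hi": r_hi, "sigma_mm": sigma_mm,
                "zero_denominator_value": 1.0},
    )


def make_prior(fused: ImageGrid, metal: MetalMask, fill_hu: float = 0.0) -> ImageGrid:
    """Fused image with the metal region replaced by tissue (default water).

    The replaced region is the union of the supplied metal mask and a
    threshold segmentation of the fused image itself, so the prior is
    guaranteed to contain no metal-valued pixel even when detector blur
    makes the MV mask slightly tighter than the fused image's bright rim.
    """
    if metal.mask.shape != fused.shape:
        raise ValueError("metal mask does not match the fused image grid")
    region = metal.mask | (fused.values >= metal.threshold_hu)
    values = fused.values.copy()
    values[region] = fill_hu
    return fused.with_values(values)
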