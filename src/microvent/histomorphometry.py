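"""Collagen and alveolar-air area fractions on histology slide images.

ROIs come from cutting the left-lung mask into three slabs of equal
vertical extent (same remainder rule as the 3-D thirds). Within each ROI,
after subtracting an exclusion mask (bronchi, large vessels), the collagen
fraction is the percentage of pixels satisfying a green-stain colour rule
and the air fraction the percentage satisfying a white rule. Both rules are
calibration-dependent and exposed as parameters; fractions are invariant to
the µm²/pixel scale, which is carried as metadata only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .biomarkers import slab_bounds

ROI_NAMES = ("upper", "middle", "lower")


@dataclass(frozen=True)
class GreenRule:
    """Green-stained collagen: hue window plus saturation/value floors."""

    hue_min_deg: float = 80.0
    hue_max_deg: float = 160.0
    min_saturation: float = 0.15
    min_value: float = 0.2

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        hsv = rgb2hsv(rgb)
        hue_deg = hsv[..., 0] * 360.0
        return (
            (hue_deg >= self.hue_min_deg)
            & (hue_deg <= self.hue_max_deg)
            & (hsv[..., 1] >= self.min_saturation)
            & (hsv[..., 2] >= self.min_value)
        )


@dataclass(frozen=True)
class WhiteRule:
    """Alveolar air (unstained): all channels near full scale."""

    min_fraction: float = 0.85

    def __call__(self, rgb: np.ndarray) -> np.ndarray:
        return rgb.min(axis=-1) >= self.min_fraction


def _as_float_rgb(slide: np.ndarray) -> np.ndarray:
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[-1] != 3:
        raise ValueError("slide must be an RGB image (h, w, 3)")
    if np.issubdtype(slide.dtype, np.integer):
        return slide.astype(float) / np.iinfo(slide.dtype).max
    return slide.astype(float)


def split_slide_rois(lung_mask_2d: np.ndarray) -> np.ndarray:
    """Label the 2-D left-lung mask into three equal-vertical-extent ROIs.

    Returns an integer map: 0 outside, 1/2/3 = upper/middle/lower; the
    vertical axis is the row axis, and remainder rows go to the upper slabs.
    """
    mask = np.asarray(lung_mask_2d) != 0
    if mask.ndim != 2:
        raise ValueError("lung mask must be 2-dimensional")
    if not mask.any():
        raise ValueError("empty lung mask")
    rows = np.nonzero(mask.any(axis=1))[0]
    lo, hi = int(rows[0]), int(rows[-1]) + 1
    labels = np.zeros(mask.shape, dtype=np.uint8)
    for i, (a, b) in enumerate(slab_bounds(hi - lo, 3)):
        sub = labels[lo + a : lo + b]
        sub[mask[lo + a : lo + b]] = i + 1
    return labels


def _area_fraction(slide, roi, exclusion, rule) -> float:
    rgb = _as_float_rgb(slide)
    roi = np.asarray(roi) != 0
    if exclusion is not None:
        roi = roi & ~(np.asarray(exclusion) != 0)
    n = int(roi.sum())
    if n == 0:
        raise ValueError("empty ROI after exclusion")
    return 100.0 * int(np.count_nonzero(rule(rgb) & roi)) / n


def collagen_fraction(
    slide: np.ndarray,
    roi: np.ndarray,
    exclusion: np.ndarray | None = None,
    green_rule: GreenRule = GreenRule(),
) -> float:
    """Percent of ROI area (post-exclusion) covered by green-stained collagen."""
    return _area_fraction(slide, roi, exclusion, green_rule)


def air_fraction(
    slide: np.ndarray,
    roi: np.ndarray,
    exclusion: np.ndarray | None = None,
    white_rule: WhiteRule = WhiteRule(),
) -> float:
    """Percent of ROI area (post-exclusion) detected as alveolar air."""
    return _area_fraction(slide, roi, exclusion, white_rule)
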