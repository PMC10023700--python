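"""Specific-gas-volume conversion and ΔSVg ventilation mapping.

A CT voxel's specific volume (ml/g, inverse density) splits into tissue and
gas contributions. With the standard HU convention (water 0, air −1000) the
total specific volume is ``SV_total = 1000 / (HU + 1000)`` and the specific
gas volume is ``SVg = SV_total − SV_tissue`` with tissue assumed at
1/1.065 ≈ 0.939 ml/g. Ventilation is the voxel-wise inspiratory-minus-
expiratory difference ``ΔSVg = SVg_insp − SVg_exp`` (expiratory volume
already warped onto the inspiratory grid), in ml of gas per gram of tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import OUTSIDE_SENTINEL, ImageVolume, LungMask

log = logging.getLogger(__name__)

#: Printed tissue density 1.065 g/ml -> specific volume rounded to 0.939 ml/g.
SV_TISSUE_DEFAULT = 0.939


@dataclass(frozen=True)
class SvgConstants:
    """Constants of the HU → SVg conversion.

    ``hu_floor`` clamps HU values from below before conversion: the mapping
    1000/(HU+1000) diverges as HU → −1000 (pure air), so near-air voxels are
    clamped to keep SVg finite. The number of clamped voxels is logged.
    """

    sv_tissue: float = SV_TISSUE_DEFAULT
    hu_floor: float = -990.0

    def __post_init__(self) -> None:
        if self.sv_tissue <= 0:
            raise ValueError("sv_tissue must be positive")
        if self.hu_floor <= -1000:
            raise ValueError("hu_floor must exceed -1000 HU")


def sv_total(hu_value, consts: SvgConstants = SvgConstants()):
    """Total (tissue + gas) specific volume, ml/g: 1000/(HU+1000), HU clamped."""
    hu = np.maximum(np.asarray(hu_value, dtype=float), consts.hu_floor)
    return 1000.0 / (hu + 1000.0)


def svg_map(vol: ImageVolume, mask: LungMask, consts: SvgConstants = SvgConstants()) -> ImageVolume:
    """Specific gas volume map inside the lung mask; outside voxels are NaN."""
    if vol.unit != "HU":
        raise ValueError(f"svg_map expects an HU volume, got {vol.unit!r}")
    vol.require_same_grid(mask, "mask")
    hu = vol.data.astype(float)
    n_clamped = int(np.count_nonzero((hu < consts.hu_floor) & mask.data))
    if n_clamped:
        log.info("svg_map: clamped %d in-mask voxels below %.0f HU", n_clamped, consts.hu_floor)
    svg = sv_total(hu, consts) - consts.sv_tissue
    out = np.full(vol.shape, OUTSIDE_SENTINEL, dtype=float)
    out[mask.data] = svg[mask.data]
    return vol.with_data(out, unit="SVg")


def ventilation_map(
    svg_insp: ImageVolume, svg_exp_warped: ImageVolume, mask_insp: LungMask
) -> ImageVolume:
    """Voxel-wise ΔSVg = SVg_insp − SVg_exp on the inspiratory grid.

    Negative values (voxels denser at inspiration) are preserved, not
    clipped. Outside the inspiratory mask the map is NaN.
    """
    if svg_insp.unit != "SVg" or svg_exp_warped.unit != "SVg":
        raise ValueError("ventilation_map expects two SVg volumes")
    svg_insp.require_same_grid(svg_exp_warped, "expiratory SVg")
    svg_insp.require_same_grid(mask_insp, "mask")
    dsvg = np.full(svg_insp.shape, OUTSIDE_SENTINEL, dtype=float)
    m = mask_insp.data
    dsvg[m] = svg_insp.data[m] - svg_exp_warped.data[m]
    return svg_insp.with_data(dsvg, unit="dSVg")
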