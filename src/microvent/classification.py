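"""Percentile-threshold functional classification of the ventilation map.

Thresholds are never fixed constants: they are percentiles of the pooled
voxel distributions of a healthy (saline-treated) control cohort —
α_I and α_E the 5th percentiles of inspiratory and expiratory SVg, β the
25th percentile of ΔSVg. Each in-mask voxel of a subject is then sorted
into one of three classes:

* fibrosis (F): SVg_insp < α_I and SVg_exp < α_E — dense in both phases;
* low ventilation (LV): not F, and ΔSVg < β;
* normal ventilation (NV): not F, and ΔSVg ≥ β.

Voxels failing exactly one α margin are resolved by the ΔSVg rule so the
three classes always partition the lung; the count of such mixed-margin
voxels is logged for QC.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GridMismatchError, ImageVolume, LungMask

log = logging.getLogger(__name__)

LABEL_OUTSIDE, LABEL_F, LABEL_LV, LABEL_NV = 0, 1, 2, 3
LABEL_LEGEND = {0: "outside", 1: "F", 2: "LV", 3: "NV"}

#: Guard tolerance (ml/g) on the strict threshold comparisons. With
#: degenerate (piecewise-constant) value pools a percentile lands exactly on
#: an atom of the distribution and interpolation round-off would otherwise
#: split the atom arbitrarily across the boundary; 1e-9 ml/g is orders of
#: magnitude below any physical SVg signal.
COMPARISON_TOL = 1e-9


@dataclass(frozen=True)
class FunctionalThresholds:
    """Classification thresholds (ml/g) with derivation provenance."""

    alpha_I: float
    alpha_E: float
    beta: float
    p_alpha: float = 5.0
    p_beta: float = 25.0
    cohort_id: str = ""
    n_voxels: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "FunctionalThresholds":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class FunctionalMap:
    """Per-voxel F/LV/NV labelling on the inspiratory grid.

    ``labels`` is uint8 with the coding of :data:`LABEL_LEGEND`
    (0 outside, 1 F, 2 LV, 3 NV).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thresholds: FunctionalThresholds | None = None
    mixed_margin_voxels: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-dimensional")

    @property
    def shape(self):
        return self.labels.shape

    def in_mask(self) -> np.ndarray:
        return self.labels != LABEL_OUTSIDE


def _percentile_pool(samples, name: str) -> np.ndarray:
    pool = np.concatenate([np.ravel(np.asarray(s, dtype=float)) for s in samples])
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError(f"empty {name} sample pool")
    return pool


def derive_thresholds(
    saline_svg_insp_samples,
    saline_svg_exp_samples,
    saline_dsvg_samples,
    p_alpha: float = 5.0,
    p_beta: float = 25.0,
    cohort_id: str = "saline",
) -> FunctionalThresholds:
    """Percentile thresholds from pooled saline-cohort voxel values.

    Each ``*_samples`` argument is a sequence of per-animal value arrays
    (NaN entries, e.g. mask sentinels, are dropped); pooling concatenates
    all animals' in-mask voxels. Percentiles use linear interpolation
    between adjacent order statistics (quantile type 7).
    """
    if not (0 < p_alpha < 100 and 0 < p_beta < 100):
        raise ValueError("percentile levels must lie in (0, 100)")
    insp = _percentile_pool(saline_svg_insp_samples, "inspiratory SVg")
    exp = _percentile_pool(saline_svg_exp_samples, "expiratory SVg")
    dsvg = _percentile_pool(saline_dsvg_samples, "dSVg")
    return FunctionalThresholds(
        alpha_I=float(np.percentile(insp, p_alpha)),
        alpha_E=float(np.percentile(exp, p_alpha)),
        beta=float(np.percentile(dsvg, p_beta)),
        p_alpha=p_alpha,
        p_beta=p_beta,
        cohort_id=cohort_id,
        n_voxels=int(insp.size),
    )


def classify(
    svg_insp: ImageVolume,
    svg_exp_warped: ImageVolume,
    dsvg: ImageVolume,
    thresholds: FunctionalThresholds,
    mask: LungMask,
) -> FunctionalMap:
    """Sort every in-mask voxel into F / LV / NV (see module docstring)."""
    for vol, unit in ((svg_insp, "SVg"), (svg_exp_warped, "SVg"), (dsvg, "dSVg")):
        if vol.unit != unit:
            raise ValueError(f"expected a {unit} volume, got {vol.unit!r}")
        svg_insp.require_same_grid(vol)
    svg_insp.require_same_grid(mask, "mask")
    if not thresholds.cohort_id:
        warnings.warn("thresholds carry no cohort provenance")

    m = mask.data
    vi, ve, dv = svg_insp.data, svg_exp_warped.data, dsvg.data
    below_ai = vi < thresholds.alpha_I - COMPARISON_TOL
    below_ae = ve < thresholds.alpha_E - COMPARISON_TOL
    is_f = below_ai & below_ae
    is_lv = ~is_f & (dv < thresholds.beta - COMPARISON_TOL)

    labels = np.full(svg_insp.shape, LABEL_OUTSIDE, dtype=np.uint8)
    labels[m] = LABEL_NV
    labels[m & is_lv] = LABEL_LV
    labels[m & is_f] = LABEL_F

    mixed = int(np.count_nonzero(m & (below_ai ^ below_ae)))
    if mixed:
        log.info("classify: %d mixed-margin voxels resolved by the dSVg rule", mixed)
    return FunctionalMap(
        labels=labels,
        spacing=svg_insp.spacing,
        origin=svg_insp.origin,
        thresholds=thresholds,
        mixed_margin_voxels=mixed,
    )


def class_percentages(fmap: FunctionalMap, region_mask: LungMask) -> tuple[float, float, float]:
    """(%F, %LV, %NV) of in-region voxel count; the three sum to 100."""
    if fmap.shape != region_mask.shape:
        raise GridMismatchError("region mask grid does not match the functional map")
    region = region_mask.data & fmap.in_mask()
    n = int(region.sum())
    if n == 0:
        raise ValueError("empty region")
    lab = fmap.labels[region]
    return tuple(
        100.0 * int(np.count_nonzero(lab == code)) / n
        for code in (LABEL_F, LABEL_LV, LABEL_NV)
    )  # type: ignore[return-value]
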