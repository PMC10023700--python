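"""Regional partitioning, histogram biomarkers, and rank correlation.

Density (HU) and ventilation (ΔSVg) distributions inside the lung are
summarised per region by median, 75th percentile and interquartile range;
functional-class volume percentages come from the classification module.
Regions are the whole lung, cranio-caudal halves (upper/lower), or thirds
along a chosen axis (ventral/intermediate/dorsal for histology matching).
Group-level density histograms are per-bin medians of per-subject
frequency-normalised histograms, and imaging biomarkers are compared to
histomorphometric endpoints with a Spearman rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import FunctionalMap, class_percentages
from .core import ImageVolume, LungMask

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Default density-histogram bin edges: 25-HU bins over [-1000, 500] HU.
DEFAULT_HU_EDGES = np.arange(-1000.0, 500.0 + 25.0, 25.0)

SCHEME_REGIONS = {
    "whole": ("whole",),
    "halves": ("upper", "lower"),
    "thirds": ("ventral", "intermediate", "dorsal"),
}


@dataclass
class RegionPartition:
    """Disjoint labelled regions covering the lung mask.

    ``labels`` holds 0 outside the lung and 1..k inside; ``region_names``
    maps label i to its name in slab order along ``axis`` (the first slab is
    the one at the low-index end: cranial for z, ventral for y).
    """

    labels: np.ndarray
    region_names: tuple[str, ...]
    scheme: str
    axis: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def region_mask(self, name: str) -> LungMask:
        idx = self.region_names.index(name) + 1
        return LungMask(self.labels == idx, spacing=self.spacing, origin=self.origin)

    def voxel_counts(self) -> dict[str, int]:
        return {
            name: int(np.count_nonzero(self.labels == i + 1))
            for i, name in enumerate(self.region_names)
        }


def slab_bounds(extent: int, n_regions: int) -> list[tuple[int, int]]:
    """Cut *extent* slices into *n_regions* contiguous slabs.

    Slab sizes differ by at most one; the remainder goes to the first
    (cranial-most / ventral-most) slabs.
    """
    if extent < n_regions:
        raise ValueError(f"extent {extent} shorter than {n_regions} regions")
    base, rem = divmod(extent, n_regions)
    bounds, start = [], 0
    for i in range(n_regions):
        size = base + (1 if i < rem else 0)
        bounds.append((start, start + size))
        start += size
    return bounds


def split_regions(mask: LungMask, scheme: str, axis: str = "z") -> RegionPartition:
    """Partition the lung mask into whole / halves / thirds along *axis*."""
    if scheme not in SCHEME_REGIONS:
        raise ValueError(f"unknown scheme {scheme!r}")
    names = SCHEME_REGIONS[scheme]
    labels = np.zeros(mask.shape, dtype=np.uint8)
    if scheme == "whole":
        labels[mask.data] = 1
        return RegionPartition(labels, names, scheme, axis, mask.spacing, mask.origin)
    ax = AXIS_INDEX[axis]
    proj = np.any(mask.data, axis=tuple(a for a in range(3) if a != ax))
    occupied = np.nonzero(proj)[0]
    lo, hi = int(occupied[0]), int(occupied[-1]) + 1
    for i, (a, b) in enumerate(slab_bounds(hi - lo, len(names))):
        slicer = [slice(None)] * 3
        slicer[ax] = slice(lo + a, lo + b)
        sub = labels[tuple(slicer)]
        sub[mask.data[tuple(slicer)]] = i + 1
    return RegionPartition(labels, names, scheme, axis, mask.spacing, mask.origin)


def distribution_metrics(vol: ImageVolume, region: LungMask | np.ndarray) -> tuple[float, float, float]:
    """(median, 75th percentile, IQR) of in-region voxel values.

    Percentiles use the same linear-interpolation convention as the
    classification thresholds; IQR = p75 − p25.
    """
    if vol.unit not in ("HU", "dSVg"):
        raise ValueError(f"distribution_metrics expects HU or dSVg, got {vol.unit!r}")
    sel = region.data if isinstance(region, LungMask) else np.asarray(region, dtype=bool)
    values = vol.data[sel]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty region")
    p25, p50, p75 = np.percentile(values, [25, 50, 75])
    return float(p50), float(p75), float(p75 - p25)


def subject_histogram(
    vol: ImageVolume, mask: LungMask, bin_edges: np.ndarray = DEFAULT_HU_EDGES
) -> np.ndarray:
    """Frequency-normalised histogram of in-mask values (sums to 1).

    Values outside the edge range are counted into the end bins, with a
    warning.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing, length >= 2")
    values = vol.data[mask.data]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty mask")
    n_out = int(np.count_nonzero((values < edges[0]) | (values > edges[-1])))
    if n_out:
        warnings.warn(f"{n_out} values outside histogram range counted into end bins")
    clipped = np.clip(values, edges[0], edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / counts.sum()


def group_median_histogram(rows: list[np.ndarray]) -> np.ndarray:
    """Per-bin median curve across subjects (need not sum to 1)."""
    if not rows:
        raise ValueError("need at least one subject histogram")
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2:
        raise ValueError("subject histograms must share bin edges (equal lengths)")
    return np.median(arr, axis=0)


def spearman(x, y, method: str = "auto") -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    ``method='t'`` uses the t-approximation on n−2 degrees of freedom for
    the p-value (the default for n > 8); ``'exact'`` enumerates all
    permutations (n ≤ 8). ``'auto'`` picks exact for n ≤ 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exact" if n <= 8 else "t"
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-value limited to n <= 8")
        from itertools import permutations

        perms = np.array(list(permutations(ry)))
        rhos = np.corrcoef(np.vstack([rx, perms]))[0, 1:]
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    elif method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    else:
        raise ValueError(f"unknown method {method!r}")
    return rho, p


# ---------------------------------------------------------------------------
# Biomarker table

DENSITY_METRICS = ("HU_median", "HU_p75", "HU_IQR")
VENT_METRICS = ("dSVg_median", "dSVg_p75", "dSVg_IQR")
CLASS_METRICS = ("pctF", "pctLV", "pctNV")
ALL_METRICS = DENSITY_METRICS + VENT_METRICS + CLASS_METRICS

_UNITS = {**{m: "HU" for m in DENSITY_METRICS}, **{m: "ml/g" for m in VENT_METRICS},
          **{m: "%" for m in CLASS_METRICS}}


@dataclass
class SubjectData:
    """Per-subject inputs for the biomarker table."""

    subject: str
    day: int
    hu_insp: ImageVolume
    dsvg: ImageVolume | None = None
    fmap: FunctionalMap | None = None
    mask: LungMask | None = None


def biomarker_table(
    subjects: list[SubjectData],
    schemes: tuple[str, ...] = ("whole",),
    axes: dict[str, str] | None = None,
    metrics: tuple[str, ...] = ALL_METRICS,
) -> pd.DataFrame:
    """Long-format table: one row per subject × region × metric.

    ``axes`` maps scheme → axis (defaults: halves along z, thirds along y).
    Rows are ordered deterministically (subject, scheme, region, metric).
    """
    axes = {"halves": "z", "thirds": "y", "whole": "z", **(axes or {})}
    rows = []
    for sub in subjects:
        if sub.mask is None:
            raise ValueError(f"subject {sub.subject}: lung mask required")
        for scheme in schemes:
            part = split_regions(sub.mask, scheme, axes[scheme])
            for region_name in part.region_names:
                rmask = part.region_mask(region_name)
                values: dict[str, float] = {}
                if any(m in metrics for m in DENSITY_METRICS):
                    med, p75, iqr = distribution_metrics(sub.hu_insp, rmask)
                    values.update(HU_median=med, HU_p75=p75, HU_IQR=iqr)
                if any(m in metrics for m in VENT_METRICS):
                    if sub.dsvg is None:
                        raise ValueError(f"subject {sub.subject}: dSVg map required")
                    med, p75, iqr = distribution_metrics(sub.dsvg, rmask)
                    values.update(dSVg_median=med, dSVg_p75=p75, dSVg_IQR=iqr)
                if any(m in metrics for m in CLASS_METRICS):
                    if sub.fmap is None:
                        raise ValueError(f"subject {sub.subject}: functional map required")
                    f, lv, nv = class_percentages(sub.fmap, rmask)
                    values.update(pctF=f, pctLV=lv, pctNV=nv)
                for metric in metrics:
                    rows.append(
                        {
                            "subject": sub.subject,
                            "day": sub.day,
                            "region": region_name,
                            "metric": metric,
                            "value": values[metric],
                            "units": _UNITS[metric],
                        }
                    )
    return pd.DataFrame(rows, columns=["subject", "day", "region", "metric", "value", "units"])
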