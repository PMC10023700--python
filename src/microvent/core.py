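"""Core grid containers shared by every stage of the pipeline.

All volumes live on axis-aligned regular grids with (x, y, z) index order,
z being the cranio-caudal axis. Physical coordinates are in micrometres:
``point = origin + index * spacing`` (voxel-centre convention, 0-based).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Recognised intensity-unit tags.
UNITS = ("raw", "HU", "SVg", "dSVg")

#: Sentinel stored outside the analysis mask in SVg / dSVg maps.
OUTSIDE_SENTINEL = np.nan


class GridMismatchError(ValueError):
    """Two objects that must share a grid (shape, spacing, origin) do not."""


@dataclass
class ImageVolume:
    """A 3-D scalar image with physical grid metadata and a unit tag.

    Parameters
    ----------
    data
        3-D array indexed ``[x, y, z]``.
    spacing
        Per-axis voxel size in µm (all components > 0).
    origin
        Physical coordinate (µm) of voxel (0, 0, 0).
    unit
        One of :data:`UNITS`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (50.0, 50.0, 50.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    unit: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-dimensional")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    # -- grid helpers -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def same_grid(self, other: "ImageVolume | LungMask", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "ImageVolume | LungMask", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} grid mismatch: {self.shape}/{self.spacing}/{self.origin} vs "
                f"{other.shape}/{other.spacing}/{other.origin}"
            )

    def index_to_physical(self, index: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to physical µm points."""
        return np.asarray(self.origin) + np.asarray(index) * np.asarray(self.spacing)

    def physical_to_index(self, point: np.ndarray) -> np.ndarray:
        """Map physical µm points (..., 3) to fractional voxel indices."""
        return (np.asarray(point) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def physical_extent(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) physical corner coordinates of the voxel-centre lattice."""
        low = np.asarray(self.origin, dtype=float)
        high = low + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return low, high

    def with_data(self, data: np.ndarray, unit: str | None = None) -> "ImageVolume":
        """A copy of this volume carrying new voxel data (and optionally a new unit)."""
        return replace(self, data=data, unit=self.unit if unit is None else unit)


@dataclass
class LungMask:
    """Binary lung mask on the same grid as its companion :class:`ImageVolume`.

    ``side`` optionally labels voxels 1 = left, 2 = right (0 elsewhere).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (50.0, 50.0, 50.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    side: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        if arr.dtype != bool:
            if np.any((arr != 0) & (arr != 1)):
                warnings.warn("mask has values outside {0,1}; treating nonzero as foreground")
            arr = arr != 0
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not arr.any():
            raise ValueError("mask is empty")
        if self.side is not None and self.side.shape != arr.shape:
            raise ValueError("side labels must share the mask shape")

    shape = ImageVolume.shape
    same_grid = ImageVolume.same_grid
    require_same_grid = ImageVolume.require_same_grid

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class LandmarkSet:
    """Paired physical landmark coordinates (µm) on the fixed and moving images."""

    fixed_points: np.ndarray   # (n, 3) µm
    moving_points: np.ndarray  # (n, 3) µm
    ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fixed_points = np.atleast_2d(np.asarray(self.fixed_points, dtype=float))
        self.moving_points = np.atleast_2d(np.asarray(self.moving_points, dtype=float))
        if self.fixed_points.shape != self.moving_points.shape or self.fixed_points.shape[1] != 3:
            raise ValueError("landmark arrays must both be (n, 3)")
        if len(self.fixed_points) < 1:
            raise ValueError("landmark set must contain at least one pair")
        if not len(self.ids):
            self.ids = [f"L{i}" for i in range(len(self.fixed_points))]
        if len(self.ids) != len(self.fixed_points):
            raise ValueError("one id per landmark pair required")

    def __len__(self) -> int:
        return len(self.fixed_points)

    def require_inside(self, vol: ImageVolume, which: str = "fixed") -> None:
        pts = self.fixed_points if which == "fixed" else self.moving_points
        low, high = vol.physical_extent()
        if np.any(pts < low - 1e-9) or np.any(pts > high + 1e-9):
            raise ValueError(f"{which} landmarks fall outside the volume extent")
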