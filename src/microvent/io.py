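"""Volume / mask / landmark I/O and grey-level → Hounsfield-Unit calibration.

Supported volume formats: NIfTI (``.nii``/``.nii.gz``), MetaImage
(``.mha``/``.mhd``) and single-channel 3-D TIFF stacks (TIFF carries no
spacing metadata, so a spacing must be supplied explicitly).  Header spacing
values are interpreted as micrometres throughout, matching the µm convention
of the rest of the package.

Landmark files are plain CSV with columns ``id, fx, fy, fz, mx, my, mz``
(physical µm coordinates of the fixed and moving point of each pair).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import ImageVolume, LandmarkSet, LungMask

_SITK_EXTENSIONS = (".nii", ".nii.gz", ".mha", ".mhd")
_TIFF_EXTENSIONS = (".tif", ".tiff")


def _extension(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


def read_volume(
    path: str,
    expected_unit: str = "raw",
    spacing: tuple[float, float, float] | None = None,
) -> ImageVolume:
    """Read a 3-D volume and tag it with *expected_unit*.

    Grid spacing/origin come from the file header (µm). For TIFF stacks,
    which carry no grid metadata, *spacing* is required; passing it for
    other formats overrides the header.
    """
    ext = _extension(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if ext in _TIFF_EXTENSIONS and spacing is None:
        raise ValueError("TIFF stacks carry no spacing metadata; pass spacing= explicitly")
    if ext not in _SITK_EXTENSIONS + _TIFF_EXTENSIONS:
        raise ValueError(f"unsupported volume format {ext!r}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3 or img.GetNumberOfComponentsPerPixel() != 1:
        raise ValueError("volume must be 3-dimensional and single-channel")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    sp = spacing if spacing is not None else tuple(img.GetSpacing())
    origin = tuple(img.GetOrigin()) if ext not in _TIFF_EXTENSIONS else (0.0, 0.0, 0.0)
    return ImageVolume(data=data, spacing=sp, origin=origin, unit=expected_unit)


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write *vol* to NIfTI or MetaImage; round-trips grid metadata and values."""
    ext = _extension(path)
    if ext not in _SITK_EXTENSIONS:
        raise ValueError(f"unsupported volume format {ext!r}")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    data = vol.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path: str, spacing: tuple[float, float, float] | None = None) -> LungMask:
    """Read a binary lung mask; any nonzero voxel is treated as foreground."""
    vol = read_volume(path, expected_unit="raw", spacing=spacing)
    return LungMask(data=vol.data, spacing=vol.spacing, origin=vol.origin)


def write_mask(mask: LungMask, path: str) -> None:
    write_volume(
        ImageVolume(mask.data.astype(np.uint8), mask.spacing, mask.origin, "raw"), path
    )


def read_landmarks(path: str) -> LandmarkSet:
    df = pd.read_csv(path)
    required = ["id", "fx", "fy", "fz", "mx", "my", "mz"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"landmark CSV missing columns {missing}")
    return LandmarkSet(
        fixed_points=df[["fx", "fy", "fz"]].to_numpy(float),
        moving_points=df[["mx", "my", "mz"]].to_numpy(float),
        ids=[str(i) for i in df["id"]],
    )


def write_landmarks(landmarks: LandmarkSet, path: str) -> None:
    df = pd.DataFrame(
        {
            "id": list(landmarks.ids),
            "fx": landmarks.fixed_points[:, 0],
            "fy": landmarks.fixed_points[:, 1],
            "fz": landmarks.fixed_points[:, 2],
            "mx": landmarks.moving_points[:, 0],
            "my": landmarks.moving_points[:, 1],
            "mz": landmarks.moving_points[:, 2],
        }
    )
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationSpec:
    """Linear grey-level → HU calibration anchored on air and water.

    The scanner's raw grey-level scale is instrument-specific, so the raw
    anchors are always user-supplied. The HU anchors default to the standard
    convention (air = −1000 HU, water = 0 HU), which is the convention under
    which the specific-gas-volume formula 1000/(HU + 1000) assigns water a
    specific volume of exactly 1 ml/g.
    """

    raw_air: float
    raw_water: float
    hu_air: float = -1000.0
    hu_water: float = 0.0

    def __post_init__(self) -> None:
        if self.raw_air == self.raw_water:
            raise ValueError("degenerate calibration: raw_air == raw_water")
        if self.hu_air == self.hu_water:
            raise ValueError("degenerate calibration: hu_air == hu_water")

    @property
    def slope(self) -> float:
        return (self.hu_water - self.hu_air) / (self.raw_water - self.raw_air)

    def raw_to_hu(self, raw: np.ndarray) -> np.ndarray:
        return self.hu_air + (np.asarray(raw, dtype=float) - self.raw_air) * self.slope

    def hu_to_raw(self, hu: np.ndarray) -> np.ndarray:
        return self.raw_air + (np.asarray(hu, dtype=float) - self.hu_air) / self.slope


def grey_to_hu(raw: ImageVolume, cal: CalibrationSpec) -> ImageVolume:
    """Affine voxel-wise conversion of a raw-intensity volume to HU."""
    if raw.unit != "raw":
        raise ValueError(f"grey_to_hu expects a raw volume, got unit {raw.unit!r}")
    return raw.with_data(cal.raw_to_hu(raw.data), unit="HU")
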