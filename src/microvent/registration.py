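"""Deformable registration of the expiratory onto the inspiratory volume.

The registration is intensity-driven Demons (symmetric forces, Gaussian
field regularisation) run through a four-level multiresolution pyramid.
Because lung density changes between respiratory phases, the similarity is
driven by Laplacian-filtered images — edge/structure maps that are far less
sensitive to the global intensity shift than the HU values themselves — and
the moving Laplacian image is histogram-matched to the fixed one before the
update loop. The resulting displacement field is expressed on the fixed
(inspiratory) grid in physical µm and is applied to the *unfiltered* HU
volumes.

Conventions: the field u maps a fixed-grid physical point p to the
corresponding moving-image point p + u(p); warping samples the moving image
at those points (edge-value padding outside the moving extent, with the
out-of-domain voxel count recorded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .core import GridMismatchError, ImageVolume, LandmarkSet, LungMask

DEFAULT_ITERATIONS = (100, 100, 50, 25)  # coarse -> fine


@dataclass
class DeformationField:
    """Dense per-voxel displacement (µm) on the fixed (inspiratory) grid.

    ``vectors`` has shape (nx, ny, nz, 3); components are ordered (x, y, z)
    in physical µm.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("deformation field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("deformation field contains non-finite components")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolate the displacement at physical points (n, 3) µm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        ]
        out = np.empty_like(pts)
        for c in range(3):
            interp = RegularGridInterpolator(
                axes, self.vectors[..., c], bounds_error=False, fill_value=None
            )
            out[:, c] = interp(pts)
        return out


@dataclass
class RegistrationReport:
    """Convergence and accuracy metrics for one registration run."""

    iterations_per_level: list[int] = field(default_factory=list)
    final_metric: float = float("nan")
    mean_squared_difference: float = float("nan")
    out_of_domain_voxels: int = 0
    tre_before: dict | None = None
    tre_after: dict | None = None

    def as_dict(self) -> dict:
        return {
            "iterations_per_level": self.iterations_per_level,
            "final_metric": self.final_metric,
            "mean_squared_difference": self.mean_squared_difference,
            "out_of_domain_voxels": self.out_of_domain_voxels,
            "tre_before": self.tre_before,
            "tre_after": self.tre_after,
        }


def laplacian_preprocess(vol: ImageVolume) -> ImageVolume:
    """Discrete 3-D Laplacian (7-point stencil) of an HU volume.

    Emphasises structural boundaries over absolute intensity; the output is
    tagged ``raw`` since it no longer lives on the HU scale. Constant and
    affine-ramp inputs map to zero in the interior.
    """
    if vol.unit != "HU":
        raise ValueError("laplacian_preprocess expects an HU volume")
    return vol.with_data(ndimage.laplace(vol.data.astype(np.float64)), unit="raw")


# ---------------------------------------------------------------------------
# Demons multiresolution driver


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0).astype(np.float32)))
    img.SetSpacing(tuple(spacing))
    img.SetOrigin(tuple(origin))
    return img


def _shrink(img: sitk.Image, factor: int) -> sitk.Image:
    if factor == 1:
        # Light anti-noise smoothing at full resolution keeps the sparse
        # Laplacian edge maps differentiable for the Demons forces.
        return sitk.SmoothingRecursiveGaussian(img, 0.5 * min(img.GetSpacing()))
    smoothed = sitk.SmoothingRecursiveGaussian(img, 0.5 * factor * min(img.GetSpacing()))
    return sitk.Shrink(smoothed, [factor] * 3)


def demons_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    levels: int = 4,
    iterations_per_level: tuple[int, ...] = DEFAULT_ITERATIONS,
    smoothing_sigma: float = 1.5,
    mask: LungMask | None = None,
    landmarks: LandmarkSet | None = None,
) -> tuple[DeformationField, RegistrationReport]:
    """Four-level multiresolution symmetric-forces Demons registration.

    Parameters
    ----------
    fixed, moving
        HU volumes on grids with identical spacing (the inspiratory volume
        is the fixed one). Both are Laplacian-filtered internally before the
        similarity-driven update; the returned field applies to the
        unfiltered volumes.
    levels
        Pyramid depth (default 4, shrink factors 2**(levels-1) … 1).
    iterations_per_level
        Demons iterations per level, coarse → fine.
    smoothing_sigma
        Gaussian field-regularisation sigma in voxels.
    mask, landmarks
        Optional; used only for the report (masked MSD, TRE before/after).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if len(iterations_per_level) != levels:
        raise ValueError("need one iteration count per level")
    if any(n <= 0 for n in iterations_per_level):
        raise ValueError("iteration counts must be positive")
    if fixed.unit != "HU" or moving.unit != "HU":
        raise ValueError("demons_register expects HU volumes")
    if not np.allclose(fixed.spacing, moving.spacing):
        raise GridMismatchError("fixed and moving volumes must share voxel spacing")

    lap_fixed = laplacian_preprocess(fixed)
    lap_moving = laplacian_preprocess(moving)

    # Unit-variance normalisation of both edge maps compensates the
    # phase-dependent edge contrast (parenchymal HU, hence boundary
    # strength, changes with lung volume). Quantile-based matching is
    # deliberately avoided: a Laplacian image is dominated by a zero atom,
    # which makes histogram transforms unstable.
    f_img = sitk.Normalize(_to_sitk(lap_fixed.data, fixed.spacing, fixed.origin))
    m_img = sitk.Normalize(_to_sitk(lap_moving.data, moving.spacing, moving.origin))

    factors = [2 ** (levels - 1 - i) for i in range(levels)]
    report = RegistrationReport()
    disp: sitk.Image | None = None
    metric = float("nan")
    for factor, n_iter in zip(factors, iterations_per_level):
        f_lvl = _shrink(f_img, factor)
        m_lvl = _shrink(m_img, factor)
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(n_iter))
        demons.SetSmoothDisplacementField(True)
        demons.SetStandardDeviations(smoothing_sigma)  # ITK: voxel units
        if disp is None:
            disp = demons.Execute(f_lvl, m_lvl)
        else:
            disp = demons.Execute(f_lvl, m_lvl, sitk.Resample(disp, f_lvl))
        metric = demons.GetMetric()
        report.iterations_per_level.append(int(demons.GetElapsedIterations()))
    assert disp is not None
    if disp.GetSize() != f_img.GetSize():
        disp = sitk.Resample(disp, f_img)
    vectors = sitk.GetArrayFromImage(disp).transpose(2, 1, 0, 3).astype(float)
    fld = DeformationField(vectors=vectors, spacing=fixed.spacing, origin=fixed.origin)
    report.final_metric = float(metric)

    warped = warp(moving, fld, interpolation="linear")
    report.out_of_domain_voxels = _out_of_domain_count(moving, fld)
    diff = warped.data - fixed.data
    if mask is not None:
        report.mean_squared_difference = float(np.mean(diff[mask.data] ** 2))
    else:
        report.mean_squared_difference = float(np.mean(diff**2))
    if landmarks is not None:
        d0, m0, s0 = target_registration_error(landmarks, None)
        d1, m1, s1 = target_registration_error(landmarks, fld)
        report.tre_before = {"per_pair_um": d0.tolist(), "mean_um": m0, "sd_um": s0}
        report.tre_after = {"per_pair_um": d1.tolist(), "mean_um": m1, "sd_um": s1}
    return fld, report


def _moving_index_coords(moving, fld: DeformationField) -> np.ndarray:
    nx, ny, nz = fld.shape
    idx = np.stack(
        np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).astype(float)
    phys = np.asarray(fld.origin) + idx * np.asarray(fld.spacing) + fld.vectors
    return (phys - np.asarray(moving.origin)) / np.asarray(moving.spacing)


def _out_of_domain_count(moving, fld: DeformationField) -> int:
    coords = _moving_index_coords(moving, fld)
    n = np.asarray(moving.shape, dtype=float)
    outside = np.any((coords < 0) | (coords > n - 1), axis=-1)
    return int(outside.sum())


def warp(moving, fld: DeformationField, interpolation: str = "linear"):
    """Resample *moving* (ImageVolume or LungMask) onto the fixed grid through *fld*.

    ``output(p) = moving(p + u(p))`` for every fixed-grid point p; samples
    outside the moving extent take the edge value. Masks must use
    ``nearest`` so the output stays strictly binary.
    """
    is_mask = isinstance(moving, LungMask)
    if is_mask and interpolation != "nearest":
        raise ValueError("masks must be warped with nearest-neighbour interpolation")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    coords = _moving_index_coords(moving, fld)
    order = 1 if interpolation == "linear" else 0
    data = moving.data.astype(np.float64) if not is_mask else moving.data.astype(np.uint8)
    out = ndimage.map_coordinates(
        data, [coords[..., 0], coords[..., 1], coords[..., 2]], order=order, mode="nearest"
    )
    if is_mask:
        return LungMask(out.astype(bool), spacing=fld.spacing, origin=fld.origin)
    return ImageVolume(out, spacing=fld.spacing, origin=fld.origin, unit=moving.unit)


def target_registration_error(
    landmarks: LandmarkSet, fld: DeformationField | None = None
) -> tuple[np.ndarray, float, float]:
    """Per-pair Euclidean landmark distances (µm) with mean and sample sd.

    Without a field this is the pre-registration misalignment
    |fixed − moving|; with a field, |fixed + u(fixed) − moving|, the
    displacement interpolated trilinearly at each fixed point.
    """
    if len(landmarks) < 1:
        raise ValueError("empty landmark set")
    mapped = landmarks.fixed_points.copy()
    if fld is not None:
        mapped = mapped + fld.sample(landmarks.fixed_points)
    d = np.linalg.norm(mapped - landmarks.moving_points, axis=1)
    sd = float(np.std(d, ddof=1)) if len(d) > 1 else 0.0
    return d, float(np.mean(d)), sd
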