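"""Synthetic paired inspiratory/expiratory micro-CT phantom.

One phantom subject is a soft-tissue "torso" ellipsoid containing two
ellipsoidal lungs of ventilated parenchyma, optionally carrying fibrotic
and low-ventilation lesions (smooth seeded random blobs, biased toward the
caudal lung half), plus bright vessel-like spherical markers whose centres
define exact landmark pairs. The expiratory phase is produced by resampling
the inspiratory anatomy through a smooth analytic cranio-caudal compression
(raised-cosine profile: zero at the apex, maximal at the diaphragm, with a
small lateral expansion) and re-assigning each compartment its expiratory
HU value — parenchyma densifies at expiration, fibrotic tissue does not.
Gaussian HU noise is added last, and both volumes are re-encoded to raw
grey levels through a known affine calibration so the calibration stage of
the pipeline is exercised end-to-end.

Ground truth returned with every phantom: the analytic displacement field
(fixed/inspiratory grid, µm), the F/LV/NV class map, the landmark pairs,
both lung masks, and the compartment HU table.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy import ndimage

from .classification import LABEL_F, LABEL_LV, LABEL_NV, LABEL_OUTSIDE, FunctionalMap
from .core import ImageVolume, LandmarkSet, LungMask
from .io import CalibrationSpec
from .registration import DeformationField

# internal anatomy label codes
_AIR, _SOFT, _NV, _LV, _F, _MARKER = 0, 1, 2, 3, 4, 5
_LUNG_LABELS = (_NV, _LV, _F, _MARKER)


@dataclass(frozen=True)
class CompartmentHU:
    """Mean HU per compartment and phase."""

    soft_tissue: float = 40.0
    parenchyma_insp: float = -550.0
    parenchyma_exp: float = -400.0
    low_vent_insp: float = -450.0
    low_vent_exp: float = -420.0
    fibrosis: float = -100.0
    marker: float = 100.0
    air: float = -1000.0
    texture_sd: float = 0.0  # smooth intra-compartment heterogeneity (HU)


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one synthetic subject."""

    shape: tuple[int, int, int] = (128, 128, 128)
    spacing: float = 50.0  # µm, isotropic
    seed: int = 7
    hu: CompartmentHU = CompartmentHU()
    frac_f: float = 0.10   # fibrotic fraction of lung volume
    frac_lv: float = 0.15  # low-ventilation fraction of lung volume
    max_compression_vox: float = 6.0  # peak cranio-caudal displacement
    lateral_expansion: float = 0.02
    noise_sd: float = 0.0  # HU
    n_landmarks: int = 10
    marker_radius_vox: float = 2.0
    blob_smooth_vox: float = 8.0
    lesion_caudal_bias: float = 1.0
    calibration: CalibrationSpec = dc_field(
        default_factory=lambda: CalibrationSpec(raw_air=1000.0, raw_water=3000.0)
    )

    def saline(self, seed: int | None = None) -> "PhantomSpec":
        """A lesion-free (healthy control) variant of this spec."""
        return replace(self, frac_f=0.0, frac_lv=0.0, seed=self.seed if seed is None else seed)


@dataclass
class PhantomTruth:
    """Ground truth accompanying one phantom subject."""

    class_map: FunctionalMap
    field: DeformationField
    landmarks: LandmarkSet
    lung_mask_insp: LungMask
    lung_mask_exp: LungMask
    compartment_hu: CompartmentHU
    calibration: CalibrationSpec
    spec: PhantomSpec


@dataclass
class Phantom:
    """A generated phantom subject: raw paired-phase volumes plus truth."""

    insp_raw: ImageVolume
    exp_raw: ImageVolume
    mask_insp: LungMask
    mask_exp: LungMask
    truth: PhantomTruth


def _ellipsoid(shape, center, semi) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    acc = np.zeros(shape, dtype=float)
    for g, c, s in zip(grids, center, semi):
        acc += ((g - c) / s) ** 2
    return acc <= 1.0


def _raised_cosine_profile(z: np.ndarray, z0: float, z1: float) -> np.ndarray:
    """0 at the apex (z <= z0), 1 at the diaphragm (z >= z1), smooth between."""
    t = np.clip((z - z0) / (z1 - z0), 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * t))


def _profile_derivative(z: np.ndarray, z0: float, z1: float) -> np.ndarray:
    t = (z - z0) / (z1 - z0)
    d = 0.5 * np.pi / (z1 - z0) * np.sin(np.pi * np.clip(t, 0.0, 1.0))
    return np.where((t > 0) & (t < 1), d, 0.0)


def _top_k_mask(field: np.ndarray, eligible: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k largest field values among eligible voxels."""
    out = np.zeros(field.shape, dtype=bool)
    if k <= 0:
        return out
    idx = np.flatnonzero(eligible)
    vals = field.ravel()[idx]
    take = idx[np.argpartition(vals, -k)[-k:]]
    out.ravel()[take] = True
    return out


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom subject (deterministic for a given spec/seed)."""
    if not (0 <= spec.frac_f <= 1 and 0 <= spec.frac_lv <= 1 and spec.frac_f + spec.frac_lv <= 1):
        raise ValueError("lesion fractions must lie in [0,1] with F+LV <= 1")
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nx, ny, nz = shape
    sp = (spec.spacing,) * 3

    # --- inspiratory anatomy -------------------------------------------------
    label = np.full(shape, _AIR, dtype=np.uint8)
    torso = _ellipsoid(shape, [nx / 2, ny / 2, nz / 2], [0.45 * nx, 0.45 * ny, 0.48 * nz])
    label[torso] = _SOFT
    lungs = _ellipsoid(shape, [0.33 * nx, ny / 2, nz / 2], [0.17 * nx, 0.20 * ny, 0.31 * nz])
    lungs |= _ellipsoid(shape, [0.67 * nx, ny / 2, nz / 2], [0.17 * nx, 0.20 * ny, 0.31 * nz])
    lungs &= torso
    label[lungs] = _NV
    side = np.zeros(shape, dtype=np.uint8)
    side_plane = np.broadcast_to(
        np.where(np.arange(nx)[:, None, None] < nx / 2, 1, 2), shape
    )
    side[lungs] = side_plane[lungs]

    zs = np.nonzero(np.any(lungs, axis=(0, 1)))[0]
    z_apex, z_diaphragm = float(zs[0]), float(zs[-1])
    z_coord = np.arange(nz, dtype=float)
    s_of_z = _raised_cosine_profile(z_coord, z_apex, z_diaphragm)

    # deformation invertibility: |d(A*s)/dz| must stay < 1
    max_grad = spec.max_compression_vox * 0.5 * np.pi / (z_diaphragm - z_apex)
    if max_grad >= 1.0:
        raise ValueError("compression amplitude makes the deformation non-invertible")

    # --- lesions (smooth seeded blobs, caudally biased) ----------------------
    n_lung = int(lungs.sum())
    caudal_weight = (s_of_z - 0.5)[None, None, :]
    for frac, code in ((spec.frac_f, _F), (spec.frac_lv, _LV)):
        if frac > 0:
            g = ndimage.gaussian_filter(rng.standard_normal(shape), spec.blob_smooth_vox)
            g = g / g[lungs].std() + spec.lesion_caudal_bias * caudal_weight
            sel = _top_k_mask(g, label == _NV, int(round(frac * n_lung)))
            label[sel] = code

    # --- landmark markers (z-stratified, inside eroded healthy lung) ---------
    # markers must fit entirely inside healthy parenchyma so the truth class
    # fractions stay exact and landmark neighbourhoods are homogeneous
    eligible = ndimage.binary_erosion(
        label == _NV, iterations=int(np.ceil(spec.marker_radius_vox)) + 1
    ) & ndimage.binary_erosion(lungs, iterations=int(np.ceil(spec.marker_radius_vox)) + 3)
    centers = _stratified_marker_centers(eligible, spec.n_landmarks, rng)
    r = spec.marker_radius_vox
    ball_off = np.argwhere(
        _ellipsoid((2 * int(r) + 1,) * 3, [int(r)] * 3, [r + 0.25] * 3)
    ) - int(r)
    for c in centers:
        pts = c + ball_off
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        label[tuple(pts[ok].T)] = _MARKER

    # --- analytic deformation and expiratory anatomy -------------------------
    amp = spec.max_compression_vox
    eps = spec.lateral_expansion

    def phi(points_idx: np.ndarray) -> np.ndarray:
        """Forward map (index units): inspiratory point -> expiratory point."""
        p = np.atleast_2d(points_idx).astype(float)
        s = _raised_cosine_profile(p[:, 2], z_apex, z_diaphragm)
        out = p.copy()
        out[:, 2] = p[:, 2] - amp * s
        out[:, 0] = nx / 2 + (1 + eps * s) * (p[:, 0] - nx / 2)
        out[:, 1] = ny / 2 + (1 + eps * s) * (p[:, 1] - ny / 2)
        return out

    # invert z -> z - amp*s(z) for every expiratory slice index (Newton)
    pz = z_coord.copy()
    for _ in range(50):
        f = pz - amp * _raised_cosine_profile(pz, z_apex, z_diaphragm) - z_coord
        df = 1.0 - amp * _profile_derivative(pz, z_apex, z_diaphragm)
        pz = pz - f / df
    scale = 1.0 + eps * _raised_cosine_profile(pz, z_apex, z_diaphragm)
    qx = np.arange(nx)[:, None, None]
    qy = np.arange(ny)[None, :, None]
    px = nx / 2 + (qx - nx / 2) / scale[None, None, :]
    py = ny / 2 + (qy - ny / 2) / scale[None, None, :]
    xi = np.clip(np.rint(px).astype(int), 0, nx - 1)
    yi = np.clip(np.rint(py).astype(int), 0, ny - 1)
    zi = np.clip(np.rint(pz).astype(int), 0, nz - 1)
    label_exp = label[
        np.broadcast_to(xi, shape), np.broadcast_to(yi, shape), np.broadcast_to(zi, shape)
    ]

    # --- HU assignment, noise, raw encoding ----------------------------------
    hu = spec.hu
    lut_insp = np.array(
        [hu.air, hu.soft_tissue, hu.parenchyma_insp, hu.low_vent_insp, hu.fibrosis, hu.marker]
    )
    lut_exp = np.array(
        [hu.air, hu.soft_tissue, hu.parenchyma_exp, hu.low_vent_exp, hu.fibrosis, hu.marker]
    )
    hu_insp = lut_insp[label]
    hu_exp = lut_exp[label_exp]
    if hu.texture_sd > 0:
        tex = ndimage.gaussian_filter(rng.standard_normal(shape), 3.0)
        tex /= tex.std()
        in_lung_i = np.isin(label, (_NV, _LV))
        hu_insp = hu_insp + hu.texture_sd * tex * in_lung_i
        tex_exp = tex[
            np.broadcast_to(xi, shape), np.broadcast_to(yi, shape), np.broadcast_to(zi, shape)
        ]
        hu_exp = hu_exp + hu.texture_sd * tex_exp * np.isin(label_exp, (_NV, _LV))
    if spec.noise_sd > 0:
        hu_insp = hu_insp + rng.normal(0.0, spec.noise_sd, shape)
        hu_exp = hu_exp + rng.normal(0.0, spec.noise_sd, shape)

    cal = spec.calibration
    insp_raw = ImageVolume(cal.hu_to_raw(hu_insp).astype(np.float32), sp, unit="raw")
    exp_raw = ImageVolume(cal.hu_to_raw(hu_exp).astype(np.float32), sp, unit="raw")

    # --- truth ----------------------------------------------------------------
    mask_insp = LungMask(np.isin(label, _LUNG_LABELS), sp, side=side)
    mask_exp = LungMask(np.isin(label_exp, _LUNG_LABELS), sp)

    s3 = s_of_z[None, None, :]
    vectors = np.empty(shape + (3,), dtype=float)
    vectors[..., 0] = eps * s3 * (qx - nx / 2) * spec.spacing
    vectors[..., 1] = eps * s3 * (qy - ny / 2) * spec.spacing
    vectors[..., 2] = -amp * s3 * np.ones(shape) * spec.spacing
    truth_field = DeformationField(vectors=vectors, spacing=sp)

    fixed_pts = np.asarray(centers, dtype=float) * spec.spacing
    moving_pts = phi(np.asarray(centers, dtype=float)) * spec.spacing
    landmarks = LandmarkSet(fixed_pts, moving_pts)

    class_labels = np.full(shape, LABEL_OUTSIDE, dtype=np.uint8)
    class_labels[np.isin(label, (_NV, _MARKER))] = LABEL_NV
    class_labels[label == _LV] = LABEL_LV
    class_labels[label == _F] = LABEL_F
    class_map = FunctionalMap(labels=class_labels, spacing=sp)

    truth = PhantomTruth(
        class_map=class_map,
        field=truth_field,
        landmarks=landmarks,
        lung_mask_insp=mask_insp,
        lung_mask_exp=mask_exp,
        compartment_hu=hu,
        calibration=cal,
        spec=spec,
    )
    return Phantom(insp_raw, exp_raw, mask_insp, mask_exp, truth)


def _stratified_marker_centers(eligible: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n marker centres spread from apex to diaphragm (one per z band)."""
    zs = np.nonzero(np.any(eligible, axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("no eligible voxels for landmark markers")
    bands = np.array_split(np.arange(zs[0], zs[-1] + 1), n)
    centers = []
    for band in bands:
        sub = np.zeros_like(eligible)
        sub[:, :, band] = eligible[:, :, band]
        cand = np.argwhere(sub)
        if cand.size == 0:
            cand = np.argwhere(eligible)
        centers.append(cand[rng.integers(len(cand))])
    return np.asarray(centers)


def write_phantom(ph: Phantom, out_dir) -> dict:
    """Write one phantom subject to *out_dir*; returns the file manifest.

    Volumes and masks go to NIfTI, the truth field to a 3-component
    MetaImage, landmarks to CSV, and the resolved spec (with the
    calibration anchors) to JSON.
    """
    import dataclasses
    import json
    from pathlib import Path

    from .io import write_landmarks, write_mask, write_volume
    from .pipeline import write_field

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.nii.gz" for k in ("insp_raw", "exp_raw", "mask_insp", "mask_exp")}
    write_volume(ph.insp_raw, paths["insp_raw"])
    write_volume(ph.exp_raw, paths["exp_raw"])
    write_mask(ph.mask_insp, paths["mask_insp"])
    write_mask(ph.mask_exp, paths["mask_exp"])
    truth_labels = ImageVolume(
        ph.truth.class_map.labels, ph.insp_raw.spacing, ph.insp_raw.origin, "raw"
    )
    paths["truth_classes"] = out / "truth_classes.nii.gz"
    write_volume(truth_labels, paths["truth_classes"])
    paths["truth_field"] = out / "truth_field.mha"
    write_field(ph.truth.field, paths["truth_field"])
    paths["landmarks"] = out / "landmarks.csv"
    write_landmarks(ph.truth.landmarks, paths["landmarks"])
    paths["spec"] = out / "phantom_spec.json"
    with open(paths["spec"], "w") as fh:
        json.dump(dataclasses.asdict(ph.truth.spec), fh, indent=2, default=str)
    return {k: str(v) for k, v in paths.items()}


def evaluate_recovery(truth: PhantomTruth, predicted: FunctionalMap) -> dict:
    """Per-class Dice and the 3×3 confusion matrix over in-mask voxels."""
    if truth.class_map.shape != predicted.shape:
        raise ValueError("grid mismatch between truth and predicted maps")
    t, p = truth.class_map.labels, predicted.labels
    classes = (LABEL_F, LABEL_LV, LABEL_NV)
    names = {LABEL_F: "F", LABEL_LV: "LV", LABEL_NV: "NV"}
    dice = {}
    for c in classes:
        ti, pi = t == c, p == c
        denom = int(ti.sum() + pi.sum())
        dice[names[c]] = 2.0 * int((ti & pi).sum()) / denom if denom else float("nan")
    confusion = np.array(
        [[int(((t == a) & (p == b)).sum()) for b in classes] for a in classes]
    )
    return {"dice": dice, "confusion": confusion, "classes": [names[c] for c in classes]}
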