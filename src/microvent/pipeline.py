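"""Study orchestration: configuration, per-subject runs, study outputs.

A study is described by a single YAML config (see :class:`StudyConfig`):
calibration anchors, registration/SVg/threshold parameters, and a subject
manifest. ``run_pipeline`` processes every subject (HU conversion →
registration → warp → SVg → ΔSVg), derives percentile thresholds from the
control-group pool, classifies every subject, and writes per-subject
volumes plus study-level thresholds JSON, biomarker CSV, histogram CSV and
a run log. Registration, the expensive stage, is cached on a content hash
of its inputs so partial reruns are cheap.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
import traceback
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .biomarkers import SubjectData, biomarker_table, group_median_histogram, subject_histogram
from .classification import classify, derive_thresholds
from .core import ImageVolume
from .io import CalibrationSpec, grey_to_hu, read_landmarks, read_mask, read_volume, write_mask, write_volume
from .registration import DeformationField, demons_register, warp
from .ventilation import SvgConstants, svg_map, ventilation_map


class _Cfg(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationCfg(_Cfg):
    raw_air: float
    raw_water: float
    hu_air: float = -1000.0
    hu_water: float = 0.0


class SvgCfg(_Cfg):
    sv_tissue: float = 0.939
    hu_floor: float = -990.0


class RegistrationCfg(_Cfg):
    levels: int = 4
    iterations: list[int] = Field(default_factory=lambda: [100, 100, 50, 25])
    smoothing_sigma: float = 1.5


class ThresholdCfg(_Cfg):
    p_alpha: float = 5.0
    p_beta: float = 25.0
    cohort_group: str = "saline"


class HistogramCfg(_Cfg):
    hu_min: float = -1000.0
    hu_max: float = 500.0
    hu_bin_width: float = 25.0

    def edges(self) -> np.ndarray:
        return np.arange(self.hu_min, self.hu_max + self.hu_bin_width, self.hu_bin_width)


class SubjectCfg(_Cfg):
    id: str
    group: str
    day: int = 0
    insp_raw: str
    exp_raw: str
    mask_insp: str
    mask_exp: str | None = None
    landmarks: str | None = None


class StudyConfig(_Cfg):
    """Validated study description; every referenced path must exist."""

    output_dir: str
    calibration: CalibrationCfg
    seed: int = 0
    spacing: float | None = None  # µm override, required for TIFF inputs
    svg: SvgCfg = SvgCfg()
    registration: RegistrationCfg = RegistrationCfg()
    thresholds: ThresholdCfg = ThresholdCfg()
    histogram: HistogramCfg = HistogramCfg()
    schemes: list[Literal["whole", "halves", "thirds"]] = Field(
        default_factory=lambda: ["whole", "halves"]
    )
    halves_axis: Literal["x", "y", "z"] = "z"
    thirds_axis: Literal["x", "y", "z"] = "y"
    subjects: list[SubjectCfg] = Field(default_factory=list)

    @field_validator("spacing")
    @classmethod
    def _positive_spacing(cls, v):
        if v is not None and v <= 0:
            raise ValueError("spacing must be positive")
        return v


def load_config(path: str) -> StudyConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return StudyConfig.model_validate(payload)


def validate_config(path: str) -> list[str]:
    """Schema + referenced-path checks; returns a list of issues (empty = valid)."""
    try:
        cfg = load_config(path)
    except Exception as exc:  # pydantic ValidationError or YAML error
        return [str(exc)]
    issues = []
    for sub in cfg.subjects:
        for field_name in ("insp_raw", "exp_raw", "mask_insp", "mask_exp", "landmarks"):
            p = getattr(sub, field_name)
            if p is not None and not Path(p).exists():
                issues.append(f"subject {sub.id}: {field_name} path does not exist: {p}")
    if not cfg.subjects:
        issues.append("no subjects in manifest")
    elif not any(s.group == cfg.thresholds.cohort_group for s in cfg.subjects):
        issues.append(f"no subject in threshold cohort group {cfg.thresholds.cohort_group!r}")
    return issues


# ---------------------------------------------------------------------------


def _hash_inputs(paths: list[str], params: dict) -> str:
    h = hashlib.sha256(json.dumps(params, sort_keys=True).encode())
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def write_field(fld: DeformationField, path: str) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(
        np.ascontiguousarray(fld.vectors.transpose(2, 1, 0, 3)), isVector=True
    )
    img.SetSpacing(fld.spacing)
    img.SetOrigin(fld.origin)
    sitk.WriteImage(img, str(path))


def read_field(path: str) -> DeformationField:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    return DeformationField(
        vectors=sitk.GetArrayFromImage(img).transpose(2, 1, 0, 3),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _process_subject(cfg: StudyConfig, sub: SubjectCfg, out: Path, log: dict) -> dict:
    cal = CalibrationSpec(**cfg.calibration.model_dump())
    consts = SvgConstants(**cfg.svg.model_dump())
    sp = (cfg.spacing,) * 3 if cfg.spacing else None
    insp = grey_to_hu(read_volume(sub.insp_raw, "raw", spacing=sp), cal)
    exp = grey_to_hu(read_volume(sub.exp_raw, "raw", spacing=sp), cal)
    mask = read_mask(sub.mask_insp, spacing=sp)
    landmarks = read_landmarks(sub.landmarks) if sub.landmarks else None

    sdir = out / "subjects" / f"{sub.id}_d{sub.day}"
    sdir.mkdir(parents=True, exist_ok=True)

    reg_params = cfg.registration.model_dump()
    cache_key = _hash_inputs([sub.insp_raw, sub.exp_raw], reg_params)
    field_path = sdir / "field.mha"
    key_path = sdir / "field.hash"
    if field_path.exists() and key_path.exists() and key_path.read_text() == cache_key:
        fld = read_field(field_path)
        report = {"cached": True}
    else:
        fld, rep = demons_register(
            insp,
            exp,
            levels=cfg.registration.levels,
            iterations_per_level=tuple(cfg.registration.iterations),
            smoothing_sigma=cfg.registration.smoothing_sigma,
            mask=mask,
            landmarks=landmarks,
        )
        write_field(fld, field_path)
        key_path.write_text(cache_key)
        report = rep.as_dict()

    exp_warped = warp(exp, fld, interpolation="linear")
    svg_insp = svg_map(insp, mask, consts)
    svg_exp = svg_map(exp_warped, mask, consts)
    dsvg = ventilation_map(svg_insp, svg_exp, mask)

    write_volume(insp, sdir / "hu_insp.nii.gz")
    write_volume(exp_warped, sdir / "hu_exp_warped.nii.gz")
    write_volume(dsvg, sdir / "dsvg.nii.gz")
    write_mask(mask, sdir / "mask_insp.nii.gz")
    with open(sdir / "registration_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)

    m = mask.data
    return {
        "cfg": sub,
        "dir": sdir,
        "hu_insp": insp,
        "mask": mask,
        "svg_insp": svg_insp,
        "svg_exp": svg_exp,
        "dsvg": dsvg,
        "pools": (svg_insp.data[m], svg_exp.data[m], dsvg.data[m]),
    }


def run_pipeline(cfg: StudyConfig) -> dict:
    """Run the full study; returns a summary dict (also written as run_log.json)."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg.model_dump()))

    log: dict = {
        "microvent_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "completed": [],
        "failed": {},
    }
    processed = {}
    for sub in cfg.subjects:
        try:
            processed[sub.id] = _process_subject(cfg, sub, out, log)
            log["completed"].append(sub.id)
        except Exception as exc:
            log["failed"][sub.id] = f"{type(exc).__name__}: {exc}"
            log.setdefault("tracebacks", {})[sub.id] = traceback.format_exc()

    cohort = [
        p for p in processed.values() if p["cfg"].group == cfg.thresholds.cohort_group
    ]
    if cohort:
        thr = derive_thresholds(
            [p["pools"][0] for p in cohort],
            [p["pools"][1] for p in cohort],
            [p["pools"][2] for p in cohort],
            p_alpha=cfg.thresholds.p_alpha,
            p_beta=cfg.thresholds.p_beta,
            cohort_id=cfg.thresholds.cohort_group,
        )
        thr.to_json(out / "thresholds.json")

        subjects_data, hist_rows, groups = [], {}, {}
        edges = cfg.histogram.edges()
        for p in processed.values():
            fmap = classify(p["svg_insp"], p["svg_exp"], p["dsvg"], thr, p["mask"])
            labels_vol = ImageVolume(
                fmap.labels, p["mask"].spacing, p["mask"].origin, "raw"
            )
            write_volume(labels_vol, p["dir"] / "functional_map.nii.gz")
            with open(p["dir"] / "functional_map_legend.json", "w") as fh:
                json.dump({"0": "outside", "1": "F", "2": "LV", "3": "NV"}, fh)
            subjects_data.append(
                SubjectData(
                    subject=p["cfg"].id,
                    day=p["cfg"].day,
                    hu_insp=p["hu_insp"],
                    dsvg=p["dsvg"],
                    fmap=fmap,
                    mask=p["mask"],
                )
            )
            hist_rows[p["cfg"].id] = subject_histogram(p["hu_insp"], p["mask"], edges)
            groups.setdefault(p["cfg"].group, []).append(hist_rows[p["cfg"].id])

        table = biomarker_table(
            subjects_data,
            schemes=tuple(cfg.schemes),
            axes={"halves": cfg.halves_axis, "thirds": cfg.thirds_axis},
        )
        table.to_csv(out / "biomarkers.csv", index=False)

        hist_df = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:]}
            | {f"subject_{sid}": h for sid, h in hist_rows.items()}
            | {f"group_median_{g}": group_median_histogram(rows) for g, rows in groups.items()}
        )
        hist_df.to_csv(out / "hu_histograms.csv", index=False)

    log["n_completed"] = len(log["completed"])
    log["n_failed"] = len(log["failed"])
    log["wall_time_s"] = round(time.time() - t0, 2)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return log
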