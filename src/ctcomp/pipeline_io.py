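"""End-to-end desk-scale pipeline: DICOM in, per-subject reports out.

Mirrors a deployed opportunistic-screening workflow at directory scale:
read a calibrated CT slice and its compartment masks, quantify body
composition, estimate muscle age when a fitted model and subject metadata
are available, and render machine- and human-readable reports.  Cases are
isolated — one corrupt input never aborts the batch — and the run summary
reports the success fraction and per-stage timing statistics.  Timings are
logged, never asserted.
"""

from __future__ import annotations

import json
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bodycomp import (
    DEFAULT_WINDOWS,
    BodyCompositionResult,
    CompartmentMasks,
    CTSlice,
    HUWindows,
    SubjectRecord,
    ValidationError,
    classify_muscle_pixels,
    quantify,
    result_to_row,
    save_quality_map,
    RESULT_CSV_COLUMNS,
)
from .muscleage import MuscleAgeEstimate, MuscleAgeModel, estimate_muscle_age
from .phantom import read_mask_png

logger = logging.getLogger("ctcomp")

__all__ = [
    "PipelineConfig",
    "SubjectReport",
    "RunSummary",
    "read_ct_dicom",
    "run_pipeline",
    "render_report",
]

CONFIG_SCHEMA_VERSION = 1


class DicomReadError(ValueError):
    """The DICOM file lacks tags required for calibrated quantification."""


@dataclass
class PipelineConfig:
    """Run configuration; all defaults reproduce the published constants."""

    windows: HUWindows = field(default_factory=HUWindows)
    model_paths: dict[str, str] = field(default_factory=dict)  # sex -> model JSON
    display_clamp: tuple[float, float] = (20.0, 90.0)
    out_dir: str = "ctcomp_out"
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = CONFIG_SCHEMA_VERSION

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a plain-text ``key = value`` config file.

        Window keys: ``window_nama = 30 150`` etc.; model keys:
        ``model_male = path.json``; everything else maps to plain fields.
        """
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"unparseable config line: {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            kv[key] = value

        version = int(kv.pop("schema_version", CONFIG_SCHEMA_VERSION))
        if version != CONFIG_SCHEMA_VERSION:
            raise ValidationError(f"unsupported config schema version {version}")

        def window(key: str, default: tuple[int, int]) -> tuple[int, int]:
            if key in kv:
                lo, hi = kv.pop(key).split()
                return int(lo), int(hi)
            return default

        d = DEFAULT_WINDOWS
        windows = HUWindows(
            nama=window("window_nama", d.nama),
            lama=window("window_lama", d.lama),
            imat=window("window_imat", d.imat),
            fat=window("window_fat", d.fat),
        )
        model_paths = {
            sex: kv.pop(f"model_{sex}") for sex in ("male", "female")
            if f"model_{sex}" in kv
        }
        clamp = kv.pop("display_clamp", None)
        display_clamp = tuple(float(x) for x in clamp.split()) if clamp else (20.0, 90.0)
        cfg = cls(
            windows=windows,
            model_paths=model_paths,
            display_clamp=display_clamp,  # type: ignore[arg-type]
            out_dir=kv.pop("out_dir", "ctcomp_out"),
            seed=int(kv.pop("seed", 0)),
            log_level=kv.pop("log_level", "INFO"),
            schema_version=version,
        )
        if kv:
            raise ValidationError(f"unknown config keys: {sorted(kv)}")
        return cfg


@dataclass
class SubjectReport:
    """Everything the pipeline produced (or failed to produce) for one case."""

    case_id: str
    subject: Optional[SubjectRecord] = None
    result: Optional[BodyCompositionResult] = None
    muscle_age: Optional[MuscleAgeEstimate] = None
    quality_map_path: Optional[str] = None
    timings_s: dict[str, float] = field(default_factory=dict)
    status: str = "success"          # "success" | "failed"
    failure_reason: Optional[str] = None
    missing_fields: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "subject": None if self.subject is None else {
                "subject_id": self.subject.subject_id,
                "age_years": self.subject.age_years,
                "sex": self.subject.sex,
                "height_cm": self.subject.height_cm,
                "weight_kg": self.subject.weight_kg,
            },
            "result": None if self.result is None else self.result.as_dict(),
            "muscle_age": None if self.muscle_age is None else self.muscle_age.as_dict(),
            "quality_map_path": self.quality_map_path,
            "timings_s": self.timings_s,
            "status": self.status,
            "failure_reason": self.failure_reason,
            "missing_fields": self.missing_fields,
        }


@dataclass
class RunSummary:
    n_cases: int
    n_success: int
    n_failed: int
    success_rate: float
    mean_case_time_s: float

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases, "n_success": self.n_success,
            "n_failed": self.n_failed, "success_rate": self.success_rate,
            "mean_case_time_s": self.mean_case_time_s,
        }


# ---------------------------------------------------------------------------
# DICOM input
# ---------------------------------------------------------------------------

def read_ct_dicom(path) -> CTSlice:
    """Read a single-frame CT DICOM into a calibrated HU slice.

    HU = stored * RescaleSlope + RescaleIntercept.  PixelSpacing and the
    rescale tags are mandatory; height/weight are optional and, when absent,
    flagged on the subject record (``None``) rather than defaulted — this
    enables the standalone muscle-age path where BMI-derived outputs are
    reported as missing.
    """
    import pydicom

    ds = pydicom.dcmread(path)
    for tag in ("PixelSpacing", "RescaleSlope", "RescaleIntercept"):
        if getattr(ds, tag, None) is None:
            raise DicomReadError(f"required DICOM tag {tag} missing in {path}")
    stored = ds.pixel_array.astype(float)
    hu = stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))

    def opt(tag):
        value = getattr(ds, tag, None)
        return None if value in (None, "") else value

    sex_code = opt("PatientSex")
    sex = {"M": "male", "F": "female"}.get(sex_code) if sex_code else None
    age_raw = opt("PatientAge")
    age = float(age_raw.rstrip("YyDdWwMm")) if age_raw else None
    size_m = opt("PatientSize")
    weight = opt("PatientWeight")
    subject = SubjectRecord(
        subject_id=str(opt("PatientID") or Path(path).stem),
        age_years=age,
        sex=sex,
        height_cm=None if size_m is None else float(size_m) * 100.0,
        weight_kg=None if weight is None else float(weight),
    )
    return CTSlice(hu=hu, pixel_spacing_mm=spacing, subject=subject)


# ---------------------------------------------------------------------------
# Batch execution
# ---------------------------------------------------------------------------

def _process_case(
    case_id: str,
    dicom_path,
    mask_path,
    config: PipelineConfig,
    models: dict[str, MuscleAgeModel],
    out_dir: Path,
) -> SubjectReport:
    report = SubjectReport(case_id=case_id)
    timings = report.timings_s

    t0 = time.perf_counter()
    slc = read_ct_dicom(dicom_path)
    masks = read_mask_png(mask_path)
    timings["read"] = time.perf_counter() - t0
    report.subject = slc.subject

    t0 = time.perf_counter()
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # missing-BMI warning becomes a report flag
        report.result = quantify(slc, masks, config.windows)
    timings["quantify"] = time.perf_counter() - t0
    if report.result.bmi is None:
        report.missing_fields += ["bmi", "sma_over_bmi"]

    t0 = time.perf_counter()
    cls = classify_muscle_pixels(slc, masks, config.windows)
    map_path = out_dir / f"{case_id}_quality_map.png"
    save_quality_map(slc, cls, map_path)
    report.quality_map_path = str(map_path)
    timings["quality_map"] = time.perf_counter() - t0

    sex = slc.subject.sex if slc.subject else None
    if sex in models and report.result.sma_over_bmi is not None:
        t0 = time.perf_counter()
        report.muscle_age = estimate_muscle_age(models[sex], report.result.sma_over_bmi)
        timings["muscle_age"] = time.perf_counter() - t0
    elif report.result.sma_over_bmi is None:
        report.missing_fields.append("muscle_age")
    return report


def run_pipeline(
    config: PipelineConfig,
    cases: Sequence[tuple[str, str]] | Sequence[tuple[str, str, str]],
) -> tuple[list[SubjectReport], RunSummary]:
    """Process a batch of (dicom_path, mask_path[, case_id]) cases.

    Per-case failures are captured as ``status='failed'`` with the reason;
    the rest of the batch completes.  Numeric outputs are deterministic for
    fixed config + inputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models = {
        sex: MuscleAgeModel.from_json(path)
        for sex, path in config.model_paths.items()
    }

    reports: list[SubjectReport] = []
    case_times = []
    for i, case in enumerate(cases):
        dicom_path, mask_path = case[0], case[1]
        case_id = case[2] if len(case) > 2 else Path(dicom_path).stem
        t0 = time.perf_counter()
        try:
            report = _process_case(case_id, dicom_path, mask_path, config, models, out_dir)
        except Exception as exc:  # noqa: BLE001 — per-case isolation is the contract
            logger.warning("case %s failed: %s", case_id, exc)
            logger.debug("%s", traceback.format_exc())
            report = SubjectReport(
                case_id=case_id, status="failed",
                failure_reason=f"{type(exc).__name__}: {exc}",
            )
        case_times.append(time.perf_counter() - t0)
        reports.append(report)

    n_success = sum(r.status == "success" for r in reports)
    summary = RunSummary(
        n_cases=len(reports),
        n_success=n_success,
        n_failed=len(reports) - n_success,
        success_rate=n_success / len(reports) if reports else 0.0,
        mean_case_time_s=float(np.mean(case_times)) if case_times else 0.0,
    )
    logger.info("pipeline run: %d/%d cases succeeded", n_success, len(reports))

    rows = [
        result_to_row(r.subject, r.result)
        for r in reports if r.result is not None
    ]
    if rows:
        pd.DataFrame(rows, columns=RESULT_CSV_COLUMNS).to_csv(
            out_dir / "results.csv", index=False
        )
    (out_dir / "run_summary.json").write_text(json.dumps(summary.as_dict(), indent=2))
    return reports, summary


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(report: SubjectReport, path, history: Optional[pd.DataFrame] = None) -> dict:
    """Write machine (JSON) and human (text) report files for one case.

    ``history`` is an optional table with columns (date, sma_cm2) of prior
    results; the serial-analysis section lists the series in chronological
    order with the current value appended.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = report.as_dict()

    if history is not None:
        hist = history.sort_values("date")
        series = [
            {"date": str(d), "sma_cm2": float(v)}
            for d, v in zip(hist["date"], hist["sma_cm2"])
        ]
        if report.result is not None:
            series.append({"date": "current", "sma_cm2": report.result.sma_cm2})
        payload["serial_analysis"] = series

    path.with_suffix(".json").write_text(json.dumps(payload, indent=2))

    lines = [f"Body composition report — case {report.case_id}", "=" * 46]
    subj = report.subject
    if subj is not None:
        lines.append(f"Subject: {subj.subject_id}  sex={subj.sex}  age={subj.age_years}")
        lines.append(f"Height: {subj.height_cm if subj.height_cm is not None else 'absent'} cm  "
                     f"Weight: {subj.weight_kg if subj.weight_kg is not None else 'absent'} kg")
    res = report.result
    if res is not None:
        lines.append(f"SMA  {res.sma_cm2:.1f} cm^2   (NAMA {res.nama_cm2:.1f}, LAMA {res.lama_cm2:.1f})")
        lines.append(f"IMAT {res.imat_cm2:.1f} cm^2   VFAT {res.vfat_cm2:.1f} cm^2   SFAT {res.sfat_cm2:.1f} cm^2")
        lines.append("BMI  absent — BMI-derived fields not computed" if res.bmi is None
                     else f"BMI  {res.bmi:.1f} kg/m^2   SMA/BMI {res.sma_over_bmi:.2f}")
    ma = report.muscle_age
    if ma is not None:
        clamp_note = " (clamped for display)" if ma.clamped else ""
        lines.append(f"Muscle age: {ma.display_age_years:.0f} ± {ma.se_years:.1f} y{clamp_note}")
    if report.missing_fields:
        lines.append(f"Missing fields: {', '.join(report.missing_fields)}")
    if "serial_analysis" in payload:
        lines.append("Serial analysis (SMA cm^2): " + " -> ".join(
            f"{p['date']}: {p['sma_cm2']:.1f}" for p in payload["serial_analysis"]
        ))
    lines.append(f"Status: {report.status}"
                 + (f" ({report.failure_reason})" if report.failure_reason else ""))
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return payload
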