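"""HU-window tissue classification and per-subject body-composition metrics.

At the level of the third lumbar vertebra (L3), a single axial CT slice is
conventionally used to quantify body composition.  Given a calibrated
Hounsfield-unit (HU) image and compartment masks (total abdominal muscle
boundary, visceral cavity, subcutaneous region), pixels are classified by
attenuation windows:

* NAMA — normal-attenuation muscle, HU in [+30, +150] (healthy muscle),
* LAMA — low-attenuation muscle, HU in [-29, +29] (fat-infiltrated muscle),
* IMAT — inter-/intramuscular adipose tissue, HU in [-190, -30], inside the
  muscle boundary,
* VFAT / SFAT — fat-window pixels ([-190, -30]) inside the visceral /
  subcutaneous compartments.

Skeletal muscle area SMA = NAMA + LAMA, and the BMI-adjusted muscle index
SMA/BMI (cm^2 * m^2 / kg) is the sarcopenia screening metric used downstream
for muscle-age estimation.

HU values are rounded to the nearest integer (ties away from zero) before
window tests: CT attenuation is integer-quantized at acquisition, and integer
semantics make the printed adjacent window bounds (-30 fat / -29 LAMA)
exhaustive.  Muscle pixels outside every window go to an explicit
``unclassified`` bucket so the four classes always partition the muscle mask.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

logger = logging.getLogger("ctcomp")

__all__ = [
    "AlignmentError",
    "ValidationError",
    "SubjectRecord",
    "CTSlice",
    "CompartmentMasks",
    "HUWindows",
    "MuscleClassification",
    "BodyCompositionResult",
    "RESULT_CSV_COLUMNS",
    "round_hu",
    "classify_muscle_pixels",
    "fat_areas",
    "pixels_to_area",
    "compute_bmi",
    "quantify",
    "result_to_row",
    "quality_map_rgb",
    "save_quality_map",
]


class AlignmentError(ValueError):
    """Masks and image grids do not share a shape."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


def round_hu(hu: np.ndarray) -> np.ndarray:
    """Round HU to the nearest integer with ties away from zero.

    ``np.round`` rounds half to even; CT convention (and the closed integer
    windows used here) wants 29.5 -> 30 and -29.5 -> -30.
    """
    hu = np.asarray(hu, dtype=float)
    return np.trunc(hu + np.copysign(0.5, hu))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """Demographics for one subject; height/weight may be absent.

    ``height_cm``/``weight_kg`` are ``None`` when the source metadata lacked
    them, which disables BMI-derived outputs downstream (never silently 0).
    """

    subject_id: str
    age_years: Optional[float] = None
    sex: Optional[str] = None          # "male" | "female"
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("height_cm", "weight_kg"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if self.age_years is not None and not self.age_years > 0:
            raise ValidationError(f"age_years must be > 0, got {self.age_years}")

    @property
    def bmi(self) -> Optional[float]:
        if self.height_cm is None or self.weight_kg is None:
            return None
        return compute_bmi(self.height_cm, self.weight_kg)


@dataclass
class CTSlice:
    """A calibrated axial CT slice: HU grid + physical pixel spacing."""

    hu: np.ndarray                      # 2-D, Hounsfield units
    pixel_spacing_mm: tuple[float, float]   # (row, col) spacing
    subject: Optional[SubjectRecord] = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 2 or self.hu.size == 0:
            raise ValidationError("hu must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.hu)):
            raise ValidationError("hu contains non-finite values")
        sy, sx = self.pixel_spacing_mm
        if not (sy > 0 and sx > 0):
            raise ValidationError(f"pixel spacing must be > 0, got {self.pixel_spacing_mm}")

    @property
    def pixel_area_cm2(self) -> float:
        sy, sx = self.pixel_spacing_mm
        return sy * sx / 100.0


@dataclass
class CompartmentMasks:
    """Boolean compartment masks aligned to a CT grid.

    ``muscle`` is the total abdominal muscle boundary, ``visceral`` the
    visceral cavity, ``subcutaneous`` the region between muscle and skin.
    Muscle must be disjoint from the other two.
    """

    muscle: np.ndarray
    visceral: np.ndarray
    subcutaneous: np.ndarray

    def __post_init__(self) -> None:
        self.muscle = np.asarray(self.muscle, dtype=bool)
        self.visceral = np.asarray(self.visceral, dtype=bool)
        self.subcutaneous = np.asarray(self.subcutaneous, dtype=bool)
        if not (self.muscle.shape == self.visceral.shape == self.subcutaneous.shape):
            raise AlignmentError("compartment masks must share one shape")
        if np.any(self.muscle & self.visceral):
            raise ValidationError("muscle and visceral masks overlap")
        if np.any(self.muscle & self.subcutaneous):
            raise ValidationError("muscle and subcutaneous masks overlap")

    def check_aligned(self, slc: CTSlice) -> None:
        if self.muscle.shape != slc.hu.shape:
            raise AlignmentError(
                f"mask shape {self.muscle.shape} != image shape {slc.hu.shape}"
            )


@dataclass(frozen=True)
class HUWindows:
    """Closed HU intervals for tissue classification (defaults as published)."""

    nama: tuple[int, int] = (30, 150)
    lama: tuple[int, int] = (-29, 29)
    imat: tuple[int, int] = (-190, -30)
    fat: tuple[int, int] = (-190, -30)

    def __post_init__(self) -> None:
        for name in ("nama", "lama", "imat", "fat"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"window {name} has lower bound > upper bound")
        if not (self.nama[0] > self.lama[1] or self.lama[0] > self.nama[1]):
            raise ValidationError("nama and lama windows must be disjoint")


DEFAULT_WINDOWS = HUWindows()


@dataclass
class MuscleClassification:
    """Per-class boolean grids and pixel counts for the muscle compartment."""

    nama: np.ndarray
    lama: np.ndarray
    imat: np.ndarray
    unclassified: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            "nama": int(self.nama.sum()),
            "lama": int(self.lama.sum()),
            "imat": int(self.imat.sum()),
            "unclassified": int(self.unclassified.sum()),
        }


@dataclass
class BodyCompositionResult:
    """Areas (cm^2) and derived indices for one subject at L3.

    Invariants: sma = nama + lama exactly;
    nama + lama + imat + unclassified = total muscle-boundary area exactly.
    ``bmi``/``sma_over_bmi`` are ``None`` when height or weight is absent.
    """

    nama_cm2: float
    lama_cm2: float
    imat_cm2: float
    sma_cm2: float
    vfat_cm2: float
    sfat_cm2: float
    unclassified_muscle_cm2: float = 0.0
    bmi: Optional[float] = None
    sma_over_bmi: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "nama_cm2": self.nama_cm2,
            "lama_cm2": self.lama_cm2,
            "imat_cm2": self.imat_cm2,
            "sma_cm2": self.sma_cm2,
            "vfat_cm2": self.vfat_cm2,
            "sfat_cm2": self.sfat_cm2,
            "unclassified_muscle_cm2": self.unclassified_muscle_cm2,
            "bmi": self.bmi,
            "sma_over_bmi": self.sma_over_bmi,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _in_window(hu_int: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    return (hu_int >= lo) & (hu_int <= hi)


def classify_muscle_pixels(
    slc: CTSlice,
    masks: CompartmentMasks,
    windows: HUWindows = DEFAULT_WINDOWS,
) -> MuscleClassification:
    """Assign every muscle-boundary pixel to exactly one attenuation class.

    HU is rounded to the nearest integer (ties away from zero) before the
    closed-interval tests.  Pixels outside the muscle mask are untouched;
    muscle pixels outside all three windows land in ``unclassified``.
    """
    masks.check_aligned(slc)
    hu_int = round_hu(slc.hu)
    m = masks.muscle
    nama = m & _in_window(hu_int, windows.nama)
    lama = m & _in_window(hu_int, windows.lama)
    imat = m & _in_window(hu_int, windows.imat)
    unclassified = m & ~(nama | lama | imat)
    return MuscleClassification(nama=nama, lama=lama, imat=imat, unclassified=unclassified)


def fat_areas(
    slc: CTSlice,
    masks: CompartmentMasks,
    windows: HUWindows = DEFAULT_WINDOWS,
) -> tuple[int, int]:
    """Count fat-window pixels in the visceral and subcutaneous compartments."""
    masks.check_aligned(slc)
    hu_int = round_hu(slc.hu)
    fat = _in_window(hu_int, windows.fat)
    vfat_px = int((masks.visceral & fat).sum())
    sfat_px = int((masks.subcutaneous & fat).sum())
    return vfat_px, sfat_px


def pixels_to_area(count: int, pixel_spacing_mm: tuple[float, float]) -> float:
    """Convert a pixel count to an area in cm^2 (spacing in mm per axis)."""
    if count < 0:
        raise ValidationError(f"pixel count must be >= 0, got {count}")
    sy, sx = pixel_spacing_mm
    if not (sy > 0 and sx > 0):
        raise ValidationError(f"pixel spacing must be > 0, got {pixel_spacing_mm}")
    return count * sy * sx / 100.0


def compute_bmi(height_cm: float, weight_kg: float) -> float:
    """Body-mass index, kg/m^2, at full precision (rounding is display-only)."""
    if not (height_cm > 0 and weight_kg > 0):
        raise ValidationError(
            f"height and weight must be > 0, got {height_cm}, {weight_kg}"
        )
    h_m = height_cm / 100.0
    return weight_kg / (h_m * h_m)


def quantify(
    slc: CTSlice,
    masks: CompartmentMasks,
    windows: HUWindows = DEFAULT_WINDOWS,
) -> BodyCompositionResult:
    """Full body-composition quantification of one slice.

    SMA = NAMA + LAMA; SMA/BMI requires subject height and weight — when
    either is absent the BMI-derived fields are ``None`` and a warning is
    emitted, never silent zeros.
    """
    cls = classify_muscle_pixels(slc, masks, windows)
    vfat_px, sfat_px = fat_areas(slc, masks, windows)
    area = lambda n: pixels_to_area(n, slc.pixel_spacing_mm)  # noqa: E731
    counts = cls.counts
    nama = area(counts["nama"])
    lama = area(counts["lama"])
    imat = area(counts["imat"])
    unclassified = area(counts["unclassified"])
    sma = nama + lama

    bmi = sma_over_bmi = None
    subj = slc.subject
    if subj is not None and subj.height_cm is not None and subj.weight_kg is not None:
        bmi = compute_bmi(subj.height_cm, subj.weight_kg)
        sma_over_bmi = sma / bmi
    else:
        warnings.warn(
            "subject height/weight absent: BMI-derived fields reported as missing",
            stacklevel=2,
        )

    return BodyCompositionResult(
        nama_cm2=nama,
        lama_cm2=lama,
        imat_cm2=imat,
        sma_cm2=sma,
        vfat_cm2=area(vfat_px),
        sfat_cm2=area(sfat_px),
        unclassified_muscle_cm2=unclassified,
        bmi=bmi,
        sma_over_bmi=sma_over_bmi,
    )


# ---------------------------------------------------------------------------
# Tabular / image output
# ---------------------------------------------------------------------------

RESULT_CSV_COLUMNS = [
    "subject_id", "age", "sex", "height_cm", "weight_kg", "bmi",
    "nama_cm2", "lama_cm2", "imat_cm2", "sma_cm2", "sma_over_bmi",
    "vfat_cm2", "sfat_cm2", "unclassified_muscle_cm2",
]


def result_to_row(subject: Optional[SubjectRecord], result: BodyCompositionResult) -> dict:
    """One CSV row per subject, fixed column order (see RESULT_CSV_COLUMNS)."""
    subj = subject or SubjectRecord(subject_id="")
    return {
        "subject_id": subj.subject_id,
        "age": subj.age_years,
        "sex": subj.sex,
        "height_cm": subj.height_cm,
        "weight_kg": subj.weight_kg,
        "bmi": result.bmi,
        "nama_cm2": result.nama_cm2,
        "lama_cm2": result.lama_cm2,
        "imat_cm2": result.imat_cm2,
        "sma_cm2": result.sma_cm2,
        "sma_over_bmi": result.sma_over_bmi,
        "vfat_cm2": result.vfat_cm2,
        "sfat_cm2": result.sfat_cm2,
        "unclassified_muscle_cm2": result.unclassified_muscle_cm2,
    }


# muscle quality map overlay colors (RGB)
_QUALITY_COLORS = {
    "nama": (214, 39, 40),    # red: healthy muscle
    "lama": (255, 215, 0),    # yellow: fat-infiltrated muscle
    "imat": (44, 160, 44),    # green: intramuscular fat
}


def quality_map_rgb(slc: CTSlice, cls: MuscleClassification) -> np.ndarray:
    """Color-coded muscle quality map over a soft-tissue grayscale window."""
    lo, hi = -150.0, 250.0
    gray = np.clip((slc.hu - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.repeat((gray * 255).astype(np.uint8)[..., None], 3, axis=2)
    for name, color in _QUALITY_COLORS.items():
        rgb[getattr(cls, name)] = color
    return rgb


def save_quality_map(slc: CTSlice, cls: MuscleClassification, path) -> None:
    from PIL import Image

    Image.fromarray(quality_map_rgb(slc, cls), mode="RGB").save(path)
    logger.info("wrote muscle quality map to %s", path)
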