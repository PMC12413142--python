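"""Synthetic CT phantoms and cohorts with exact ground truth.

Real opportunistic-screening inputs (scanner slices, trained segmentations,
an 11,845-subject reference population) are not redistributable, so every
downstream stage here is exercised against synthetic data whose ground truth
is known by construction:

* ``gen_phantom`` — an abdominal-slice phantom built from concentric shapes
  (body ellipse, subcutaneous rim, annular muscle ring, visceral interior).
  Each compartment pixel is assigned a tissue class and sampled at least
  ``hu_margin`` HU inside its class window, with truncated Gaussian noise
  bounded at 4 SD; ``hu_margin > 4 * noise_sd_hu`` therefore guarantees that
  no pixel can cross a window boundary and the returned ground-truth areas
  are exact pixel counts.
* ``gen_reference_cohort`` — subject tables with a linear age trend in
  SMA/BMI plus (optionally heteroscedastic) Gaussian noise, for fitting the
  muscle-age regression.
* ``gen_checkup_cohort`` — subject-level metric tables drawn from per
  sex-and-age-decade group means/SDs, emulating a health check-up cohort
  whose published summary statistics are the generative parameters.

All randomness flows through explicit integer seeds; there is no global
random state, and identical inputs reproduce bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

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
    compute_bmi,
    pixels_to_area,
)

logger = logging.getLogger("ctcomp")

__all__ = [
    "GeometryError",
    "HUOverflowError",
    "PhantomSpec",
    "ReferenceCohortParams",
    "gen_phantom",
    "gen_reference_cohort",
    "gen_checkup_cohort",
    "write_phantom_dicom",
    "write_mask_png",
    "read_mask_png",
    "masks_to_labels",
    "labels_to_masks",
    "AGE_BANDS",
]


class GeometryError(ValueError):
    """Requested compartments do not fit the phantom geometry."""


class HUOverflowError(OverflowError):
    """HU values exceed the range representable as stored DICOM pixels."""


# ---------------------------------------------------------------------------
# Phantom slices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic L3-like slice.

    Geometry is a body ellipse (semi-axes ``body_axes_mm``) containing a
    circular muscle annulus (``muscle_ring`` inner/outer radii); inside the
    ring is the visceral cavity, between ring and skin the subcutaneous
    region.  ``class_fractions`` give the target NAMA/LAMA/IMAT fractions of
    muscle-ring pixels (remainder is deliberately out-of-window,
    "unclassified").  ``vfat_target_cm2``/``sfat_target_cm2`` request fat
    areas realized by sampling that many compartment pixels in the fat
    window.
    """

    image_size: int = 256
    pixel_spacing_mm: float = 1.0
    body_axes_mm: tuple[float, float] = (110.0, 90.0)
    muscle_ring: tuple[float, float] = (45.0, 65.0)
    class_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)
    vfat_target_cm2: float = 40.0
    sfat_target_cm2: float = 60.0
    hu_margin: float = 10.0
    noise_sd_hu: float = 2.0
    subject: SubjectRecord = field(
        default_factory=lambda: SubjectRecord(
            subject_id="phantom", age_years=50.0, sex="female",
            height_cm=165.0, weight_kg=60.0,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValidationError("image_size too small")
        if not self.pixel_spacing_mm > 0:
            raise ValidationError("pixel_spacing_mm must be > 0")
        f = self.class_fractions
        if len(f) != 3 or any(not (0.0 <= x <= 1.0) for x in f):
            raise ValidationError("class_fractions must each lie in [0, 1]")
        if sum(f) > 1.0 + 1e-12:
            raise ValidationError(f"class_fractions sum to {sum(f)} > 1")
        if self.vfat_target_cm2 < 0 or self.sfat_target_cm2 < 0:
            raise ValidationError("fat targets must be >= 0")
        if not self.hu_margin > 4.0 * self.noise_sd_hu:
            raise ValidationError(
                "hu_margin must exceed 4 * noise_sd_hu so noise cannot cross a window"
            )
        r_in, r_out = self.muscle_ring
        if not (0 < r_in < r_out):
            raise GeometryError(f"muscle ring radii must satisfy 0 < inner < outer, got {self.muscle_ring}")
        if r_out >= min(self.body_axes_mm):
            raise GeometryError(
                f"muscle ring (outer {r_out} mm) does not fit inside body "
                f"semi-axes {self.body_axes_mm}"
            )
        half_fov = self.image_size * self.pixel_spacing_mm / 2.0
        if max(self.body_axes_mm) >= half_fov:
            raise GeometryError("body ellipse does not fit in the field of view")


_AIR_HU = -1000.0
# soft-tissue filler for non-fat pixels of the fat compartments; must stay
# clear of the fat window's upper bound (-30) by more than any noise excursion
_SOFT_TISSUE_RANGE = (0.0, 40.0)


def _sample_in(rng: np.random.Generator, n: int, lo: float, hi: float,
               margin: float, noise_sd: float) -> np.ndarray:
    """Uniform draw in the window shrunk by ``margin``, plus truncated noise.

    Noise is hard-clipped at +/- 4 SD; with margin > 4 SD the final value is
    strictly inside (lo, hi), so integer rounding stays within [lo, hi].
    """
    if hi - lo <= 2 * margin:
        raise ValidationError(f"window [{lo}, {hi}] narrower than twice the margin {margin}")
    base = rng.uniform(lo + margin, hi - margin, size=n)
    if noise_sd > 0:
        noise = np.clip(rng.normal(0.0, noise_sd, size=n), -4 * noise_sd, 4 * noise_sd)
    else:
        noise = 0.0
    return base + noise


def gen_phantom(
    spec: PhantomSpec,
    windows: HUWindows = DEFAULT_WINDOWS,
) -> tuple[CTSlice, CompartmentMasks, BodyCompositionResult]:
    """Generate one phantom slice, its masks, and its exact ground truth.

    The HU grid is integer-valued (CT attenuation is integer-quantized at
    acquisition; this also makes DICOM round-trips exact).  Quantifying the
    returned slice with the returned masks under the same windows reproduces
    ``ground_truth`` bit-exactly.
    """
    n = spec.image_size
    s = spec.pixel_spacing_mm
    rng = np.random.default_rng(spec.seed)

    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    x = (xx - c) * s
    y = (yy - c) * s
    ax, ay = spec.body_axes_mm
    body = (x / ax) ** 2 + (y / ay) ** 2 <= 1.0
    r = np.hypot(x, y)
    r_in, r_out = spec.muscle_ring
    muscle = body & (r >= r_in) & (r <= r_out)
    visceral = body & (r < r_in)
    subcutaneous = body & (r > r_out)
    masks = CompartmentMasks(muscle=muscle, visceral=visceral, subcutaneous=subcutaneous)

    hu = np.full((n, n), _AIR_HU)
    if spec.noise_sd_hu > 0:
        bg = ~body
        hu[bg] += np.clip(
            rng.normal(0.0, spec.noise_sd_hu, size=int(bg.sum())),
            -4 * spec.noise_sd_hu, 4 * spec.noise_sd_hu,
        )

    # --- muscle ring: NAMA / LAMA / IMAT / unclassified ---
    m_idx = np.flatnonzero(muscle.ravel())
    n_m = m_idx.size
    fr = spec.class_fractions
    n_nama = int(round(fr[0] * n_m))
    n_lama = int(round(fr[1] * n_m))
    n_imat = int(round(fr[2] * n_m))
    # per-class rounding can overshoot the pixel budget by 1-2; trim smallest last
    while n_nama + n_lama + n_imat > n_m:
        if n_imat > 0:
            n_imat -= 1
        elif n_lama > 0:
            n_lama -= 1
        else:
            n_nama -= 1
    perm = rng.permutation(m_idx)
    groups = {
        "nama": (perm[:n_nama], windows.nama),
        "lama": (perm[n_nama:n_nama + n_lama], windows.lama),
        "imat": (perm[n_nama + n_lama:n_nama + n_lama + n_imat], windows.imat),
    }
    flat = hu.ravel()
    for _, (idx, (lo, hi)) in groups.items():
        flat[idx] = _sample_in(rng, idx.size, lo, hi, spec.hu_margin, spec.noise_sd_hu)
    uncls_idx = perm[n_nama + n_lama + n_imat:]
    if uncls_idx.size:
        # above the NAMA window: bone-like attenuation, outside every window
        lo = windows.nama[1] + spec.hu_margin
        flat[uncls_idx] = _sample_in(
            rng, uncls_idx.size, lo, lo + 200.0, spec.hu_margin, spec.noise_sd_hu
        )

    # --- fat compartments ---
    def fill_fat(mask: np.ndarray, target_cm2: float, label: str) -> int:
        idx = np.flatnonzero(mask.ravel())
        n_fat = int(round(target_cm2 * 100.0 / (s * s)))
        if n_fat > idx.size:
            raise GeometryError(
                f"{label} target {target_cm2} cm^2 needs {n_fat} pixels but the "
                f"compartment has only {idx.size}"
            )
        perm = rng.permutation(idx)
        fat_idx, rest_idx = perm[:n_fat], perm[n_fat:]
        lo, hi = windows.fat
        flat[fat_idx] = _sample_in(rng, fat_idx.size, lo, hi, spec.hu_margin, spec.noise_sd_hu)
        st_lo, st_hi = _SOFT_TISSUE_RANGE
        if rest_idx.size:
            base = rng.uniform(st_lo, st_hi, size=rest_idx.size)
            flat[rest_idx] = base + np.clip(
                rng.normal(0.0, spec.noise_sd_hu, size=rest_idx.size),
                -4 * spec.noise_sd_hu, 4 * spec.noise_sd_hu,
            )
        return n_fat

    n_vfat = fill_fat(visceral, spec.vfat_target_cm2, "VFAT")
    n_sfat = fill_fat(subcutaneous, spec.sfat_target_cm2, "SFAT")

    hu = np.trunc(flat.reshape(n, n) + np.copysign(0.5, flat.reshape(n, n)))
    slc = CTSlice(hu=hu, pixel_spacing_mm=(s, s), subject=spec.subject)

    spacing = (s, s)
    nama_cm2 = pixels_to_area(n_nama, spacing)
    lama_cm2 = pixels_to_area(n_lama, spacing)
    subj = spec.subject
    bmi = sma_over_bmi = None
    if subj.height_cm is not None and subj.weight_kg is not None:
        bmi = compute_bmi(subj.height_cm, subj.weight_kg)
        sma_over_bmi = (nama_cm2 + lama_cm2) / bmi
    ground_truth = BodyCompositionResult(
        nama_cm2=nama_cm2,
        lama_cm2=lama_cm2,
        imat_cm2=pixels_to_area(n_imat, spacing),
        sma_cm2=nama_cm2 + lama_cm2,
        vfat_cm2=pixels_to_area(n_vfat, spacing),
        sfat_cm2=pixels_to_area(n_sfat, spacing),
        unclassified_muscle_cm2=pixels_to_area(int(uncls_idx.size), spacing),
        bmi=bmi,
        sma_over_bmi=sma_over_bmi,
    )
    return slc, masks, ground_truth


# ---------------------------------------------------------------------------
# Reference cohorts (for muscle-age fitting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceCohortParams:
    """Generative model of a reference population: SMA/BMI linear in age.

    Per sex, ``sma_over_bmi = a + b * age + eps`` with ``eps`` mean-zero
    Gaussian whose SD is ``noise_sd + noise_sd_slope * (age - age_range[0])``
    (heteroscedastic when the slope is nonzero).  Ages are uniform on
    ``age_range``.
    """

    coeffs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (8.6, -0.045), "female": (5.9, -0.028)}
    )
    noise_sd: float = 0.6
    noise_sd_slope: float = 0.0
    age_range: tuple[float, float] = (20.0, 80.0)
    n_per_sex: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_sex < 3:
            raise ValidationError(
                "n_per_sex must be >= 3 (a two-parameter line cannot be fit otherwise)"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("age_range must be increasing")
        span = hi - lo
        if self.noise_sd < 0 or self.noise_sd + min(0.0, self.noise_sd_slope) * span < 0:
            raise ValidationError("noise SD must stay positive over the age range")

    def sd_at(self, age: np.ndarray) -> np.ndarray:
        return self.noise_sd + self.noise_sd_slope * (np.asarray(age) - self.age_range[0])


def gen_reference_cohort(params: ReferenceCohortParams) -> pd.DataFrame:
    """Draw a subject table (age, sex, sma_over_bmi); sexes are independent."""
    rng = np.random.default_rng(params.seed)
    frames = []
    for sex in sorted(params.coeffs):
        a, b = params.coeffs[sex]
        age = rng.uniform(*params.age_range, size=params.n_per_sex)
        sd = params.sd_at(age)
        eps = rng.normal(0.0, 1.0, size=params.n_per_sex) * sd
        frames.append(pd.DataFrame({
            "age": age, "sex": sex, "sma_over_bmi": a + b * age + eps,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Check-up cohorts (from published group statistics)
# ---------------------------------------------------------------------------

AGE_BANDS = ("20-29", "30-39", "40-49", "50-59", "60-69", "70+")

_BAND_RANGES = {
    "20-29": (20.0, 30.0), "30-39": (30.0, 40.0), "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0), "60-69": (60.0, 70.0),
    # open-ended band generated on a bounded support so moments are finite
    "70+": (70.0, 80.0),
}


def gen_checkup_cohort(
    group_sizes: Mapping[tuple[str, str], int],
    group_stats: Mapping[tuple[str, str], Mapping[str, tuple[float, float]]],
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a subject-level metric table from per sex x decade group stats.

    ``group_sizes`` maps (sex, band) -> n; ``group_stats`` maps (sex, band)
    -> {metric: (mean, sd)}.  Each subject's metrics are independent normals
    at the group's mean/SD; ages are uniform within the decade band.
    """
    for (sex, band), size in group_sizes.items():
        if band not in _BAND_RANGES:
            raise ValidationError(f"unknown age band {band!r}")
        if size < 0:
            raise ValidationError(f"group size for {(sex, band)} is negative")
        if size > 0 and (sex, band) not in group_stats:
            raise ValidationError(f"group {(sex, band)} has size {size} but no statistics")
        for metric, (_, sd) in group_stats.get((sex, band), {}).items():
            if sd < 0:
                raise ValidationError(f"SD for {metric} in group {(sex, band)} is negative")

    rng = np.random.default_rng(seed)
    rows = []
    for (sex, band) in sorted(group_sizes):
        size = group_sizes[(sex, band)]
        if size == 0:
            continue
        lo, hi = _BAND_RANGES[band]
        age = rng.uniform(lo, hi, size=size)
        frame = {"sex": np.repeat(sex, size), "age": age, "age_band": np.repeat(band, size)}
        for metric, (mean, sd) in group_stats[(sex, band)].items():
            frame[metric] = rng.normal(mean, sd, size=size) if sd > 0 else np.full(size, mean)
        rows.append(pd.DataFrame(frame))
    if not rows:
        return pd.DataFrame(columns=["sex", "age", "age_band"])
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "subject_id", [f"synth-{i:05d}" for i in range(len(df))])
    return df


# ---------------------------------------------------------------------------
# DICOM + mask output
# ---------------------------------------------------------------------------

def masks_to_labels(masks: CompartmentMasks) -> np.ndarray:
    """Label image: 0 background, 1 muscle, 2 visceral, 3 subcutaneous."""
    labels = np.zeros(masks.muscle.shape, dtype=np.uint8)
    labels[masks.muscle] = 1
    labels[masks.visceral] = 2
    labels[masks.subcutaneous] = 3
    return labels


def labels_to_masks(labels: np.ndarray) -> CompartmentMasks:
    labels = np.asarray(labels)
    return CompartmentMasks(
        muscle=labels == 1, visceral=labels == 2, subcutaneous=labels == 3
    )


def write_mask_png(masks: CompartmentMasks, path) -> None:
    from PIL import Image

    Image.fromarray(masks_to_labels(masks), mode="L").save(path)


def read_mask_png(path) -> CompartmentMasks:
    from PIL import Image

    return labels_to_masks(np.asarray(Image.open(path)))


def write_phantom_dicom(
    slc: CTSlice,
    masks: Optional[CompartmentMasks],
    path,
) -> dict[str, Path]:
    """Write a single-frame CT DICOM (plus a lossless mask PNG alongside).

    Stored pixels are signed 16-bit with RescaleSlope 1 / Intercept 0, so
    read-back HU equals the written HU exactly; PatientSize (meters),
    PatientWeight (kg), PatientAge and PatientSex come from the subject
    record when present.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    hu = np.asarray(slc.hu)
    if not np.array_equal(hu, np.round(hu)):
        raise ValidationError("DICOM writer requires integer-valued HU grids")
    if hu.min() < -32768 or hu.max() > 32767:
        raise HUOverflowError(
            f"HU range [{hu.min()}, {hu.max()}] exceeds signed 16-bit storage"
        )

    path = Path(path)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.Rows, ds.Columns = hu.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    ds.RescaleType = "HU"
    ds.PixelSpacing = [f"{slc.pixel_spacing_mm[0]:g}", f"{slc.pixel_spacing_mm[1]:g}"]
    ds.PixelData = hu.astype(np.int16).tobytes()

    subj = slc.subject
    if subj is not None:
        ds.PatientID = subj.subject_id
        ds.PatientName = subj.subject_id
        if subj.height_cm is not None:
            ds.PatientSize = subj.height_cm / 100.0
        if subj.weight_kg is not None:
            ds.PatientWeight = subj.weight_kg
        if subj.age_years is not None:
            ds.PatientAge = f"{int(round(subj.age_years)):03d}Y"
        if subj.sex is not None:
            ds.PatientSex = {"male": "M", "female": "F"}[subj.sex]

    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    out = {"dicom": path}
    if masks is not None:
        mask_path = path.with_suffix(".mask.png")
        write_mask_png(masks, mask_path)
        out["mask"] = mask_path
    logger.info("wrote phantom DICOM to %s", path)
    return out
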