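"""HU-window classification, area conversion, and BMI arithmetic."""

import numpy as np
import pytest

from ctcomp import (
    AlignmentError,
    CompartmentMasks,
    CTSlice,
    DEFAULT_WINDOWS,
    HUWindows,
    SubjectRecord,
    ValidationError,
    classify_muscle_pixels,
    compute_bmi,
    fat_areas,
    pixels_to_area,
    quantify,
)
from ctcomp.bodycomp import round_hu


def make_slice(hu, spacing=(1.0, 1.0), subject=None):
    return CTSlice(hu=np.asarray(hu, dtype=float), pixel_spacing_mm=spacing,
                   subject=subject)


def full_masks(shape, muscle=True):
    m = np.full(shape, muscle)
    empty = np.zeros(shape, dtype=bool)
    return CompartmentMasks(muscle=m, visceral=empty, subcutaneous=empty)


class TestClassification:
    @pytest.mark.parametrize(
        "hu,expected",
        [(100, "nama"), (30, "nama"), (150, "nama"),
         (0, "lama"), (-29, "lama"), (29, "lama"),
         (-100, "imat"), (-190, "imat"), (-30, "imat"),
         (151, "unclassified"), (-191, "unclassified"), (500, "unclassified")],
    )
    def test_single_pixel_window_assignment(self, hu, expected):
        slc = make_slice([[hu]])
        cls = classify_muscle_pixels(slc, full_masks((1, 1)))
        counts = cls.counts
        assert counts[expected] == 1
        assert sum(counts.values()) == 1

    @pytest.mark.parametrize(
        "raw,rounded", [(29.5, 30.0), (-29.5, -30.0), (29.4, 29.0), (-30.2, -30.0)]
    )
    def test_rounding_ties_away_from_zero(self, raw, rounded):
        assert round_hu(np.array([raw]))[0] == rounded

    def test_half_hu_values_have_no_window_gap(self):
        # -29.5 rounds to -30 (IMAT); -29.4 rounds to -29 (LAMA): the printed
        # adjacent bounds are exhaustive for any real-valued HU in between
        slc = make_slice([[-29.5, -29.4]])
        cls = classify_muscle_pixels(slc, full_masks((1, 2)))
        assert cls.counts == {"nama": 0, "lama": 1, "imat": 1, "unclassified": 0}

    def test_empty_muscle_mask_gives_zero_counts(self):
        slc = make_slice(np.zeros((4, 4)))
        masks = CompartmentMasks(
            muscle=np.zeros((4, 4), bool),
            visceral=np.zeros((4, 4), bool),
            subcutaneous=np.zeros((4, 4), bool),
        )
        assert classify_muscle_pixels(slc, masks).counts == {
            "nama": 0, "lama": 0, "imat": 0, "unclassified": 0
        }

    def test_counts_match_brute_force_loop(self, rng):
        """Vectorized classification equals a per-pixel reference loop."""
        hu = rng.integers(-1100, 600, size=(40, 40)).astype(float)
        muscle = rng.random((40, 40)) < 0.5
        masks = CompartmentMasks(muscle=muscle,
                                 visceral=np.zeros_like(muscle),
                                 subcutaneous=np.zeros_like(muscle))
        cls = classify_muscle_pixels(make_slice(hu), masks)

        expected = {"nama": 0, "lama": 0, "imat": 0, "unclassified": 0}
        w = DEFAULT_WINDOWS
        for i in range(40):
            for j in range(40):
                if not muscle[i, j]:
                    continue
                v = hu[i, j]
                if w.nama[0] <= v <= w.nama[1]:
                    expected["nama"] += 1
                elif w.lama[0] <= v <= w.lama[1]:
                    expected["lama"] += 1
                elif w.imat[0] <= v <= w.imat[1]:
                    expected["imat"] += 1
                else:
                    expected["unclassified"] += 1
        assert cls.counts == expected

    def test_partition_identity(self, rng):
        hu = rng.normal(0, 300, size=(50, 50))
        muscle = rng.random((50, 50)) < 0.4
        masks = CompartmentMasks(muscle=muscle,
                                 visceral=np.zeros_like(muscle),
                                 subcutaneous=np.zeros_like(muscle))
        cls = classify_muscle_pixels(make_slice(hu), masks)
        counts = cls.counts
        assert sum(counts.values()) == int(muscle.sum())
        # classes are mutually exclusive grids
        assert not np.any(cls.nama & cls.lama)
        assert not np.any((cls.nama | cls.lama) & cls.imat)

    def test_shape_mismatch_raises(self):
        slc = make_slice(np.zeros((4, 4)))
        with pytest.raises(AlignmentError):
            classify_muscle_pixels(slc, full_masks((5, 5)))

    def test_custom_windows_shift_classification(self):
        slc = make_slice([[40.0]])
        narrow = HUWindows(nama=(50, 150), lama=(-29, 49))
        cls = classify_muscle_pixels(slc, full_masks((1, 1)), narrow)
        assert cls.counts["lama"] == 1 and cls.counts["nama"] == 0


class TestFatAreas:
    def test_fat_window_membership(self):
        hu = np.array([[-80.0, 20.0], [-190.0, -29.0]])
        vis = np.array([[True, True], [False, False]])
        sub = np.array([[False, False], [True, True]])
        masks = CompartmentMasks(muscle=np.zeros((2, 2), bool),
                                 visceral=vis, subcutaneous=sub)
        vfat, sfat = fat_areas(make_slice(hu), masks)
        assert vfat == 1   # -80 counted, +20 not
        assert sfat == 1   # -190 counted, -29 not

    def test_all_false_masks(self):
        masks = CompartmentMasks(*(np.zeros((3, 3), bool) for _ in range(3)))
        assert fat_areas(make_slice(np.full((3, 3), -100.0)), masks) == (0, 0)

    def test_counts_match_brute_force(self, rng):
        hu = rng.integers(-300, 100, size=(30, 30)).astype(float)
        vis = rng.random((30, 30)) < 0.3
        sub = ~vis & (rng.random((30, 30)) < 0.3)
        masks = CompartmentMasks(muscle=np.zeros_like(vis), visceral=vis,
                                 subcutaneous=sub)
        vfat, sfat = fat_areas(make_slice(hu), masks)
        lo, hi = DEFAULT_WINDOWS.fat
        assert vfat == sum(
            1 for i in range(30) for j in range(30)
            if vis[i, j] and lo <= hu[i, j] <= hi
        )
        assert sfat == sum(
            1 for i in range(30) for j in range(30)
            if sub[i, j] and lo <= hu[i, j] <= hi
        )


class TestAreasAndBMI:
    @pytest.mark.parametrize(
        "count,spacing,expected",
        [(0, (1.0, 1.0), 0.0),
         (10_000, (1.0, 1.0), 100.0),
         (4_523, (0.74, 0.74), 24.767948)],
    )
    def test_pixels_to_area(self, count, spacing, expected):
        assert pixels_to_area(count, spacing) == pytest.approx(expected, abs=1e-9)

    def test_negative_spacing_rejected(self):
        with pytest.raises(ValidationError):
            pixels_to_area(10, (0.0, 1.0))

    @pytest.mark.parametrize(
        "height,weight,expected",
        [(200.0, 100.0, 25.0), (172.0, 55.0, 18.59), (154.5, 59.5, 24.93)],
    )
    def test_bmi(self, height, weight, expected):
        assert compute_bmi(height, weight) == pytest.approx(expected, abs=0.005)

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            compute_bmi(0.0, 70.0)


class TestQuantify:
    def test_scale_equivariance(self, rng):
        """Doubling the pixel spacing quadruples every area."""
        hu = rng.integers(-200, 200, size=(20, 20)).astype(float)
        muscle = rng.random((20, 20)) < 0.5
        masks = CompartmentMasks(muscle=muscle,
                                 visceral=np.zeros_like(muscle),
                                 subcutaneous=np.zeros_like(muscle))
        subj = SubjectRecord(subject_id="x", height_cm=170, weight_kg=70)
        r1 = quantify(make_slice(hu, (1.0, 1.0), subj), masks)
        r2 = quantify(make_slice(hu, (2.0, 2.0), subj), masks)
        for f in ("nama_cm2", "lama_cm2", "imat_cm2", "sma_cm2",
                  "unclassified_muscle_cm2"):
            assert getattr(r2, f) == pytest.approx(4 * getattr(r1, f))

    def test_sma_is_nama_plus_lama_and_partition_holds(self, phantom_case):
        slc, masks, _ = phantom_case
        r = quantify(slc, masks)
        assert r.sma_cm2 == r.nama_cm2 + r.lama_cm2
        total_muscle = pixels_to_area(int(masks.muscle.sum()), slc.pixel_spacing_mm)
        assert (r.nama_cm2 + r.lama_cm2 + r.imat_cm2 + r.unclassified_muscle_cm2
                == pytest.approx(total_muscle, abs=1e-12))

    def test_missing_height_weight_flags_bmi_fields(self):
        subj = SubjectRecord(subject_id="nobmi")
        slc = make_slice(np.zeros((4, 4)), subject=subj)
        with pytest.warns(UserWarning, match="height/weight absent"):
            r = quantify(slc, full_masks((4, 4)))
        assert r.bmi is None and r.sma_over_bmi is None
        assert r.sma_cm2 > 0  # areas still computed

    def test_sma_over_bmi_orders_muscle_quality(self):
        """Higher SMA/BMI means higher muscle quality under any monotone scale."""
        healthy, sarcopenic = 6.1, 4.0
        assert healthy > sarcopenic
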