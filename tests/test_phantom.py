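"""Phantom generator: exact ground truth, determinism, cohorts, DICOM I/O."""

import numpy as np
import pandas as pd
import pytest

from ctcomp import (
    CompartmentMasks,
    DEFAULT_WINDOWS,
    GeometryError,
    HUOverflowError,
    PhantomSpec,
    ReferenceCohortParams,
    SubjectRecord,
    ValidationError,
    gen_checkup_cohort,
    gen_phantom,
    gen_reference_cohort,
    quantify,
    read_ct_dicom,
    read_mask_png,
    write_phantom_dicom,
)
from ctcomp.reference_tables import (
    CHECKUP_BODYCOMP_STATS,
    CHECKUP_GROUP_SIZES,
    checkup_group_sizes,
    checkup_group_stats,
)


class TestGenPhantom:
    def test_zero_fat_targets_give_zero_fat_areas(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__,
                              "vfat_target_cm2": 0.0, "sfat_target_cm2": 0.0})
        _, _, truth = gen_phantom(spec)
        assert truth.vfat_cm2 == 0.0 and truth.sfat_cm2 == 0.0

    def test_pure_nama_ring(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__, "class_fractions": (1.0, 0.0, 0.0)})
        slc, masks, truth = gen_phantom(spec)
        assert truth.lama_cm2 == 0.0 and truth.imat_cm2 == 0.0
        ring_hu = slc.hu[masks.muscle]
        assert ring_hu.min() >= 30 and ring_hu.max() <= 150

    @pytest.mark.parametrize("seed", [0, 7, 123])
    @pytest.mark.parametrize("fractions", [(0.7, 0.2, 0.1), (0.5, 0.3, 0.1), (1.0, 0.0, 0.0)])
    def test_quantify_reproduces_ground_truth_exactly(self, small_spec, seed, fractions):
        """Independent pixel-count quantification equals the generator's truth."""
        spec = PhantomSpec(**{**small_spec.__dict__,
                              "seed": seed, "class_fractions": fractions})
        slc, masks, truth = gen_phantom(spec)
        result = quantify(slc, masks)
        assert result.as_dict() == truth.as_dict()

    def test_margin_keeps_all_pixels_inside_their_window(self, phantom_case):
        """Exhaustive check: no sampled muscle pixel crosses a window bound."""
        slc, masks, truth = phantom_case
        w = DEFAULT_WINDOWS
        hu = slc.hu[masks.muscle]
        in_any = ((hu >= w.nama[0]) & (hu <= w.nama[1])) | \
                 ((hu >= w.lama[0]) & (hu <= w.lama[1])) | \
                 ((hu >= w.imat[0]) & (hu <= w.imat[1]))
        px_area = slc.pixel_area_cm2
        expected_classified = round(
            (truth.nama_cm2 + truth.lama_cm2 + truth.imat_cm2) / px_area
        )
        assert int(in_any.sum()) == expected_classified

    def test_ground_truth_conservation(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__, "class_fractions": (0.6, 0.3, 0.1)})
        slc, masks, truth = gen_phantom(spec)
        total = (truth.nama_cm2 + truth.lama_cm2 + truth.imat_cm2
                 + truth.unclassified_muscle_cm2)
        px = slc.pixel_area_cm2
        assert total == pytest.approx(int(masks.muscle.sum()) * px, abs=1e-12)

    def test_background_is_air(self, phantom_case):
        slc, masks, _ = phantom_case
        body = masks.muscle | masks.visceral | masks.subcutaneous
        assert np.all(np.abs(slc.hu[~body] + 1000) <= 9)

    def test_determinism(self, small_spec):
        s1, m1, t1 = gen_phantom(small_spec)
        s2, m2, t2 = gen_phantom(small_spec)
        assert np.array_equal(s1.hu, s2.hu)
        assert np.array_equal(m1.muscle, m2.muscle)
        assert t1.as_dict() == t2.as_dict()

    def test_infeasible_ring_raises(self, small_spec):
        with pytest.raises(GeometryError):
            PhantomSpec(**{**small_spec.__dict__, "muscle_ring": (45.0, 70.0)})

    def test_fractions_over_one_rejected(self, small_spec):
        with pytest.raises(ValidationError):
            PhantomSpec(**{**small_spec.__dict__, "class_fractions": (0.8, 0.3, 0.2)})

    def test_fat_target_exceeding_compartment_raises(self, small_spec):
        spec = PhantomSpec(**{**small_spec.__dict__, "vfat_target_cm2": 1e5})
        with pytest.raises(GeometryError):
            gen_phantom(spec)

    def test_margin_must_dominate_noise(self, small_spec):
        with pytest.raises(ValidationError):
            PhantomSpec(**{**small_spec.__dict__, "hu_margin": 4.0, "noise_sd_hu": 2.0})


class TestReferenceCohort:
    def test_noiseless_cohort_lies_on_the_line(self):
        params = ReferenceCohortParams(
            coeffs={"male": (8.0, -0.05)}, noise_sd=0.0, n_per_sex=50, seed=1
        )
        df = gen_reference_cohort(params)
        resid = df["sma_over_bmi"] - (8.0 - 0.05 * df["age"])
        assert np.allclose(resid, 0.0, atol=1e-12)

    def test_heteroscedastic_sd_grows_with_age(self):
        """Residual SD in the oldest age decile exceeds the youngest at n=10,000."""
        params = ReferenceCohortParams(
            coeffs={"female": (6.0, -0.03)}, noise_sd=0.3, noise_sd_slope=0.02,
            n_per_sex=10_000, seed=5,
        )
        df = gen_reference_cohort(params)
        resid = df["sma_over_bmi"] - (6.0 - 0.03 * df["age"])
        q = df["age"].quantile([0.1, 0.9])
        sd_young = resid[df["age"] <= q.iloc[0]].std()
        sd_old = resid[df["age"] >= q.iloc[1]].std()
        assert sd_old > sd_young

    def test_ages_within_configured_range(self):
        params = ReferenceCohortParams(age_range=(30.0, 40.0), n_per_sex=500, seed=2)
        df = gen_reference_cohort(params)
        assert df["age"].between(30, 40).all()

    def test_sexes_have_independent_coefficients(self):
        params = ReferenceCohortParams(
            coeffs={"male": (9.0, -0.05), "female": (5.0, -0.02)},
            noise_sd=0.0, n_per_sex=100, seed=3,
        )
        df = gen_reference_cohort(params)
        male = df[df.sex == "male"]
        assert np.allclose(male["sma_over_bmi"], 9.0 - 0.05 * male["age"])

    def test_too_few_rows_refused(self):
        with pytest.raises(ValidationError):
            ReferenceCohortParams(n_per_sex=2)


class TestCheckupCohort:
    def test_published_group_sizes_reproduce_totals(self):
        df = gen_checkup_cohort(CHECKUP_GROUP_SIZES, CHECKUP_BODYCOMP_STATS, seed=0)
        assert len(df) == 537
        assert (df["sex"] == "male").sum() == 345

    def test_zero_sd_group_is_degenerate(self):
        df = gen_checkup_cohort(
            {("male", "20-29"): 10}, {("male", "20-29"): {"nama": (100.0, 0.0)}}, seed=0
        )
        assert (df["nama"] == 100.0).all()

    def test_sample_means_converge_at_clt_rate(self):
        """At n=10,000 per group the sample mean is within 3 SD/sqrt(n)."""
        mean, sd = CHECKUP_BODYCOMP_STATS[("male", "20-29")]["sma_over_bmi"]
        df = gen_checkup_cohort(
            {("male", "20-29"): 10_000},
            {("male", "20-29"): {"sma_over_bmi": (mean, sd)}},
            seed=7,
        )
        assert df["sma_over_bmi"].mean() == pytest.approx(mean, abs=3 * sd / 100)

    def test_ages_respect_band_bounds(self):
        df = gen_checkup_cohort(
            {("female", "70+"): 200},
            {("female", "70+"): {"nama": (55.3, 13.9)}}, seed=1,
        )
        assert df["age"].between(70, 80).all()

    def test_missing_stats_for_nonzero_group_rejected(self):
        with pytest.raises(ValidationError):
            gen_checkup_cohort({("male", "20-29"): 5}, {}, seed=0)

    def test_sex_filter_helpers(self):
        male_sizes = checkup_group_sizes("male")
        assert sum(male_sizes.values()) == 345
        stats = checkup_group_stats("female", metrics=("nama",))
        assert set(stats[("female", "70+")]) == {"nama"}


class TestDicomRoundTrip:
    def test_hu_and_metadata_round_trip(self, phantom_case, subject, tmp_path):
        slc, masks, _ = phantom_case
        paths = write_phantom_dicom(slc, masks, tmp_path / "case.dcm")
        back = read_ct_dicom(paths["dicom"])
        assert np.array_equal(back.hu, slc.hu)
        assert back.pixel_spacing_mm == slc.pixel_spacing_mm
        # 172 cm subject stores PatientSize 1.72 m and reads back as 172 cm
        assert back.subject.height_cm == pytest.approx(172.0)
        assert back.subject.weight_kg == pytest.approx(55.0)
        assert back.subject.sex == "female"

    def test_mask_png_round_trip(self, phantom_case, tmp_path):
        slc, masks, _ = phantom_case
        paths = write_phantom_dicom(slc, masks, tmp_path / "case.dcm")
        back = read_mask_png(paths["mask"])
        assert np.array_equal(back.muscle, masks.muscle)
        assert np.array_equal(back.visceral, masks.visceral)
        assert np.array_equal(back.subcutaneous, masks.subcutaneous)

    def test_hu_overflow_rejected(self, subject, tmp_path):
        from ctcomp import CTSlice

        slc = CTSlice(hu=np.full((4, 4), 40000.0), pixel_spacing_mm=(1.0, 1.0),
                      subject=subject)
        with pytest.raises(HUOverflowError):
            write_phantom_dicom(slc, None, tmp_path / "x.dcm")
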