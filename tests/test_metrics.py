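import math

import numpy as np
import pytest

from eusquant import (
    CalibratedImage,
    CalibrationSpec,
    EmptyRegionError,
    FullyCysticError,
    GrayMoments,
    InconsistentRegionsError,
    LesionAnnotation,
    ParenchymaCircle,
    SeedSpec,
    UndefinedSDError,
    ValidationError,
    compute_moments,
    density,
    mean_gray,
    measure_lesion,
    measure_parenchyma,
    sd_gray,
    subtract_moments,
)
from eusquant.phantom import PhantomSpec, RegionNoise, render_phantom
from oracles import direct_moments

CAL1 = CalibrationSpec(1.0)
STUDY = CalibrationSpec()


def _image(grid, cal=CAL1):
    return CalibratedImage(gray=np.asarray(grid, dtype=np.uint8), calibration=cal)


class TestMoments:
    def test_three_pixel_example(self):
        img = _image([[10, 20, 30], [0, 0, 0]])
        mask = np.array([[1, 1, 1], [0, 0, 0]], dtype=bool)
        m = compute_moments(img, mask)
        assert (m.n, m.sum_gray, m.sum_sq) == (3, 60, 1400)

    def test_all_zero_region(self):
        img = _image(np.zeros((1, 5)))
        m = compute_moments(img, np.ones((1, 5), bool))
        assert (m.n, m.sum_gray, m.sum_sq) == (5, 0, 0)

    def test_single_saturated_pixel(self):
        img = _image([[255]])
        m = compute_moments(img, np.ones((1, 1), bool))
        assert (m.n, m.sum_gray, m.sum_sq) == (1, 255, 65025)

    def test_empty_mask_rejected(self):
        img = _image([[1, 2]])
        with pytest.raises(EmptyRegionError):
            compute_moments(img, np.zeros((1, 2), bool))

    def test_cauchy_schwarz_guard(self):
        with pytest.raises(ValidationError):
            GrayMoments(n=2, sum_gray=100, sum_sq=100, calibration=CAL1)


class TestScalarMetrics:
    def test_mean_examples(self):
        assert mean_gray(GrayMoments(3, 60, 1400, CAL1)) == 20
        assert mean_gray(GrayMoments(5, 0, 0, CAL1)) == 0
        assert mean_gray(GrayMoments(1, 255, 65025, CAL1)) == 255

    def test_sd_examples(self):
        assert sd_gray(GrayMoments(3, 60, 1400, CAL1)) == pytest.approx(10.0)
        # constant region
        assert sd_gray(GrayMoments(4, 4 * 17, 4 * 17**2, CAL1)) == 0.0
        # two pixels {0, 255}
        assert sd_gray(GrayMoments(2, 255, 65025, CAL1)) == pytest.approx(math.sqrt(32512.5))

    def test_sd_denominator_switch(self):
        m = GrayMoments(3, 60, 1400, CAL1)
        assert sd_gray(m, sample=False) == pytest.approx(math.sqrt(200 / 3))

    def test_sd_needs_two_pixels(self):
        with pytest.raises(UndefinedSDError):
            sd_gray(GrayMoments(1, 10, 100, CAL1))

    def test_density_reproduces_study_scale(self):
        # mean 27.8 at 12.2674 px/mm → 27.8 × 150.489 ≈ 4183.6 Σgray/mm²
        m = GrayMoments(1000, 27800, 27800 * 28, STUDY)
        assert density(m) == pytest.approx(27.8 * STUDY.pixels_per_mm2, rel=1e-9)
        assert density(m) == pytest.approx(4183.6, rel=1e-4)

    def test_density_unit_calibration(self):
        assert density(GrayMoments(3, 60, 1400, CAL1)) == pytest.approx(20.0)

    def test_density_zero_region_value(self):
        assert density(GrayMoments(5, 0, 0, CAL1)) == 0.0


class TestSubtractMoments:
    def test_ten_pixel_worked_example(self):
        whole = GrayMoments(10, 100, 1200, CAL1)
        cystic = GrayMoments(4, 20, 120, CAL1)
        solid = subtract_moments(whole, cystic)
        assert (solid.n, solid.sum_gray, solid.sum_sq) == (6, 80, 1080)
        assert mean_gray(solid) == pytest.approx(13.333, abs=5e-4)
        assert sd_gray(solid) == pytest.approx(1.633, abs=5e-4)

    def test_empty_cystic_is_identity(self):
        whole = GrayMoments(10, 100, 1200, CAL1)
        solid = subtract_moments(whole, GrayMoments(0, 0, 0, CAL1))
        assert (solid.n, solid.sum_gray, solid.sum_sq) == (10, 100, 1200)

    def test_fully_cystic_error(self):
        m = GrayMoments(4, 20, 120, CAL1)
        with pytest.raises(FullyCysticError):
            subtract_moments(m, m)

    def test_non_subset_error(self):
        with pytest.raises(InconsistentRegionsError):
            subtract_moments(GrayMoments(4, 20, 120, CAL1), GrayMoments(5, 10, 60, CAL1))

    def test_matches_difference_mask_on_random_regions(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            gray = rng.integers(0, 256, (12, 12), dtype=np.uint8)
            img = _image(gray)
            whole_mask = rng.random((12, 12)) < 0.6
            if whole_mask.sum() < 2:
                continue
            inner = whole_mask & (rng.random((12, 12)) < 0.5)
            if inner.sum() == whole_mask.sum() or inner.sum() == 0:
                continue
            solid = subtract_moments(compute_moments(img, whole_mask), compute_moments(img, inner))
            n, s, ss = direct_moments(gray, whole_mask & ~inner)
            assert (solid.n, solid.sum_gray, solid.sum_sq) == (n, s, ss)
            direct = GrayMoments(n, s, ss, CAL1)
            if n >= 2:
                assert sd_gray(solid) == pytest.approx(sd_gray(direct), abs=1e-9)


class TestIdentities:
    def test_density_equals_mean_times_pixels_per_mm2(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            vals = rng.integers(0, 256, n)
            cal = CalibrationSpec(float(rng.uniform(0.5, 30)))
            m = GrayMoments(n, int(vals.sum()), int((vals**2).sum()), cal)
            assert density(m) == pytest.approx(mean_gray(m) * cal.pixels_per_mm2, rel=1e-9)

    def test_mixture_identity(self):
        rng = np.random.default_rng(29)
        gray = rng.integers(0, 256, (15, 15), dtype=np.uint8)
        img = _image(gray)
        whole = np.ones((15, 15), bool)
        cyst = rng.random((15, 15)) < 0.4
        mw = compute_moments(img, whole)
        mc = compute_moments(img, cyst)
        ms = subtract_moments(mw, mc)
        assert mean_gray(mw) * mw.n == pytest.approx(
            mean_gray(mc) * mc.n + mean_gray(ms) * ms.n, rel=1e-12
        )

    def test_scale_equivariance(self):
        vals = np.array([10, 20, 30, 40])
        cal1, cal2 = CalibrationSpec(5.0), CalibrationSpec(10.0)
        m1 = GrayMoments(4, int(vals.sum()), int((vals**2).sum()), cal1)
        m2 = GrayMoments(4, int(vals.sum()), int((vals**2).sum()), cal2)
        assert mean_gray(m1) == mean_gray(m2)
        assert sd_gray(m1) == sd_gray(m2)
        assert density(m2) == pytest.approx(4 * density(m1), rel=1e-12)
        assert m2.area_mm2 == pytest.approx(m1.area_mm2 / 4, rel=1e-12)


def _rect_polygon(r0, c0, r1, c1):
    return np.array(
        [[r0 - 0.5, c0 - 0.5], [r0 - 0.5, c1 + 0.5], [r1 + 0.5, c1 + 0.5], [r1 + 0.5, c0 - 0.5]]
    )


class TestMeasureLesion:
    @pytest.fixture
    def blocky(self):
        """20×20 image: lesion rows 2–11 × cols 2–11 at gray 40, with a dark
        4×4 cystic block (gray 8) at rows 4–7 × cols 4–7; background 80."""
        gray = np.full((20, 20), 80, dtype=np.uint8)
        gray[2:12, 2:12] = 40
        gray[4:8, 4:8] = 8
        return _image(gray, STUDY)

    def test_exact_block_measurement(self, blocky):
        ann = LesionAnnotation(
            image_id="block",
            lesion_polygon=_rect_polygon(2, 2, 11, 11),
            cystic_seeds=(SeedSpec((5.0, 5.0), 10),),
            calibration=STUDY,
        )
        rec = measure_lesion(blocky, ann)
        px = STUDY.pixel_area_mm2
        assert rec.area_whole_mm2 == pytest.approx(100 * px, rel=1e-12)
        assert rec.area_cystic_mm2 == pytest.approx(16 * px, rel=1e-12)
        assert rec.area_solid_mm2 == pytest.approx(84 * px, rel=1e-12)
        assert rec.area_ratio == pytest.approx(0.16)
        assert rec.mean_cystic == 8
        assert rec.mean_solid == 40
        assert rec.mean_whole == pytest.approx((16 * 8 + 84 * 40) / 100)
        assert rec.sd_cystic == 0.0
        assert rec.lobule_count == 1
        assert rec.density_whole == pytest.approx(rec.mean_whole * STUDY.pixels_per_mm2, rel=1e-9)
        # area additivity
        assert rec.area_whole_mm2 == pytest.approx(
            rec.area_cystic_mm2 + rec.area_solid_mm2, abs=1e-9
        )

    def test_no_seeds_solid_is_whole(self, blocky):
        ann = LesionAnnotation(
            image_id="noseed", lesion_polygon=_rect_polygon(2, 2, 11, 11), calibration=STUDY
        )
        rec = measure_lesion(blocky, ann)
        assert rec.area_cystic_mm2 is None
        assert rec.mean_cystic is None
        assert rec.area_ratio == 0.0
        assert rec.lobule_count == 0
        assert rec.mean_solid == rec.mean_whole
        assert rec.area_solid_mm2 == rec.area_whole_mm2

    def test_fully_cystic_solid_missing(self):
        gray = np.full((10, 10), 30, dtype=np.uint8)
        img = _image(gray, STUDY)
        ann = LesionAnnotation(
            image_id="full",
            lesion_polygon=_rect_polygon(2, 2, 7, 7),
            cystic_seeds=(SeedSpec((4.0, 4.0), 255),),
            calibration=STUDY,
        )
        rec = measure_lesion(img, ann)
        assert rec.area_ratio == pytest.approx(1.0)
        assert rec.mean_solid is None
        assert rec.area_solid_mm2 is None
        assert rec.density_solid is None

    def test_two_seeds_one_lobule_when_touching(self, blocky):
        ann = LesionAnnotation(
            image_id="twoseeds",
            lesion_polygon=_rect_polygon(2, 2, 11, 11),
            cystic_seeds=(SeedSpec((5.0, 5.0), 10), SeedSpec((6.0, 6.0), 10)),
            calibration=STUDY,
        )
        rec = measure_lesion(blocky, ann)
        assert rec.lobule_count == 1
        assert rec.area_cystic_mm2 == pytest.approx(16 * STUDY.pixel_area_mm2, rel=1e-12)

    def test_phantom_recovery_against_truth(self, contrast_phantom):
        img, truth = contrast_phantom
        rec = measure_lesion(img, truth.annotation)
        truth_frac = truth.realized["cystic"].n / truth.realized["whole"].n
        assert rec.area_ratio == pytest.approx(truth_frac, abs=0.02)
        cyst = truth.realized["cystic"]
        assert rec.mean_cystic == pytest.approx(cyst.mean, abs=3 * cyst.sd / math.sqrt(cyst.n) + 0.5)


class TestMeasureParenchyma:
    CIRCLES = (
        ParenchymaCircle((40.0, 40.0)),
        ParenchymaCircle((40.0, 140.0)),
        ParenchymaCircle((140.0, 40.0)),
    )

    def test_constant_discs_homogeneous(self):
        img = _image(np.full((200, 200), 68), STUDY)
        res = measure_parenchyma(img, self.CIRCLES, STUDY)
        assert res.mean == 68
        assert res.sd == 0.0
        assert res.homogeneous

    def test_one_divergent_disc_fails_two_pairs(self):
        gray = np.full((200, 200), 68, dtype=np.uint8)
        gray[100:, :] = 90  # third circle sits in the bright band
        img = _image(gray, STUDY)
        res = measure_parenchyma(img, self.CIRCLES, STUDY)
        assert res.pair_pass == (True, False, False)
        assert not res.homogeneous

    def test_out_of_bounds_circle_rejected(self):
        img = _image(np.full((200, 200), 68), STUDY)
        bad = (ParenchymaCircle((2.0, 2.0)),) + self.CIRCLES[1:]
        with pytest.raises(ValidationError, match="inside"):
            measure_parenchyma(img, bad, STUDY)

    def test_homogeneous_field_passes_mostly(self):
        """Three discs from one homogeneous noise field: the pooled mean sits
        within 3 SE of the target and the pairwise homogeneity check passes in
        the large majority of seeded replicates."""
        passes = 0
        means = []
        n_rep = 300
        for s in range(n_rep):
            spec = PhantomSpec(
                height=150,
                width=360,
                background=RegionNoise(68.3, 11.3),
                parenchyma_circles=((75.0, 60.0), (75.0, 180.0), (75.0, 300.0)),
                auto_parenchyma_circles=False,
                seed=1000 + s,
            )
            img, truth = render_phantom(spec)
            res = measure_parenchyma(img, truth.circles, spec.calibration)
            means.append(res.mean)
            passes += res.homogeneous
        n_px = res.n
        assert np.mean(means) == pytest.approx(68.3, abs=3 * 11.3 / math.sqrt(n_px))
        assert passes / n_rep >= 0.85
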