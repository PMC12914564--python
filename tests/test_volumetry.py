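"""Polynomial area-profile volumetry and the per-slice area measurements."""

import numpy as np
import pytest

from cortiquant import slicestack, volumetry
from cortiquant.exceptions import ProfileError, RoiError
from cortiquant.types import AreaProfile, SliceImage, SliceMask


def make_slice(channels, pixel_size_um=2.0):
    return SliceImage(channels=channels, pixel_size_um=pixel_size_um,
                      ap_position_mm=0.0)


class TestFitAndIntegrate:
    def test_constant_profile_exact(self):
        prof = AreaProfile(np.linspace(0, 1, 5), np.ones(5))
        res = volumetry.fit_and_integrate(prof, degree=2)
        assert res.volume_mm3 == pytest.approx(1.0, rel=1e-9)
        assert res.fit_r2 == 1.0

    def test_quadratic_sphere_profile_exact(self):
        """A(x) = π(0.25 − x²) on [−0.5, 0.5] integrates to the sphere
        volume 4/3·π·0.5³ with ≤ 1e-9 relative error."""
        x = np.linspace(-0.5, 0.5, 9)
        prof = AreaProfile(x, np.pi * np.maximum(0.25 - x ** 2, 0.0))
        res = volumetry.fit_and_integrate(prof, degree=2)
        assert res.volume_mm3 == pytest.approx(4 / 3 * np.pi * 0.125,
                                               rel=1e-9)

    def test_too_few_samples_raises(self):
        prof = AreaProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ProfileError):
            volumetry.fit_and_integrate(prof, degree=2)

    def test_all_zero_profile_warns_and_returns_zero(self):
        prof = AreaProfile(np.linspace(0, 1, 5), np.zeros(5))
        with pytest.warns(UserWarning, match="all-zero"):
            res = volumetry.fit_and_integrate(prof)
        assert res.volume_mm3 == 0.0

    def test_trapezoid_agreement_on_dense_profile(self):
        x = np.linspace(-0.5, 0.5, 51)
        y = np.pi * np.maximum(0.25 - x ** 2, 0.0)
        res = volumetry.fit_and_integrate(AreaProfile(x, y), degree=2)
        assert res.volume_mm3 == pytest.approx(np.trapezoid(y, x), rel=0.02)

    def test_monotone_in_lesion_size(self):
        vols = []
        for r in (0.3, 0.4, 0.5):
            x = np.linspace(-r, r, 9)
            y = np.pi * np.maximum(r ** 2 - x ** 2, 0.0)
            vols.append(volumetry.fit_and_integrate(
                AreaProfile(x, y)).volume_mm3)
        assert vols[0] < vols[1] < vols[2]

    def test_negative_fit_regions_clamped(self):
        # profile dipping to zero in the middle: integral stays >= 0
        x = np.linspace(0, 1, 7)
        y = np.abs(x - 0.5)
        res = volumetry.fit_and_integrate(AreaProfile(x, y), degree=2,
                                          fit_support_only=False)
        assert res.volume_mm3 >= 0.0


class TestLesionArea:
    def test_uninjured_slice_zero(self):
        img = np.full((300, 300), 1000.0)
        sl = make_slice({"dapi": img})
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        assert volumetry.lesion_area_per_slice(sl, m) == 0.0

    def test_planted_circular_cavity_area(self):
        """0.5 mm-radius circular hole at 2 μm/px → π·0.25 mm² within 2%."""
        img = np.full((1400, 1400), 1000.0)
        rr, cc = np.mgrid[0:1400, 0:1400]
        img[(rr - 700) ** 2 + (cc - 700) ** 2 <= 250 ** 2] = 0.0
        sl = make_slice({"dapi": img})
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        assert volumetry.lesion_area_per_slice(sl, m) == pytest.approx(
            np.pi * 0.25, rel=0.02)

    def test_two_cavities_additive(self):
        img = np.full((1200, 1200), 1000.0)
        rr, cc = np.mgrid[0:1200, 0:1200]
        r1 = int(round(np.sqrt(0.1 / np.pi) * 500))   # 0.1 mm²
        r2 = int(round(np.sqrt(0.2 / np.pi) * 500))   # 0.2 mm²
        img[(rr - 300) ** 2 + (cc - 300) ** 2 <= r1 ** 2] = 0.0
        img[(rr - 800) ** 2 + (cc - 800) ** 2 <= r2 ** 2] = 0.0
        sl = make_slice({"dapi": img})
        m = slicestack.make_dapi_mask(sl, blur_sigma=0, threshold=500.0)
        assert volumetry.lesion_area_per_slice(sl, m) == pytest.approx(
            0.3, rel=0.02)

    def test_scale_equivariance(self):
        """Doubling the pixel size quadruples the measured area of the same
        pixel grid."""
        img = np.full((600, 600), 1000.0)
        img[250:350, 250:350] = 0.0
        a2 = volumetry.lesion_area_per_slice(
            make_slice({"dapi": img}, 2.0),
            slicestack.make_dapi_mask(make_slice({"dapi": img}, 2.0),
                                      blur_sigma=0, threshold=500.0))
        a4 = volumetry.lesion_area_per_slice(
            make_slice({"dapi": img}, 4.0),
            slicestack.make_dapi_mask(make_slice({"dapi": img}, 4.0),
                                      blur_sigma=0, threshold=500.0))
        assert a4 == pytest.approx(4 * a2, rel=1e-9)


class TestIba1Area:
    def test_noise_only_above_ceiling_threshold_zero(self):
        rng = np.random.default_rng(0)
        img = rng.normal(100, 10, (500, 500)).clip(0)
        sl = make_slice({"iba1": img})
        assert volumetry.iba1_area_per_slice(sl, threshold=5000.0) == 0.0

    def test_min_size_filters_specks(self):
        img = np.zeros((600, 600))
        img[100:140, 100:150] = 5000.0          # 2000 px region
        for k in range(5):                       # 5 specks of 100 px
            img[300 + 30 * k: 300 + 30 * k + 10, 400:410] = 5000.0
        sl = make_slice({"iba1": img})
        area = volumetry.iba1_area_per_slice(sl, threshold=2500.0,
                                             blur_sigma=0, min_size_px=1000)
        assert area == pytest.approx(2000 * 4e-6, rel=1e-9)

    def test_phantom_iba1_area_close_to_noise_free_oracle(self,
                                                          small_stack,
                                                          small_stack_clean,
                                                          small_spec):
        """Measured IBA1⁺ area within 10% of the pixel-count oracle on the
        noise-free rendering.

        The oracle adds the closed-form mean of zero-clipped Gaussian
        noise, E[max(N(μ,σ),0)] − μ = σφ(μ/σ) − μΦ(−μ/σ), to the clean
        field before blurring: the contralesionally calibrated threshold
        sits where diffuse signal meets background, so the clipping bias
        shifts the measured boundary and a faithful oracle must model it.
        """
        from scipy import ndimage, stats

        noisy, _ = small_stack
        clean, _ = small_stack_clean
        thr = volumetry.calibrate_threshold(noisy[1], (50, 50, 100, 100))
        a_noisy = volumetry.iba1_area_per_slice(noisy[1], thr)

        mu = clean[1].channel("iba1").astype(float)
        sd = small_spec.noise_sd
        clipped_mean = (mu + sd * stats.norm.pdf(mu / sd)
                        - mu * stats.norm.cdf(-mu / sd))
        blurred = ndimage.gaussian_filter(clipped_mean, 5.0)
        labels, n = ndimage.label(blurred >= thr)
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        a_oracle = float(sizes[sizes >= 1000].sum()) \
            * clean[1].pixel_area_mm2()
        assert a_noisy == pytest.approx(a_oracle, rel=0.10)


class TestCalibrateThreshold:
    def test_constant_roi_returns_mean(self):
        img = np.full((200, 200), 100.0)
        sl = make_slice({"iba1": img})
        assert volumetry.calibrate_threshold(sl, (10, 10, 50, 50),
                                             blur_sigma=0) == 100.0

    def test_mean_plus_k_sd_formula(self):
        img = np.full((200, 200), 50.0)
        img[:, ::2] = 40.0
        img[:, 1::2] = 60.0   # mean 50, sd 10
        sl = make_slice({"iba1": img})
        thr = volumetry.calibrate_threshold(sl, (0, 0, 200, 200), k=3,
                                            blur_sigma=0)
        assert thr == pytest.approx(80.0)

    def test_roi_outside_image_raises(self):
        sl = make_slice({"iba1": np.zeros((100, 100))})
        with pytest.raises(RoiError):
            volumetry.calibrate_threshold(sl, (90, 90, 50, 50))

    def test_calibrated_threshold_excludes_contralesional_pixels(
            self, small_stack):
        """mean + 3·sd leaves ≤ 1% of contralesional blurred pixels above
        threshold (Gaussian tail)."""
        from scipy import ndimage

        slices, _ = small_stack
        s = slices[1]
        roi = (50, 50, 150, 150)  # top-left contralesional corner
        thr = volumetry.calibrate_threshold(s, roi)
        blurred = ndimage.gaussian_filter(s.channel("iba1").astype(float), 5)
        patch = blurred[roi[0]:roi[0] + roi[2], roi[1]:roi[1] + roi[3]]
        assert np.mean(patch >= thr) <= 0.01
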