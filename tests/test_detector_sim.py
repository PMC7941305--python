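import warnings

import numpy as np
import pytest
from scipy import integrate

import saxskit as sk
from saxskit import fixtures as fx


def small_geometry(shape=(64, 64), distance=1000.0):
    return sk.DetectorGeometry(shape=shape, pixel_size=0.172,
                               distance=distance, wavelength=1.0,
                               beam_center=((shape[0] - 1) / 2,
                                            (shape[1] - 1) / 2))


class TestPixelToS:
    def test_beam_center_is_zero(self):
        g = small_geometry()
        assert sk.pixel_to_s(g, *g.beam_center) == 0.0

    def test_inverse_identity(self):
        """r = D tan(2 theta) recovers the chosen theta to machine precision."""
        g = small_geometry(distance=1000.0)
        for theta in (1e-4, 5e-3, 2e-2):
            r_mm = g.distance * np.tan(2 * theta)
            j = g.beam_center[1] + r_mm / g.pixel_size
            s = sk.pixel_to_s(g, g.beam_center[0], j)
            theta_back = np.arcsin(s * g.wavelength / (4 * np.pi))
            assert theta_back == pytest.approx(theta, rel=1e-12)

    def test_small_angle_limit(self):
        """s ~ 2 pi r / (lambda D) within 0.1% for r/D < 0.02."""
        g = small_geometry(distance=1000.0)
        r_mm = np.array([1.0, 5.0, 19.9])
        j = g.beam_center[1] + r_mm / g.pixel_size
        s = sk.pixel_to_s(g, g.beam_center[0], j)
        approx = 2 * np.pi * r_mm / (g.wavelength * g.distance)
        np.testing.assert_allclose(s, approx, rtol=1e-3)


class TestExpectedImage:
    def _flat_curve(self, k=0.5):
        return sk.ScatteringCurve(s=np.linspace(0.0, 1.0, 10),
                                  I=np.full(10, k), scale="absolute")

    def test_flat_curve_uniform_up_to_cos3(self):
        g = small_geometry()
        model = sk.ExposureModel(flux=1e10, exposure=1.0, concentration=1.0)
        exp_img = sk.expected_image(self._flat_curve(), g, model)
        cos3 = sk.solid_angle_map(g) / (g.pixel_size / g.distance) ** 2
        flattened = exp_img.mu / cos3
        assert np.ptp(flattened) < 1e-9 * flattened.max()

    def test_exposure_time_linearity(self):
        g = small_geometry()
        m1 = sk.ExposureModel(flux=1e10, exposure=1.0, concentration=1.0)
        m2 = sk.ExposureModel(flux=1e10, exposure=2.0, concentration=1.0)
        e1 = sk.expected_image(self._flat_curve(), g, m1)
        e2 = sk.expected_image(self._flat_curve(), g, m2)
        np.testing.assert_allclose(e2.mu, 2.0 * e1.mu, rtol=1e-12)

    def test_total_counts_match_quadrature(self):
        """Total expected counts equal the curve integrated over the detector
        solid angle (independent radial quadrature), within 1%."""
        R = 30.0
        g = small_geometry(shape=(256, 256), distance=2000.0)
        curve = fx.sphere_curve(R, np.linspace(0.0, 0.2, 2000), i0=0.2
                                ).with_(scale="absolute")
        model = sk.ExposureModel(flux=1e10, exposure=1.0, concentration=1.0)
        # circular mask inscribed in the panel to make the domain exact
        ii, jj = np.meshgrid(np.arange(256), np.arange(256), indexing="ij")
        r_pix = np.hypot(ii - g.beam_center[0], jj - g.beam_center[1])
        mask = r_pix <= 120.0
        exp_img = sk.expected_image(curve, g, model, mask=mask)
        total = exp_img.mu.sum()

        k = model.photon_factor
        r_max_mm = 120.0 * g.pixel_size

        def integrand(r_mm):
            theta = 0.5 * np.arctan2(r_mm, g.distance)
            s = 4 * np.pi / g.wavelength * np.sin(theta)
            cos_psi = g.distance / np.hypot(g.distance, r_mm)
            return (curve.interp(s) * cos_psi ** 3 * 2 * np.pi * r_mm
                    / g.distance ** 2)

        oracle, _ = integrate.quad(integrand, 0.0, r_max_mm, limit=200)
        oracle *= k
        assert total == pytest.approx(oracle, rel=0.01)

    def test_out_of_range_pixels_masked_with_warning(self):
        g = small_geometry()
        narrow = sk.ScatteringCurve(s=[1e-4, 5e-4], I=[1.0, 1.0],
                                    scale="absolute")
        model = sk.ExposureModel(flux=1e10, exposure=1.0, concentration=1.0)
        with pytest.warns(UserWarning, match="outside the curve s-range"):
            exp_img = sk.expected_image(narrow, g, model)
        assert not exp_img.mask.all()

    def test_relative_scale_curve_rejected(self):
        g = small_geometry()
        c = sk.ScatteringCurve(s=[0.01, 0.5], I=[1.0, 1.0])
        model = sk.ExposureModel(flux=1e10, exposure=1.0, concentration=1.0)
        with pytest.raises(ValueError):
            sk.expected_image(c, g, model)


class TestSampleImage:
    def _expected(self, mu_value, shape=(32, 32)):
        g = small_geometry(shape=shape)
        return sk.ExpectedImage(mu=np.full(shape, float(mu_value)),
                                geometry=g,
                                mask=np.ones(shape, dtype=bool),
                                norm=np.ones(shape))

    def test_zero_expectation_gives_zero_image(self):
        img = sk.sample_image(self._expected(0.0), seed=1)
        assert img.counts.sum() == 0

    def test_seed_determinism(self):
        e = self._expected(5.0)
        a = sk.sample_image(e, seed=42)
        b = sk.sample_image(e, seed=42)
        c = sk.sample_image(e, seed=43)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_poisson_mean(self):
        e = self._expected(5.0, shape=(100, 100))
        img = sk.sample_image(e, seed=7)
        # 10^4 pixels at mu=5: mean within 3 sigma of the mean estimate
        assert img.counts.mean() == pytest.approx(5.0,
                                                  abs=3 * np.sqrt(5.0 / 1e4))

    def test_fano_factor_unity(self):
        """Variance/mean across replicate pixels ~ 1 for Poisson counts."""
        e = self._expected(5.0, shape=(100, 100))
        img = sk.sample_image(e, seed=11)
        fano = img.counts.var() / img.counts.mean()
        assert fano == pytest.approx(1.0, abs=0.05)


class TestImageOp:
    def _img(self, counts, norm=None):
        counts = np.asarray(counts)
        g = small_geometry(shape=counts.shape)
        return sk.DetectorImage(counts=counts, geometry=g,
                                mask=np.ones(counts.shape, dtype=bool),
                                norm=norm)

    def test_xor_self_is_zero(self):
        a = self._img(np.eye(8, dtype=np.int64))
        out = sk.image_op(a, a, "xor")
        assert out.counts.sum() == 0

    def test_and_with_ones_is_identity(self):
        a = self._img((np.arange(64).reshape(8, 8) % 2))
        ones = self._img(np.ones((8, 8), dtype=np.int64))
        np.testing.assert_array_equal(sk.image_op(a, ones, "and").counts,
                                      a.counts)

    def test_logic_requires_binary(self):
        a = self._img(np.full((4, 4), 3))
        with pytest.raises(ValueError):
            sk.image_op(a, a, "xor")

    def test_shape_mismatch(self):
        a = self._img(np.zeros((4, 4), dtype=np.int64))
        b = self._img(np.zeros((5, 5), dtype=np.int64))
        with pytest.raises(ValueError):
            sk.image_op(a, b, "add")

    def test_sub_clamps_and_flags(self):
        a = self._img(np.zeros((4, 4), dtype=np.int64))
        b = self._img(np.ones((4, 4), dtype=np.int64))
        with pytest.warns(UserWarning, match="clamped"):
            out = sk.image_op(a, b, "sub")
        assert out.clipped
        assert np.all(out.counts == 0)

    def test_apply_mask_zeroes_permanently(self):
        a = self._img(np.full((4, 4), 7))
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = True
        out = sk.image_op(a, m, "apply_mask")
        assert out.counts.sum() == 7
        assert out.mask.sum() == 1

    def test_poisson_additivity_of_summed_images(self, detector_setup):
        """Summing two Poisson frames is statistically one frame at summed mu:
        the reduction of the sum agrees with an independent double-exposure
        frame (all DATCMP tests non-significant)."""
        exp_img = detector_setup["expected"]
        a = sk.sample_image(exp_img, seed=100)
        b = sk.sample_image(exp_img, seed=101)
        summed = sk.image_op(a, b, "add")
        double = sk.ExpectedImage(mu=2 * exp_img.mu,
                                  geometry=exp_img.geometry,
                                  mask=exp_img.mask, norm=2 * exp_img.norm)
        one_shot = sk.sample_image(double, seed=102)
        ra = sk.radial_average(summed, nbins=500, reject=False)
        rb = sk.radial_average(one_shot, nbins=500, reject=False)
        res = sk.datcmp(ra, rb)
        assert res.chi2_p > 0.01
        assert res.cormap_p > 0.01
        assert res.ad_p > 0.01
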