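import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import saxskit as sk
from saxskit import fixtures as fx
from saxskit.compare import (ad_pvalue, ad_statistic, cormap_pvalue,
                             fraction_within, longest_run)


def _noisy_pair(n=500, seed=0, mu=1000.0):
    s = np.linspace(0.01, 0.5, n)
    base = sk.ScatteringCurve(s=s, I=np.full(n, mu),
                              sigma=np.full(n, np.sqrt(mu)))
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(2):
        x = rng.poisson(mu, n).astype(float)
        out.append(sk.ScatteringCurve(s=s, I=x,
                                      sigma=np.sqrt(np.maximum(x, 1.0))))
    return out


class TestReducedChi2:
    def test_identical_curves(self):
        c = sk.ScatteringCurve(s=[0.01, 0.02, 0.03], I=[1.0, 2.0, 3.0],
                               sigma=[0.1, 0.1, 0.1])
        stat, p = sk.reduced_chi2(c, c)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("stat,n,p_expected,tol", [
        (1.081, 1776, 0.0091, 0.0005),
        (1.007, 2652, 0.3942, 0.004),
    ])
    def test_upper_tail_p_values(self, stat, n, p_expected, tol):
        """chi2 survival probabilities for published test values (statistics
        rounded to 3 decimals, which bounds attainable agreement)."""
        from scipy import stats as sps
        assert sps.chi2.sf(stat * n, df=n) == pytest.approx(p_expected,
                                                            abs=tol)

    def test_requires_errors(self):
        a = sk.ScatteringCurve(s=[0.01, 0.02], I=[1.0, 2.0])
        with pytest.raises(ValueError):
            sk.reduced_chi2(a, a)


class TestCormap:
    @pytest.mark.parametrize("n,C,p_expected", [
        (2652, 13, 0.2759),
        (1434, 11, 0.5031),
        (1776, 13, 0.1941),   # exact value; see also n=1777 -> 0.1942
        (1, 1, 1.0),
    ])
    def test_exact_run_probabilities(self, n, C, p_expected):
        assert cormap_pvalue(n, C) == pytest.approx(p_expected, abs=5e-5)

    @pytest.mark.parametrize("n,C", [(10, 3), (12, 4), (14, 5), (9, 2)])
    def test_matches_brute_force_enumeration(self, n, C):
        count = 0
        for seq in itertools.product((0, 1), repeat=n):
            run = best = 1
            for a, b in zip(seq, seq[1:]):
                run = run + 1 if a == b else 1
                best = max(best, run)
            if best >= C:
                count += 1
        assert cormap_pvalue(n, C) == pytest.approx(count / 2 ** n, rel=1e-12)

    def test_longest_run_sign_of_zero_positive(self):
        assert longest_run(np.array([1.0, 0.0, 2.0, -1.0])) == 3

    def test_cormap_on_curves(self):
        s = np.linspace(0.01, 0.1, 6)
        a = sk.ScatteringCurve(s=s, I=[1, 2, 1, 2, 1, 2])
        b = sk.ScatteringCurve(s=s, I=[2, 1, 2, 1, 2, 1])
        C, p = sk.cormap(a, b)
        assert C == 1
        assert p == 1.0

    @given(st.integers(min_value=1, max_value=3000),
           st.integers(min_value=1, max_value=40))
    @settings(max_examples=60, deadline=None)
    def test_p_monotone_decreasing_in_C(self, n, C):
        if C + 1 <= n:
            assert cormap_pvalue(n, C + 1) <= cormap_pvalue(n, C) + 1e-12


class TestAndersonDarling:
    @pytest.mark.parametrize("a2,p_expected", [
        (0.320, 0.9226),
        (0.611, 0.6374),
        (2.284, 0.0644),
    ])
    def test_asymptotic_p_values(self, a2, p_expected):
        assert ad_pvalue(a2) == pytest.approx(p_expected, abs=1e-3)

    def test_p_monotone_decreasing(self):
        grid = np.linspace(0.05, 11.9, 300)
        p = np.array([ad_pvalue(z) for z in grid])
        assert np.all(np.diff(p) <= 1e-12)

    def test_floor_above_12(self):
        assert ad_pvalue(12.5) == 0.0

    def test_statistic_on_normal_sample_is_moderate(self):
        rng = np.random.default_rng(17)
        r = rng.standard_normal(2000)
        a2 = ad_statistic(r)
        assert ad_pvalue(a2) > 0.01

    def test_shifted_curve_rejected(self):
        """A +5 sigma offset drives residuals to ~5 and the AD test rejects."""
        n = 200
        s = np.linspace(0.01, 0.5, n)
        a = sk.ScatteringCurve(s=s, I=np.full(n, 10.0),
                               sigma=np.full(n, 1.0))
        b = sk.ScatteringCurve(s=s, I=np.full(n, 10.0 + 5 * np.sqrt(2)),
                               sigma=np.full(n, 1.0))
        r = sk.residuals(a, b)
        np.testing.assert_allclose(r, -5.0, atol=1e-12)
        a2, p = sk.anderson_darling(a, b)
        assert p < 1e-6

    def test_small_n_warns(self):
        s = np.linspace(0.01, 0.05, 5)
        a = sk.ScatteringCurve(s=s, I=np.ones(5), sigma=np.ones(5))
        with pytest.warns(UserWarning, match="unreliable"):
            sk.anderson_darling(a, a)


class TestResiduals:
    def test_identical_curves_zero(self):
        c = sk.ScatteringCurve(s=[0.01, 0.02], I=[1.0, 2.0],
                               sigma=[0.1, 0.1])
        np.testing.assert_allclose(sk.residuals(c, c), 0.0)

    def test_calibrated_replicates_fraction_within_3(self):
        """Two independent replicates of one curve: >= 99% of standardized
        residuals in +/-3 at large n."""
        base = fx.sphere_curve(25.0, np.linspace(1e-3, 0.25, 2500), i0=1e4)
        a = fx.noisy_curve(base, noise=0.03, seed=11)
        b = fx.noisy_curve(base, noise=0.03, seed=12)
        frac = fraction_within(sk.residuals(a, b))
        assert frac >= 0.99


class TestTypeIError:
    def test_all_three_tests_calibrated_at_one_percent(self):
        """Comparing independent Poisson replicates of the same curve, each
        test rejects at alpha = 0.01 in ~1% of 1000 trials (3-sigma binomial
        band; CorMap is discrete so its attainable level sits at or below
        0.01)."""
        n, mu, trials = 500, 1000.0, 1000
        rng = np.random.default_rng(2024)
        s = np.linspace(0.01, 0.5, n)
        rej = {"chi2": 0, "cormap": 0, "ad": 0}
        for _ in range(trials):
            x1 = rng.poisson(mu, n).astype(float)
            x2 = rng.poisson(mu, n).astype(float)
            a = sk.ScatteringCurve(s=s, I=x1, sigma=np.sqrt(x1))
            b = sk.ScatteringCurve(s=s, I=x2, sigma=np.sqrt(x2))
            _, p_chi = sk.reduced_chi2(a, b)
            _, p_cor = sk.cormap(a, b)
            a2 = ad_statistic(sk.residuals(a, b))
            p_ad = ad_pvalue(a2)
            rej["chi2"] += p_chi < 0.01
            rej["cormap"] += p_cor < 0.01
            rej["ad"] += p_ad < 0.01
        for name, k in rej.items():
            rate = k / trials
            assert 0.001 <= rate <= 0.022, (name, rate)


class TestResample:
    def _curve(self, n=100, seed=3):
        base = fx.sphere_curve(20.0, np.linspace(1e-3, 0.2, n), i0=100.0)
        return fx.noisy_curve(base, noise=0.05, seed=seed)

    def test_zero_scale_is_identity(self):
        c = self._curve()
        reps = sk.resample_curve(c, 5, scale=0.0, seed=1)
        for r in reps:
            np.testing.assert_array_equal(r.I, c.I)
            np.testing.assert_array_equal(r.sigma, c.sigma)

    def test_seed_determinism(self):
        c = self._curve()
        a = sk.resample_curve(c, 3, seed=9)
        b = sk.resample_curve(c, 3, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.I, y.I)

    def test_replicate_spread_matches_scaled_sigma(self):
        c = self._curve()
        reps = sk.resample_curve(c, 1000, scale=1.5, seed=21)
        spread = np.std([r.I for r in reps], axis=0)
        # pointwise SD -> 1.5 sigma within Monte-Carlo error (~ few %)
        np.testing.assert_allclose(spread, 1.5 * c.sigma, rtol=0.15)

    def test_missing_sigma_rejected(self):
        c = fx.sphere_curve(20.0, np.linspace(1e-3, 0.2, 50), i0=1.0)
        with pytest.raises(ValueError):
            sk.resample_curve(c, 3)

    def test_rg_standard_error_validated_by_resampling(self):
        """SD of Guinier Rg over resampled replicates matches the regression
        standard error (the DATRG cross-validation workflow)."""
        base = fx.sphere_curve(30.0, np.linspace(2e-3, 0.12, 400), i0=1000.0)
        data = fx.noisy_curve(base, noise=0.02, seed=8)
        g0 = sk.guinier_fit(data, srg_limit=1.0)
        rgs = []
        for rep in sk.resample_curve(data, 300, seed=30):
            try:
                rgs.append(sk.guinier_fit(rep, srg_limit=1.0).rg)
            except ValueError:
                continue
        assert len(rgs) > 280
        sd = np.std(rgs)
        assert sd == pytest.approx(g0.rg_se, rel=0.35)
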