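"""TDI point estimation: binary search, exact and approximate forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from tdi import (
    ConfigurationError,
    DegenerateDistributionError,
    SearchSettings,
    solve_p1,
    tdi_inter,
    tdi_intra,
    tdi_msd_approx,
    tdi_ncx2_exact,
    tdi_probability_interval,
)

SIGMA_D = math.sqrt(2 * 52.867)


class TestSolveP1:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.80, 0.864), (0.85, 0.896), (0.90, 0.929), (0.95, 0.963)],
    )
    def test_blood_pressure_solutions(self, p, expected):
        """The four published upper-tail proportions of the case study."""
        p1 = solve_p1(2.174 / SIGMA_D, p)
        assert round(p1, 3) == expected

    @pytest.mark.parametrize("p", [0.5, 0.8, 0.9, 0.95, 0.99])
    def test_zero_ratio_is_exact_symmetric_solution(self, p):
        assert solve_p1(0.0, p) == (1 + p) / 2

    def test_inter_ratio_matches_grid_oracle(self):
        # frozen from a dense grid search over p1 at step 1e-7 using the
        # normal CDF directly
        p1 = solve_p1(2.174 / 7.2710, 0.90)
        assert p1 == pytest.approx(0.9219015, abs=2e-6)

    def test_defining_equation_holds_at_solution(self):
        tol = 1e-10
        for ratio in (0.05, 0.3, 1.2, 2.7):
            for p in (0.6, 0.9, 0.975):
                p1 = solve_p1(ratio, p, SearchSettings(tol=tol))
                z = ndtri(p1)
                assert abs(ndtr(z) - ndtr(-2 * ratio - z) - p) < tol

    def test_sign_of_ratio_irrelevant(self):
        assert solve_p1(-0.7, 0.9) == solve_p1(0.7, 0.9)

    def test_monotone_decreasing_in_ratio(self):
        """p1 falls from (1+p)/2 at zero ratio toward p as the bias grows:
        the interval recentres its mass into the tail nearer zero."""
        p1s = [solve_p1(r, 0.9) for r in np.linspace(0.01, 1.0, 15)]
        assert all(a > b for a, b in zip(p1s, p1s[1:]))
        # saturates at p (to within tolerance) once the bias dominates
        assert solve_p1(3.0, 0.9) == pytest.approx(0.9, abs=1e-6)
        assert all(0.9 < x < 0.95 for x in p1s)

    def test_iteration_count_within_logarithmic_bound(self):
        for tol in (1e-4, 1e-10):
            settings = SearchSettings(tol=tol)
            bound = math.ceil(math.log2(1 / tol)) + 5
            for ratio in (0.05, 0.21, 1.0, 2.9):
                for p in (0.5, 0.8, 0.9, 0.95, 0.99):
                    _, iters = solve_p1(ratio, p, settings, full_output=True)
                    assert iters <= bound

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad_p):
        with pytest.raises(ConfigurationError):
            solve_p1(0.5, bad_p)

    def test_settings_validation(self):
        with pytest.raises(ConfigurationError):
            SearchSettings(tol=0.5)
        with pytest.raises(ConfigurationError):
            SearchSettings(tol=1e-10, max_iter=3)


class TestProbabilityInterval:
    def test_blood_pressure_estimate(self):
        r = tdi_probability_interval(2.174, SIGMA_D, 0.90)
        assert r.kappa_hat == pytest.approx(17.29, abs=0.005)
        assert r.p1 == pytest.approx(0.929, abs=5e-4)

    def test_zero_mean_reduces_to_central_interval(self):
        for sigma, p in [(1.0, 0.9), (7.3, 0.8), (0.2, 0.99)]:
            r = tdi_probability_interval(0.0, sigma, p)
            assert r.kappa_hat == pytest.approx(sigma * ndtri((1 + p) / 2), rel=1e-12)
            assert r.p1 == (1 + p) / 2

    def test_table_truth_value(self):
        # mu=5, sigma=sqrt(2*52.867), p=0.95 -> log kappa = 3.105
        r = tdi_probability_interval(5.0, SIGMA_D, 0.95)
        assert math.log(r.kappa_hat) == pytest.approx(3.105, abs=5e-4)

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            tdi_probability_interval(1.0, 0.0, 0.9)

    @hyp_settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        mu=st.floats(-20, 20),
        sigma=st.floats(0.1, 30),
        p=st.floats(0.5, 0.99),
    )
    def test_defining_coverage_property(self, mu, sigma, p):
        """The mass of N(mu, sigma) inside (-kappa, kappa) equals p."""
        r = tdi_probability_interval(mu, sigma, p)
        mass = norm.cdf(r.kappa_hat, abs(mu), sigma) - norm.cdf(-r.kappa_hat, abs(mu), sigma)
        assert mass == pytest.approx(p, abs=1e-9)

    @hyp_settings(derandomize=True, max_examples=25, deadline=None)
    @given(mu=st.floats(0, 10), sigma=st.floats(0.5, 20), p=st.floats(0.5, 0.99))
    def test_symmetric_in_sign_of_mu(self, mu, sigma, p):
        a = tdi_probability_interval(mu, sigma, p).kappa_hat
        b = tdi_probability_interval(-mu, sigma, p).kappa_hat
        assert a == pytest.approx(b, rel=1e-12)

    def test_strictly_monotone_in_p_sigma_mu(self):
        ps = np.linspace(0.55, 0.98, 12)
        k_p = [tdi_probability_interval(1.0, 2.0, p).kappa_hat for p in ps]
        assert all(a < b for a, b in zip(k_p, k_p[1:]))
        sigmas = np.linspace(0.5, 8, 12)
        k_s = [tdi_probability_interval(1.0, s, 0.9).kappa_hat for s in sigmas]
        assert all(a < b for a, b in zip(k_s, k_s[1:]))
        mus = np.linspace(0, 6, 12)
        k_m = [tdi_probability_interval(m, 2.0, 0.9).kappa_hat for m in mus]
        assert all(a < b for a, b in zip(k_m, k_m[1:]))


class TestNcx2Exact:
    def test_zero_mean_low_variance_scenario(self):
        # sigma^2 = 32, p=0.80: log kappa = 1.981
        k = tdi_ncx2_exact(0.0, math.sqrt(32), 0.80)
        assert k == pytest.approx(7.2497, abs=2e-4)
        assert math.log(k) == pytest.approx(1.981, abs=5e-4)

    def test_standard_normal_central_quantile(self):
        assert tdi_ncx2_exact(0.0, 1.0, 0.95) == pytest.approx(1.95996, abs=1e-5)

    def test_identity_with_probability_interval_on_grid(self):
        """The two routes to the TDI agree to 1e-8 relative everywhere."""
        for ratio in np.linspace(0.0, 3.0, 20):
            for p in (0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.95, 0.99):
                sigma = 10.2827
                mu = ratio * sigma
                exact = tdi_ncx2_exact(mu, sigma, p)
                pi = tdi_probability_interval(mu, sigma, p).kappa_hat
                assert pi == pytest.approx(exact, rel=1e-8)


class TestMsdApprox:
    def test_exact_at_zero_mean(self):
        for sigma, p in [(3.0, 0.9), (10.0, 0.8)]:
            assert tdi_msd_approx(0.0, sigma, p) == pytest.approx(
                tdi_ncx2_exact(0.0, sigma, p), rel=1e-12
            )

    def test_closed_form_values(self):
        assert tdi_msd_approx(2.174, 10.2827, 0.90) == pytest.approx(17.29, abs=0.02)
        assert tdi_msd_approx(5.0, 5.6569, 0.80) == pytest.approx(9.68, abs=0.01)


class TestIntraInter:
    @pytest.mark.parametrize("p, expected", [(0.90, 16.9), (0.95, 20.2)])
    def test_intra_blood_pressure_values(self, p, expected):
        assert round(tdi_intra(52.867, p), 1) == expected

    def test_intra_scales_with_sqrt_variance(self):
        assert tdi_intra(4 * 52.867, 0.9) == pytest.approx(2 * tdi_intra(52.867, 0.9))

    def test_inter_paper_compat_reproduces_concordance_table(self):
        r = tdi_inter(
            2.174, math.sqrt(52.867), 0.90,
            mode="paper_compat", total_params=(2.174, SIGMA_D),
        )
        assert round(r.kappa_hat, 1) == 12.9

    def test_inter_strict_matches_grid_oracle(self):
        r = tdi_inter(2.174, math.sqrt(52.867), 0.90, mode="strict")
        assert r.kappa_hat == pytest.approx(12.4841, abs=1e-3)

    def test_modes_coincide_at_zero_mean(self):
        sigma_i = 3.0
        strict = tdi_inter(0.0, sigma_i, 0.9, mode="strict")
        compat = tdi_inter(0.0, sigma_i, 0.9, mode="paper_compat", total_params=(0.0, 5.0))
        expected = sigma_i * ndtri(0.95)
        assert strict.kappa_hat == pytest.approx(expected, rel=1e-12)
        assert compat.kappa_hat == pytest.approx(expected, rel=1e-12)

    def test_paper_compat_requires_total_params(self):
        with pytest.raises(ConfigurationError):
            tdi_inter(1.0, 2.0, 0.9, mode="paper_compat")
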