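"""Displacement densities: closed forms, route agreement, scaling laws."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy import special as sc

from superfbm.densities import (asymptotic_exponents, ctrw_pdf,
                                displacement_variance, gaussian_kernel,
                                ggbm_lambda_pdf, ggbm_pdf, pdf_u,
                                superstat_dx, superstat_dxx, superstat_dt,
                                superstat_pdf)
from superfbm.params import ModelParams, golding_cox_preset
from superfbm.special import kratzel


def mp(H=0.35, lambda0=1.0, nu=1.0, rho=1.0):
    return ModelParams(H=H, lambda0=lambda0, nu=nu, rho=rho)


class TestSuperstatPdf:
    @pytest.mark.parametrize("H", [0.25, 0.5, 0.75])
    @pytest.mark.parametrize("t", [0.5, 1.0, 3.0])
    def test_exponential_population_gives_laplace(self, H, t):
        # mixing Gaussians over an Exp(1) variance scale yields the Laplace
        # density (1/(2 t^H)) exp(-|x|/t^H)
        p = mp(H=H)
        for x in (-2.0, 0.4, 1.5):
            expected = 0.5 / t ** H * math.exp(-abs(x) / t ** H)
            assert superstat_pdf(x, t, p, route="kratzel") == pytest.approx(
                expected, rel=1e-8)

    def test_three_routes_agree(self):
        p = mp(nu=1.75, rho=1.25)
        x, t = 0.8, 1.0
        vals = [superstat_pdf(x, t, p, route=r)
                for r in ("mixture", "kratzel", "mellin-barnes")]
        assert vals[0] == pytest.approx(vals[1], rel=1e-6)
        assert vals[0] == pytest.approx(vals[2], rel=1e-6)

    def test_normalization(self):
        p = mp(nu=1.5, rho=1.75)
        val, _ = integrate.quad(lambda x: superstat_pdf(x, 2.0, p), -np.inf,
                                np.inf, limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_and_positivity(self):
        p = golding_cox_preset()
        sigma = math.sqrt(displacement_variance(1.0, p))
        for x in np.linspace(0.05, 10, 25) * sigma:
            a = superstat_pdf(x, 1.0, p)
            b = superstat_pdf(-x, 1.0, p)
            assert a > 0 and a == pytest.approx(b, rel=1e-12)

    def test_singularity_reported_at_origin_for_small_nu(self):
        with pytest.raises(ValueError, match="diverges"):
            superstat_pdf(0.0, 1.0, mp(nu=0.4, rho=0.9))
        # finite at the origin for nu > 1/2
        assert superstat_pdf(0.0, 1.0, mp(nu=0.9, rho=0.9)) > 0

    def test_degenerate_population_recovers_gaussian_kernel(self):
        # point-mass population == conditional Gaussian kernel
        lam, H, t = 0.7, 0.35, 2.0
        for x in (0.1, 0.5, 1.5):
            assert gaussian_kernel(x, t, lam, H) == pytest.approx(
                math.exp(-x * x / (4 * lam * t ** (2 * H)))
                / math.sqrt(4 * math.pi * lam * t ** (2 * H)), rel=1e-14)

    def test_self_similar_collapse_in_H(self):
        # sqrt(<x^2>) P plotted vs x/sqrt(<x^2>) is H-invariant
        base = mp(H=0.25, nu=1.5, rho=1.75)
        other = mp(H=0.75, nu=1.5, rho=1.75)
        for xi in (0.3, 1.0, 2.5):
            vals = []
            for p in (base, other):
                s = math.sqrt(displacement_variance(1.7, p))
                vals.append(s * superstat_pdf(xi * s, 1.7, p))
            assert vals[0] == pytest.approx(vals[1], rel=1e-8)


class TestRescaledDensity:
    def test_point_value_via_bessel_oracle(self):
        # nu = rho = 1: P(u) = 2 * (4 pi u)^{-1/2} Z_1^{1/2}(u), with the
        # factor 2 folding both displacement signs onto the half-line
        u = 1.0
        z = 2.0 * u ** 0.25 * sc.kv(0.5, 2.0)
        assert pdf_u(u, mp()) == pytest.approx(2 * z / math.sqrt(4 * math.pi * u),
                                               rel=1e-8)

    def test_unit_normalization(self):
        p = mp(nu=1.25, rho=1.5)
        val, _ = integrate.quad(lambda u: pdf_u(u, p), 0, 60.0,
                                points=[1e-6, 1.0], limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_free_of_H_and_lambda0(self):
        a = pdf_u(0.7, mp(H=0.2, lambda0=0.01, nu=1.3, rho=1.2))
        b = pdf_u(0.7, mp(H=0.8, lambda0=50.0, nu=1.3, rho=1.2))
        assert a == b

    def test_stretched_exponential_tail_dominates(self):
        # |log P(u) + (rho+1)(u/rho)^{rho/(rho+1)}| grows slower than the
        # leading term on u in [1e2, 1e3]
        for nu, rho in [(1.25, 1.5), (0.92, 0.92), (1.75, 1.25)]:
            p = mp(nu=nu, rho=rho)
            for u in (1e2, 1e3):
                lead = (rho + 1.0) * (u / rho) ** (rho / (rho + 1.0))
                rem = abs(math.log(pdf_u(u, p)) + lead)
                assert rem < 0.5 * lead


class TestVarianceAndAsymptotics:
    def test_exponential_unit_variance_point(self):
        assert displacement_variance(1.0, mp(H=0.25)) == pytest.approx(2.0,
                                                                       rel=1e-12)

    def test_matches_numerical_second_moment(self):
        p = mp(nu=1.5, rho=1.75)
        t = 3.0
        val, _ = integrate.quad(lambda x: x * x * superstat_pdf(x, t, p),
                                -np.inf, np.inf, limit=300)
        assert val == pytest.approx(displacement_variance(t, p), rel=1e-5)

    def test_loglog_slope_is_2H_for_preset(self):
        p = golding_cox_preset()
        slope = (math.log(displacement_variance(4.0, p))
                 - math.log(displacement_variance(1.0, p))) / math.log(4.0)
        assert slope == pytest.approx(0.70, abs=1e-12)

    @pytest.mark.parametrize("nu,expected_d", [(1.25, -0.5), (0.3, -0.7)])
    def test_small_u_exponent_rule(self, nu, expected_d):
        exps = asymptotic_exponents(mp(nu=nu, rho=1.1))
        assert exps.small_u == pytest.approx(expected_d)

    def test_stretch_exponent_and_degenerate_flag(self):
        exps = asymptotic_exponents(mp(nu=1.2, rho=1.0))
        assert exps.stretch == pytest.approx(0.5)
        assert asymptotic_exponents(mp(nu=0.5, rho=1.0)).degenerate


class TestComparisonModels:
    def test_ggbm_gaussian_collapse(self):
        # as 1/(2 rho) -> 1/2 the M-Wright order tends to the Gaussian closed
        # form; rho = 1 itself is outside the ggBm domain, so approach it
        lam0, H, t = 1.0, 0.35, 1.0
        for x in (0.2, 1.0, 2.0):
            s = math.sqrt(lam0) * t ** H
            expected = 0.5 / s * math.exp(-(x / s) ** 2 / 4) / math.sqrt(math.pi)
            assert ggbm_pdf(x, t, lam0, 1.0 + 1e-7, H) == pytest.approx(
                expected, rel=1e-4)

    def test_ggbm_normalization_and_symmetry(self):
        val, _ = integrate.quad(lambda x: ggbm_pdf(x, 1.0, 1.0, 1.43, 0.35),
                                -30, 30, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)
        assert ggbm_pdf(0.7, 1.0, 1.0, 1.43, 0.35) == ggbm_pdf(-0.7, 1.0, 1.0,
                                                               1.43, 0.35)

    def test_ggbm_domain_error(self):
        with pytest.raises(ValueError):
            ggbm_pdf(0.1, 1.0, 1.0, 0.9, 0.35)

    def test_ctrw_gaussian_at_half(self):
        lam0, t = 1.0, 2.0
        s = math.sqrt(lam0) * t ** 0.5
        for x in (0.0, 0.5, 1.5):
            expected = 0.5 / s * math.exp(-(x / s) ** 2 / 4) / math.sqrt(math.pi)
            assert ctrw_pdf(x, t, lam0, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_ctrw_normalization(self):
        val, _ = integrate.quad(lambda x: ctrw_pdf(x, 2.0, 1.0, 0.35), -40, 40,
                                limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ggbm_reduces_to_ctrw_at_matched_shape(self):
        H = 0.35
        for x, t in [(0.3, 1.0), (1.2, 2.0)]:
            assert ggbm_pdf(x, t, 1.0, 1.0 / (2 * H), H) == pytest.approx(
                ctrw_pdf(x, t, 1.0, H), rel=1e-10)

    def test_ggbm_lambda_population(self):
        # rho = 2 -> M_{1/2} closed form in lam
        lam0 = 1.0
        for lam in (0.2, 1.0, 2.5):
            expected = math.exp(-lam * lam / 4) / math.sqrt(math.pi) / lam0
            assert ggbm_lambda_pdf(lam, lam0, 2.0) == pytest.approx(expected,
                                                                    rel=1e-12)
        # integrate to the lam where the M-Wright tail exponent reaches 30
        beta = 1.0 / 1.6
        b = (1 - beta) * beta ** (beta / (1 - beta))
        cut = (30.0 / b) ** (1 - beta)
        val, _ = integrate.quad(lambda l: ggbm_lambda_pdf(l, 1.0, 1.6), 0, cut,
                                limit=200, epsabs=1e-9, epsrel=1e-8)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_ggbm_lambda_series_oracle_at_scale(self):
        import mpmath as mpm
        rho = 1.7
        with mpm.workdps(50):
            b = 1 / mpm.mpf(rho)
            oracle = float(sum((-mpm.mpf(1)) ** n / mpm.factorial(n)
                               * mpm.rgamma(-n * b + 1 - b) for n in range(400)))
        assert ggbm_lambda_pdf(1.0, 1.0, rho) == pytest.approx(oracle, rel=1e-10)


class TestAnalyticDerivatives:
    """Krätzel-recurrence derivatives against finite differences."""

    P = golding_cox_preset()

    def test_dx_and_dxx_match_finite_differences(self):
        x, t = 0.05, 1.0
        h = 1e-4
        fd1 = (superstat_pdf(x + h, t, self.P) - superstat_pdf(x - h, t, self.P)) / (2 * h)
        fd2 = (superstat_pdf(x + h, t, self.P) - 2 * superstat_pdf(x, t, self.P)
               + superstat_pdf(x - h, t, self.P)) / h ** 2
        assert superstat_dx(x, t, self.P) == pytest.approx(fd1, rel=1e-5)
        assert superstat_dxx(x, t, self.P) == pytest.approx(fd2, rel=1e-3)

    def test_dt_matches_finite_differences(self):
        x, t = 0.05, 1.0
        h = 1e-5
        fd = (superstat_pdf(x, t + h, self.P) - superstat_pdf(x, t - h, self.P)) / (2 * h)
        assert superstat_dt(x, t, self.P) == pytest.approx(fd, rel=1e-6)
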