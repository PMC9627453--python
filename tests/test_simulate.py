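"""fBm generator and ensemble diagnostics: exactness, scaling, ergodicity breaking."""

import math

import numpy as np
import pytest
from scipy import integrate, interpolate, stats

from superfbm.densities import superstat_pdf
from superfbm.params import ModelParams, ScalePopulation, gengamma_mean
from superfbm.simulate import (TrajectoryEnsemble, ensemble_tamsd,
                               rescale_ensemble, simulate_ensemble,
                               simulate_fbm, tamsd, tamsd_scatter)


class TestFbmGenerator:
    def test_brownian_increments_uncorrelated(self):
        paths = simulate_fbm(2 ** 12, 1.0, 0.5, seed=1)
        inc = np.diff(paths[0])
        r1 = np.corrcoef(inc[:-1], inc[1:])[0, 1]
        assert abs(r1) < 3.0 / math.sqrt(inc.size)

    def test_variance_matches_power_law(self):
        H = 0.35
        paths = simulate_fbm(256, 1.0, H, seed=2, n_paths=2000)
        for k in (8, 32, 64, 128, 256):
            emp = paths[:, k].var(ddof=1)
            theory = float(k) ** (2 * H)
            se = theory * math.sqrt(2.0 / (paths.shape[0] - 1))
            assert abs(emp - theory) < 3 * se, k

    def test_covariance_closed_form(self):
        H = 0.7
        paths = simulate_fbm(128, 1.0, H, seed=3, n_paths=4000)
        for s, t in [(16, 64), (32, 96), (64, 128)]:
            emp = np.mean(paths[:, s] * paths[:, t])
            th = 0.5 * (s ** (2 * H) + t ** (2 * H) - abs(t - s) ** (2 * H))
            sd = np.std(paths[:, s] * paths[:, t], ddof=1) / math.sqrt(
                paths.shape[0])
            assert abs(emp - th) < 3.5 * sd, (s, t)

    def test_increment_stationarity(self):
        H = 0.35
        paths = simulate_fbm(2 ** 10, 1.0, H, seed=4, n_paths=200)
        lag = 4
        early = (paths[:, lag] - paths[:, 0]).ravel()
        late = (paths[:, 512 + lag] - paths[:, 512]).ravel()
        assert stats.ks_2samp(early, late).pvalue > 0.01

    def test_seed_determinism_and_argument_validation(self):
        a = simulate_fbm(64, 0.5, 0.35, seed=9)
        b = simulate_fbm(64, 0.5, 0.35, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            simulate_fbm(1, 1.0, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_fbm(16, 1.0, 1.5, seed=0)


class TestEnsemble:
    def test_conditional_variance_and_stored_scales(self, preset):
        ens = simulate_ensemble(preset, 50, 128, 1.0, seed=7)
        assert ens.positions.shape == (50, 129)
        assert np.all(ens.positions[:, 0] == 0.0)
        assert ens.scales.shape == (50,)
        assert np.all(ens.scales > 0)

    def test_second_moment_matches_variance_law(self, preset):
        ens = simulate_ensemble(preset, 3000, 64, 1.0, seed=8)
        t = 64.0
        emp = np.mean(ens.positions[:, -1] ** 2)
        theory = 2.0 * gengamma_mean(ScalePopulation(preset)) * t ** (2 * preset.H)
        se = np.std(ens.positions[:, -1] ** 2, ddof=1) / math.sqrt(ens.n_traj)
        assert abs(emp - theory) < 3 * se

    def test_marginal_distribution_ks(self, preset):
        # single-time marginal against the analytic superstatistical density,
        # CDF tabulated once on a fine grid and interpolated
        ens = simulate_ensemble(preset, 5000, 8, 0.125, seed=9)
        x1 = ens.positions[:, -1]  # t = 1
        grid = np.linspace(0.0, 1.5 * np.abs(x1).max(), 1500)
        pdf_vals = np.array([superstat_pdf(g, 1.0, preset) for g in grid])
        half = integrate.cumulative_trapezoid(pdf_vals, grid, initial=0.0)
        cdf_abs = interpolate.interp1d(grid, np.minimum(2 * half, 1.0),
                                       bounds_error=False, fill_value=(0, 1))
        ks = stats.ks_1samp(np.abs(x1), lambda v: cdf_abs(v))
        assert ks.pvalue > 0.01

    def test_fixed_lambda_marginal_is_gaussian(self, preset):
        ens = simulate_ensemble(preset, 2000, 8, 0.125, seed=10,
                                fixed_lambda=preset.lambda0)
        x1 = ens.positions[:, -1]
        sigma = math.sqrt(2 * preset.lambda0)
        assert stats.kstest(x1, "norm", args=(0, sigma)).pvalue > 0.01

    def test_marginal_converges_with_ensemble_size(self, preset):
        def ks_stat(n):
            ens = simulate_ensemble(preset, n, 8, 0.125, seed=11)
            x1 = ens.positions[:, -1]
            sigma = math.sqrt(2 * preset.lambda0)
            return stats.kstest(x1, "norm", args=(0, sigma)).statistic

        # KS distance to the (wrong) Gaussian stabilizes, but to the true
        # law it must shrink: compare empirical CDFs at 500 vs 5000 against
        # a large reference sample
        ref = simulate_ensemble(preset, 8000, 8, 0.125, seed=12).positions[:, -1]
        d = {}
        for n in (500, 5000):
            ens = simulate_ensemble(preset, n, 8, 0.125, seed=13)
            d[n] = stats.ks_2samp(ens.positions[:, -1], ref).statistic
        assert d[5000] < d[500]

    def test_seed_determinism_bit_identical(self, preset):
        a = simulate_ensemble(preset, 10, 64, 1.0, seed=21)
        b = simulate_ensemble(preset, 10, 64, 1.0, seed=21)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.scales, b.scales)


class TestTamsd:
    def test_ballistic_trajectory_exact(self):
        v, dt = 1.7, 0.5
        x = v * np.arange(100) * dt
        curve = tamsd(x, dt, [1, 3, 7])
        assert np.allclose(curve.values, (v * curve.lags) ** 2, rtol=1e-12)

    def test_ensemble_average_slope_near_2H(self, het_ensemble, preset):
        lags = np.unique(np.round(np.geomspace(2, 64, 12)).astype(int))
        mean_curve = ensemble_tamsd(het_ensemble, lags).mean(axis=0)
        slope = np.polyfit(np.log(lags), np.log(mean_curve), 1)[0]
        assert abs(slope - 2 * preset.H) < 0.05

    def test_amplitude_tracks_trajectory_scale(self, preset):
        ens = simulate_ensemble(preset, 100, 2 ** 12, 1.0, seed=22)
        vals = ensemble_tamsd(ens, [10])[:, 0]
        r = np.corrcoef(vals, ens.scales)[0, 1]
        assert r > 0.9

    def test_lag_validation(self, het_ensemble):
        with pytest.raises(ValueError):
            tamsd(het_ensemble.positions[0], 1.0, [])
        with pytest.raises(ValueError):
            tamsd(het_ensemble.positions[0], 1.0, [het_ensemble.n_steps + 1])


class TestScatterAndRescaling:
    def test_heterogeneous_scatter_exceeds_homogeneous(self, het_ensemble,
                                                       hom_ensemble):
        het = tamsd_scatter(het_ensemble, 10)
        hom = tamsd_scatter(hom_ensemble, 10)
        assert het > 2.0 * hom

    def test_homogeneous_scatter_shrinks_with_length(self, preset):
        short = simulate_ensemble(preset, 100, 2 ** 8, 1.0, seed=23,
                                  fixed_lambda=preset.lambda0)
        long = simulate_ensemble(preset, 100, 2 ** 12, 1.0, seed=23,
                                 fixed_lambda=preset.lambda0)
        assert tamsd_scatter(long, 10) < tamsd_scatter(short, 10)

    def test_rescaling_reduces_scatter_by_half(self, het_ensemble):
        before = tamsd_scatter(het_ensemble, 10)
        after = tamsd_scatter(rescale_ensemble(het_ensemble), 10)
        assert after < 0.5 * before

    def test_rescaling_homogeneous_is_near_identity(self, hom_ensemble):
        resc = rescale_ensemble(hom_ensemble)
        ratio = resc.positions[:, 1:] / hom_ensemble.positions[:, 1:]
        amps = np.nanmedian(np.abs(ratio), axis=1)
        assert np.all(np.abs(amps - 1.0) < 0.35)

    def test_rescaling_gaussianizes_marginal(self, het_ensemble):
        x = het_ensemble.positions[:, 256]
        resc = rescale_ensemble(het_ensemble)
        y = resc.positions[:, 256]
        assert abs(stats.kurtosis(y)) < 0.5 * abs(stats.kurtosis(x))

    def test_short_ensemble_rejected(self, preset):
        ens = simulate_ensemble(preset, 5, 64, 1.0, seed=24)
        with pytest.raises(ValueError):
            rescale_ensemble(ens)

    def test_scatter_needs_two_trajectories(self, preset):
        ens = simulate_ensemble(preset, 1, 64, 1.0, seed=25)
        with pytest.raises(ValueError):
            tamsd_scatter(ens, 5)
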