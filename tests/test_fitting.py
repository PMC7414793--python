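"""Fitting-engine tests: binning, thresholding, chi2, parameter recovery."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import least_squares

from flimglia import (
    BelowThresholdError,
    BiExpParams,
    DomainError,
    FitConfig,
    GridMismatchError,
    bin_stack,
    chi2_reduced,
    fit_image,
    fit_pixel,
    model_decay,
    threshold_pixels,
)
from flimglia.fitting import _fit_decays, _grid_combos, _IrfConvolver

CFG = FitConfig(min_photons=0)
TRUTH = BiExpParams(a1=0.8, tau1=400.0, tau2=1150.0, amplitude=1e4)  # tau_m 550


def _poisson_batch(grid, irf, params, n, rng):
    curve = model_decay(params, irf, grid)
    return rng.poisson(np.broadcast_to(curve, (n, curve.size)))


class TestBinStack:
    def test_constant_stack_interior_nine_pixel_sum(self):
        stack = np.ones((4, 8, 8), dtype=np.uint16)  # 4 photons per pixel
        out = bin_stack(stack, 1)
        assert out.sum(axis=0)[4, 4] == 36
        assert out.sum(axis=0)[0, 0] == 16  # truncated corner: 2x2 window

    def test_zero_factor_is_identity(self, rng):
        stack = rng.integers(0, 50, size=(16, 10, 10))
        np.testing.assert_array_equal(bin_stack(stack, 0), stack)

    def test_single_pixel_support_is_window(self):
        stack = np.zeros((3, 15, 15), dtype=np.uint16)
        stack[:, 7, 7] = 5
        out = bin_stack(stack, 2).sum(axis=0)
        expected = np.zeros((15, 15), bool)
        expected[5:10, 5:10] = True
        np.testing.assert_array_equal(out > 0, expected)

    def test_matches_brute_force_window_sums(self, rng):
        stack = rng.integers(0, 30, size=(6, 9, 12))
        for b in (1, 2):
            out = bin_stack(stack, b)
            for y in range(9):
                for x in range(12):
                    ref = stack[
                        :, max(0, y - b) : y + b + 1, max(0, x - b) : x + b + 1
                    ].sum(axis=(1, 2))
                    np.testing.assert_array_equal(out[:, y, x], ref)

    def test_interior_scaling_and_conservation(self, rng):
        stack = np.full((8, 20, 20), 3, dtype=np.uint16)
        assert bin_stack(stack, 0).sum() == stack.sum()
        for b in (1, 2, 3):
            out = bin_stack(stack, b)
            k = (2 * b + 1) ** 2
            interior = out[:, b:-b, b:-b]
            np.testing.assert_array_equal(interior, 3 * k)


class TestThreshold:
    def test_examples(self):
        stack = np.zeros((1, 1, 3), dtype=np.int64)
        stack[0, 0] = [50, 200, 1000]
        np.testing.assert_array_equal(
            threshold_pixels(stack, 100), [[False, True, True]]
        )
        assert threshold_pixels(stack, 0).all()
        assert not threshold_pixels(stack, 1001).any()


class TestChi2:
    def test_perfect_fit_is_zero(self, grid, irf):
        m = model_decay(TRUTH, irf, grid)
        obs = m.copy()
        assert chi2_reduced(obs, m, 4) == 0.0

    def test_single_extra_photon_hand_computed(self, grid, irf):
        m = model_decay(TRUTH, irf, grid)
        obs = m.copy()
        k = int(np.argmax(m))
        obs[k] += 1.0
        c = obs[k]
        include = (m > 1e-12) | (obs > 0)
        dof = include.sum() - 4
        assert chi2_reduced(obs, m, 4) == pytest.approx((1.0 / c) / dof)

    def test_calibrated_on_well_populated_channels(self, grid, irf, rng):
        # Neyman chi2 ~ 1 where the Gaussian approximation holds
        # (expected >= 10 counts); ~120 pixels at >= 5000 photons
        p = replace(TRUTH, amplitude=8000.0)
        m = model_decay(p, irf, grid)
        mask = m >= 10
        vals = [
            chi2_reduced(rng.poisson(m), m, 0, channel_mask=mask)
            for _ in range(120)
        ]
        assert 0.8 < np.mean(vals) < 1.2

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(DomainError):
            chi2_reduced(np.ones(5), np.ones(5), 5)


class TestFitPixel:
    def test_noise_free_recovery_sub_permille(self, grid, irf):
        curve = model_decay(TRUTH, irf, grid)
        r = fit_pixel(curve, irf, grid, CFG)
        assert r.converged
        assert r.a1 == pytest.approx(TRUTH.a1, rel=1e-3)
        assert r.tau1 == pytest.approx(TRUTH.tau1, rel=1e-3)
        assert r.tau2 == pytest.approx(TRUTH.tau2, rel=1e-3)
        assert r.taum == pytest.approx(TRUTH.taum, rel=1e-3)
        # taum is exactly the identity of the fitted parameters
        assert r.taum == pytest.approx(
            r.a1 * r.tau1 + (1 - r.a1) * r.tau2, rel=1e-12
        )

    def test_poisson_1e5_within_two_percent(self, grid, irf, rng):
        p = replace(TRUTH, amplitude=1e5)
        obs = rng.poisson(model_decay(p, irf, grid))
        r = fit_pixel(obs, irf, grid, CFG)
        assert r.taum == pytest.approx(550.0, rel=0.02)

    def test_monoexponential_taum_identifiable(self, grid, irf, rng):
        # true a1 = 1 (pure 550 ps decay): components are degenerate but
        # tau_m must still come out within 2%
        p = BiExpParams(a1=1.0, tau1=550.0, tau2=551.0, amplitude=1e5)
        obs = rng.poisson(model_decay(p, irf, grid))
        r = fit_pixel(obs, irf, grid, CFG)
        assert r.taum == pytest.approx(550.0, rel=0.02)
        at_bound = r.a1 >= 0.99 or r.a1 <= 0.01
        assert at_bound or abs(r.tau1 - r.tau2) < 0.2 * r.taum

    def test_below_threshold_rejected(self, grid, irf):
        decay = np.zeros(grid.n_time_channels)
        decay[10] = 5
        with pytest.raises(BelowThresholdError):
            fit_pixel(decay, irf, grid, FitConfig(min_photons=100))


class TestEngineCrossChecks:
    def test_lm_beats_coarse_grid_oracle(self, grid, irf, rng):
        """Refined fit never ends above the exhaustive grid minimum."""
        cfg = FitConfig(min_photons=0, weighting="poisson")
        combos = _grid_combos()
        op = _IrfConvolver(irf.kernel, grid.channel_width)
        include = np.arange(grid.n_time_channels) >= irf.peak_channel - 3
        for _ in range(50):
            a1 = rng.uniform(0.2, 0.95)
            tau1 = rng.uniform(250, 700)
            tau2 = rng.uniform(900, 3000)
            p = BiExpParams(a1=a1, tau1=tau1, tau2=tau2, amplitude=1e4)
            y = rng.poisson(model_decay(p, irf, grid)).astype(float)
            w = 1.0 / np.maximum(y, 1.0)
            w[~include] = 0.0
            # independent oracle: enumerate the grid, profile the amplitude
            best = np.inf
            for ga1, gt1, gt2 in combos:
                c = (
                    ga1 * op.exp_conv(np.array([[gt1]]))
                    + (1 - ga1) * op.exp_conv(np.array([[gt2]]))
                )[0]
                A = max((w * y * c).sum() / (w * c * c).sum(), 0.0)
                best = min(best, (w * (y - A * c) ** 2).sum())
            res = _fit_decays(y[None, :], irf, grid, cfg)
            dof = include.sum() - cfg.n_free_params
            fitted = res["chi2_reduced"][0] * dof
            assert fitted <= best * (1 + 1e-6)

    def test_agrees_with_scipy_least_squares(self, grid, irf, rng):
        """Same weighted objective, independent optimizer, same optimum."""
        cfg = FitConfig(min_photons=0, weighting="poisson")
        op = _IrfConvolver(irf.kernel, grid.channel_width)
        include = np.arange(grid.n_time_channels) >= irf.peak_channel - 3
        for _ in range(5):
            y = rng.poisson(model_decay(replace(TRUTH, amplitude=3e4), irf, grid))
            y = y.astype(float)
            w = 1.0 / np.maximum(y, 1.0)
            w[~include] = 0.0
            sw = np.sqrt(w)

            def resid(q):
                a1, t1, t2 = q
                c = (
                    a1 * op.exp_conv(np.array([[t1]]))
                    + (1 - a1) * op.exp_conv(np.array([[t2]]))
                )[0]
                A = max((w * y * c).sum() / (w * c * c).sum(), 0.0)
                return (y - A * c) * sw

            ref = least_squares(
                resid, x0=[0.7, 400.0, 1000.0],
                bounds=([0, 100, 800], [1, 1000, 6000]),
            )
            mine = _fit_decays(y[None, :], irf, grid, cfg)
            taum_ref = ref.x[0] * ref.x[1] + (1 - ref.x[0]) * ref.x[2]
            assert mine["taum"][0] == pytest.approx(taum_ref, rel=0.01)

    def test_numba_and_numpy_engines_agree(self, grid, irf, rng):
        ys = _poisson_batch(grid, irf, replace(TRUTH, amplitude=3e4), 50, rng)
        fast = _fit_decays(ys, irf, grid, CFG)
        slow = _fit_decays(ys, irf, grid, replace(CFG, engine="numpy"))
        np.testing.assert_allclose(fast["taum"], slow["taum"], atol=0.5)
        np.testing.assert_allclose(fast["a1"], slow["a1"], atol=2e-3)

    def test_phasor_agrees_with_fitted_model(self, grid, irf, rng):
        """Fit-free phasor of the data matches the phasor of the fitted curve."""
        from flimglia import phasor_transform

        y = rng.poisson(model_decay(replace(TRUTH, amplitude=2e5), irf, grid))
        r = fit_pixel(y, irf, grid, CFG)
        fitted_curve = model_decay(
            BiExpParams(a1=r.a1, tau1=r.tau1, tau2=r.tau2, amplitude=float(y.sum())),
            irf,
            grid,
        )
        g_obs, s_obs = phasor_transform(y, grid)
        g_fit, s_fit = phasor_transform(fitted_curve, grid)
        assert g_obs == pytest.approx(g_fit, abs=0.01)
        assert s_obs == pytest.approx(s_fit, abs=0.01)

    def test_no_photon_count_bias_coupling(self, grid, irf, rng):
        """Recovered parameters uncorrelated with pixel brightness."""
        amps = rng.uniform(1e4, 1e5, size=200)
        curve = model_decay(replace(TRUTH, amplitude=1.0), irf, grid)
        ys = rng.poisson(amps[:, None] * curve[None, :])
        res = _fit_decays(ys, irf, grid, CFG)
        rho_taum = stats.spearmanr(res["total_photons"], res["taum"]).statistic
        rho_a1 = stats.spearmanr(res["total_photons"], res["a1"]).statistic
        assert abs(rho_taum) < 0.2
        assert abs(rho_a1) < 0.2


class TestFitImage:
    def test_spatially_invariant_input_gives_identical_fits(self, irf, grid):
        from flimglia import AcquisitionGrid

        g = AcquisitionGrid(height=6, width=6)
        curve = np.round(model_decay(replace(TRUTH, amplitude=2e4), irf, grid))
        stack = np.tile(curve[:, None, None], (1, 6, 6)).astype(np.uint16)
        maps = fit_image(stack, irf, g, FitConfig(min_photons=100, bin_factor=0))
        assert maps.valid_mask.all()
        assert np.ptp(maps.taum) == 0.0
        assert np.ptp(maps.a1) == 0.0

    def test_all_zero_stack_is_all_invalid(self, irf, grid):
        from flimglia import AcquisitionGrid

        g = AcquisitionGrid(height=4, width=4)
        stack = np.zeros((grid.n_time_channels, 4, 4), dtype=np.uint16)
        with pytest.warns(UserWarning):
            maps = fit_image(stack, irf, g, FitConfig(min_photons=10))
        assert not maps.valid_mask.any()
        assert np.isnan(maps.taum).all()

    def test_two_region_separation(self, irf, grid, rng):
        """550 ps vs 800 ps populations separate by >10 within-region SDs."""
        from flimglia import AcquisitionGrid, solve_tau2

        g = AcquisitionGrid(height=10, width=20)
        left = model_decay(replace(TRUTH, amplitude=2e4), irf, grid)
        p2 = BiExpParams(
            a1=0.8, tau1=400.0, tau2=solve_tau2(800.0, 0.8, 400.0), amplitude=2e4
        )
        right = model_decay(p2, irf, grid)
        lam = np.empty((grid.n_time_channels, 10, 20))
        lam[:, :, :10] = left[:, None, None]
        lam[:, :, 10:] = right[:, None, None]
        stack = rng.poisson(lam)
        maps = fit_image(stack, irf, g, FitConfig(min_photons=100, bin_factor=0))
        taum_l = maps.taum[:, :10]
        taum_r = maps.taum[:, 10:]
        sd = max(taum_l.std(), taum_r.std())
        assert taum_r.mean() - taum_l.mean() > 10 * sd

    def test_bit_identical_determinism(self, irf, grid, rng):
        from flimglia import AcquisitionGrid

        g = AcquisitionGrid(height=8, width=8)
        lam = model_decay(replace(TRUTH, amplitude=1500.0), irf, grid)
        stack = rng.poisson(np.broadcast_to(lam[:, None, None], (lam.size, 8, 8)))
        m1 = fit_image(stack, irf, g)
        m2 = fit_image(stack, irf, g)
        np.testing.assert_array_equal(m1.taum, m2.taum)
        np.testing.assert_array_equal(m1.a1, m2.a1)
        np.testing.assert_array_equal(m1.valid_mask, m2.valid_mask)

    def test_valid_mask_respects_threshold(self, irf, grid, rng):
        from flimglia import AcquisitionGrid

        g = AcquisitionGrid(height=4, width=4)
        lam = model_decay(replace(TRUTH, amplitude=300.0), irf, grid)
        stack = rng.poisson(np.broadcast_to(lam[:, None, None], (lam.size, 4, 4)))
        stack[:, 0, 0] = 0
        maps = fit_image(stack, irf, g, FitConfig(min_photons=200, bin_factor=0))
        assert not maps.valid_mask[0, 0]
        assert maps.valid_mask[2, 2]
        assert np.isnan(maps.taum[0, 0])

    def test_grid_mismatch_raises(self, irf, grid):
        stack = np.zeros((grid.n_time_channels + 1, 4, 4))
        with pytest.raises(GridMismatchError):
            fit_image(stack, irf, grid)


class TestFitConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(DomainError):
            FitConfig(bin_factor=-1)
        with pytest.raises(DomainError):
            FitConfig(weighting="magic")
        with pytest.raises(DomainError):
            FitConfig(init_strategy="prayer")

    def test_overlapping_tau_bounds_flagged(self):
        cfg = FitConfig(tau1_bounds=(100.0, 1000.0), tau2_bounds=(800.0, 6000.0))
        assert cfg.bounds_overlap
        cfg2 = FitConfig(tau1_bounds=(100.0, 700.0), tau2_bounds=(800.0, 6000.0))
        assert not cfg2.bounds_overlap
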