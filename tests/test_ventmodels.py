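"""Model fits, rate-density calibration and the SEM mean expectation."""

import numpy as np
import pytest

import washsem as w
from washsem.phantom import WashoutSeries
from washsem.ventmodels import _calibrate, sem_curve

from conftest import grid_oracle_deninger, grid_oracle_sem


def _voxel_series(values, n_extra_shape=(34, 34)):
    """Wrap per-frame scalars into a minimal one-hot-voxel series."""
    values = np.asarray(values, dtype=float)
    frames = np.zeros((len(values),) + n_extra_shape)
    frames[:, 5, 5] = values
    mask = np.zeros(n_extra_shape, dtype=bool)
    mask[5, 5] = True
    return WashoutSeries(frames=frames, breath_index=np.arange(len(values))), mask


class TestFitDeninger:
    def test_noiseless_voxel_recovered_exactly(self):
        series, mask = _voxel_series([1.0, 0.7, 0.49, 0.343])
        p = w.fit_deninger(series, mask)
        assert p.r_map[5, 5] == pytest.approx(0.300, abs=1e-6)
        assert p.s0_map[5, 5] == pytest.approx(1.000, abs=1e-6)

    def test_uniform_phantom_mean_recovered(self):
        t = w.make_phantom_truth(r_mean=0.22, r_sd=0.0, snr=float("inf"),
                                 n_images=8, seed=0)
        s = w.simulate_washout(t, model="deninger")
        p = w.fit_deninger(s, t.lung_mask)
        assert np.nanmean(p.r_map[t.lung_mask]) == pytest.approx(0.22, abs=1e-4)

    def test_matches_grid_oracle_on_noisy_voxels(self):
        rng = np.random.default_rng(7)
        n = np.arange(10, dtype=float)
        for _ in range(20):
            r, s0 = rng.uniform(0.1, 0.4), rng.uniform(0.8, 1.2)
            s = np.abs(s0 * (1 - r) ** n + 0.05 * rng.standard_normal(10))
            series, mask = _voxel_series(s)
            fit = w.fit_deninger(series, mask)
            _, r_oracle = grid_oracle_deninger(n, s)
            assert fit.r_map[5, 5] == pytest.approx(r_oracle, abs=1e-3)

    def test_all_zero_voxel_flagged_absent(self):
        series, mask = _voxel_series([1.0, 0.7, 0.49, 0.343])
        mask2 = mask.copy()
        mask2[6, 6] = True      # all-zero voxel
        p = w.fit_deninger(series, mask2)
        assert np.isnan(p.r_map[6, 6])

    def test_too_few_frames_rejected(self):
        series, mask = _voxel_series([1.0, 0.7])
        with pytest.raises(ValueError):
            w.fit_deninger(series, mask)

    def test_washin_order_rejected(self):
        series, mask = _voxel_series([1.0, 0.7, 0.49, 0.343])
        with pytest.raises(ValueError):
            w.fit_deninger(series.time_reversed(), mask)


class TestFitSem:
    def test_mono_exponential_limit_recovered(self):
        n = np.arange(8, dtype=float)
        series, mask = _voxel_series(np.exp(-0.2 * n))
        p = w.fit_sem(series, mask)
        assert p.rprime_map[5, 5] == pytest.approx(0.200, abs=1e-4)
        assert p.beta_map[5, 5] == pytest.approx(1.000, abs=1e-4)

    def test_uniform_phantom_pair_recovered(self):
        t = w.make_phantom_truth(r_mean=0.24, r_sd=0.0, beta_mean=0.90,
                                 beta_sd=0.0, snr=float("inf"), n_images=10, seed=0)
        s = w.simulate_washout(t, model="sem")
        p = w.fit_sem(s, t.lung_mask)
        assert np.nanmean(p.rprime_map[t.lung_mask]) == pytest.approx(0.24, abs=1e-3)
        assert np.nanmean(p.beta_map[t.lung_mask]) == pytest.approx(0.90, abs=1e-3)

    def test_matches_grid_oracle_on_noisy_voxels(self):
        rng = np.random.default_rng(11)
        n = np.arange(10, dtype=float)
        for _ in range(20):
            rp, b = rng.uniform(0.1, 0.35), rng.uniform(0.6, 0.98)
            s = np.abs(sem_curve(n, 1.0, rp, b) + 0.05 * rng.standard_normal(10))
            series, mask = _voxel_series(s)
            fit = w.fit_sem(series, mask)
            _, rp_oracle, b_oracle = grid_oracle_sem(n, s)
            assert fit.rprime_map[5, 5] == pytest.approx(rp_oracle, abs=1e-2)
            assert fit.beta_map[5, 5] == pytest.approx(b_oracle, abs=1e-2)


class TestRateDensity:
    @pytest.mark.parametrize("rprime,beta", [(0.22, 0.98), (0.24, 0.90), (0.14, 0.76)])
    def test_normalisation_after_B(self, rprime, beta):
        d = w.eval_density(rprime, beta)
        assert d.integral() == pytest.approx(1.0, abs=1e-3)
        assert np.all(d.p_values >= 0)

    @pytest.mark.parametrize("rprime,beta", [(0.22, 0.98), (0.24, 0.90), (0.14, 0.76)])
    def test_forward_laplace_reproduces_decay_within_0p05(self, rprime, beta):
        d = w.eval_density(rprime, beta)
        n = np.arange(13)
        forward = np.trapezoid(
            np.exp(-np.outer(n, d.r_grid)) * d.p_values, d.r_grid, axis=1)
        target = np.exp(-(n * rprime) ** beta)
        assert np.max(np.abs(forward - target)) < 0.05
        assert d.max_laplace_dev < 0.05

    def test_unimodal_with_mode_below_rprime(self):
        # the rate density peaks below r' and carries a heavy high-rate
        # tail, so mode < r' < expectation (reported peak locations sit
        # below the corresponding r' for all three gases)
        d = w.eval_density(0.24, 0.90)
        mode = d.r_grid[np.argmax(d.p_values)]
        assert mode < 0.24
        assert d.expectation() > 0.24
        peaks = np.flatnonzero(
            (np.diff(np.signbit(np.diff(d.p_values))).astype(int) > 0))
        assert len(peaks) == 1

    def test_branch_switch_adds_no_discontinuity_at_beta_half(self):
        # the auxiliary function changes branch at beta = 0.5; the density
        # must remain continuous there: the jump across 0.5 +/- 1e-3 may
        # not exceed the intrinsic smooth beta-sensitivity measured at
        # neighbouring beta values away from the branch point
        def jump(beta0):
            lo = w.eval_density(0.2, beta0 - 1e-3)
            hi = w.eval_density(0.2, beta0 + 1e-3)
            return np.max(np.abs(lo.p_values - hi.p_values)) / lo.p_values.max()

        baseline = 0.5 * (jump(0.45) + jump(0.55))
        assert jump(0.5) <= 1.2 * baseline
        assert jump(0.5) < 0.03

    def test_beta_near_one_rejected_in_eval(self):
        with pytest.raises(ValueError):
            w.eval_density(0.2, 0.999)


class TestRsemExpectation:
    def test_delta_limit_at_beta_one(self):
        assert w.rsem_expectation(0.31, 1.0) == pytest.approx(0.31)

    def test_rsem_at_least_rprime_on_parameter_grid(self):
        for rp in (0.1, 0.2, 0.3):
            for b in (0.7, 0.8, 0.9, 0.98):
                assert w.rsem_expectation(rp, b) >= rp - 1e-9

    def test_calibration_constants_roundtrip(self):
        B, C = w.calibrate_density_constants(0.76, 0.14)
        assert B > 0 and C >= 0
        B2, C2, dev = _calibrate(0.14, 0.76)
        assert (B, C) == (B2, C2)
        assert dev < 0.05

    def test_invalid_arguments_rejected(self):
        for rp, b in [(0.0, 0.9), (1.0, 0.9), (0.2, 0.0), (0.2, 1.1)]:
            with pytest.raises(ValueError):
                w.rsem_expectation(rp, b)


class TestAddRsem:
    def test_map_filled_only_where_fit_succeeded(self):
        t = w.make_phantom_truth(r_mean=0.2, r_sd=0.0, beta_mean=0.9,
                                 beta_sd=0.0, snr=float("inf"), n_images=10, seed=0)
        s = w.simulate_washout(t, model="sem")
        p = w.add_rsem(w.fit_sem(s, t.lung_mask))
        m = t.lung_mask
        assert np.all(np.isfinite(p.rsem_map[m]))
        assert np.all(np.isnan(p.rsem_map[~m]))
        # uniform truth: every voxel quantises to the same expectation
        expected = w.rsem_expectation(0.2, 0.9)
        assert np.nanmean(p.rsem_map[m]) == pytest.approx(expected, abs=5e-3)

    def test_requires_sem_maps(self):
        t = w.make_phantom_truth(seed=0)
        s = w.simulate_washout(t, model="deninger")
        p = w.fit_deninger(s, t.lung_mask)
        with pytest.raises(ValueError):
            w.add_rsem(p)
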