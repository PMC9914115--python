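"""K-space transforms, under-sampling masks, Hann filter, half-echo merge."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import washsem as w
from washsem.phantom import WashoutSeries
from washsem.sampling import hann_window


class TestLinesForAf:
    @pytest.mark.parametrize("af,n,expected", [
        (10, 64, 7), (14, 64, 5), (1, 64, 64), (2, 64, 32), (64, 64, 1),
    ])
    def test_line_counts(self, af, n, expected):
        assert w.lines_for_af(af, n) == expected

    def test_af_below_one_rejected(self):
        with pytest.raises(ValueError):
            w.lines_for_af(0.5, 64)

    @settings(deadline=None, max_examples=50)
    @given(af=st.floats(1.0, 64.0), n=st.integers(1, 256))
    def test_matches_ceiling_definition(self, af, n):
        import math
        assert w.lines_for_af(af, n) == math.ceil(n / af - 1e-12)


class TestMakeSamplingMask:
    def test_af10_counts_dc_and_variety(self):
        m = w.make_sampling_mask(8, 64, 10, "fgre", seed=3)
        assert m.pattern.shape == (8, 64)
        assert np.all(m.pattern.sum(axis=1) == 7)
        assert np.all(m.pattern[:, 32] == 1)          # DC always kept
        distinct = {tuple(row) for row in m.pattern}
        assert len(distinct) >= 2

    def test_af1_all_lines(self):
        m = w.make_sampling_mask(8, 64, 1, "fgre", seed=0)
        assert np.all(m.pattern == 1)

    def test_determinism_and_scheme_streams(self):
        a = w.make_sampling_mask(8, 64, 10, "fgre", seed=3)
        b = w.make_sampling_mask(8, 64, 10, "fgre", seed=3)
        c = w.make_sampling_mask(8, 64, 10, "xcentric", seed=3)
        assert np.array_equal(a.pattern, b.pattern)
        assert not np.array_equal(a.pattern, c.pattern)

    def test_union_coverage_exceeds_single_breath(self):
        m = w.make_sampling_mask(8, 64, 10, "fgre", seed=1)
        union = (m.pattern.sum(axis=0) > 0).sum()
        assert union > 7

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 2**20), af=st.sampled_from([4, 10, 14]),
           scheme=st.sampled_from(["fgre", "xcentric"]))
    def test_exact_density_for_every_seed_and_scheme(self, seed, af, scheme):
        m = w.make_sampling_mask(10, 64, af, scheme, seed)
        assert np.all(m.pattern.sum(axis=1) == w.lines_for_af(af, 64))

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            w.make_sampling_mask(8, 64, 10, "radial", seed=0)


class TestForwardKspace:
    def test_constant_image_concentrates_at_dc(self):
        frames = np.full((2, 64, 64), 3.0)
        s = WashoutSeries(frames=frames, breath_index=np.arange(2))
        k = w.forward_kspace(s)
        dc = k.frames[0][k.dc_index]
        assert abs(dc) == pytest.approx(3.0 * 64, rel=1e-12)
        off = k.frames[0].copy()
        off[k.dc_index] = 0
        assert np.abs(off).max() < 1e-10

    def test_round_trip_unitarity(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        back = w.ifft_recon(k)
        err = np.linalg.norm(back.frames - noisy_series.frames)
        assert err / np.linalg.norm(noisy_series.frames) < 1e-10

    def test_shifted_impulse_has_flat_magnitude_spectrum(self):
        frames = np.zeros((1, 64, 64))
        frames[0, 40, 21] = 1.0
        s = WashoutSeries(frames=frames, breath_index=np.arange(1))
        k = w.forward_kspace(s)
        mags = np.abs(k.frames[0])
        assert mags == pytest.approx(np.full((64, 64), 1.0 / 64), abs=1e-12)


class TestApplyMask:
    def test_af1_without_hann_is_identity(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        m = w.make_sampling_mask(noisy_series.n_images, 64, 1, "fgre", 0)
        out = w.apply_mask(k, m, hann=False)
        assert np.array_equal(out.frames, k.frames)

    def test_af10_leaves_exactly_seven_lines_per_frame(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        m = w.make_sampling_mask(noisy_series.n_images, 64, 10, "fgre", 0)
        out = w.apply_mask(k, m)
        for b in range(out.n_images):
            live_lines = np.abs(out.frames[b]).sum(axis=1) > 0
            assert live_lines.sum() == 7
            assert out.observed[b].sum() == 7 * 64

    def test_hann_impulse_reconstructs_window_transform(self):
        # an impulse image has flat k-space, so the Hann-filtered recon is
        # exactly the (unitary) inverse transform of the window itself
        frames = np.zeros((1, 64, 64))
        frames[0, 32, 32] = 1.0
        s = WashoutSeries(frames=frames, breath_index=np.arange(1))
        k = w.forward_kspace(s)
        m = w.make_sampling_mask(1, 64, 1, "fgre", 0)
        rec = w.ifft_recon(w.apply_mask(k, m, hann=True))
        kwin = w.forward_kspace(s)
        kwin.frames = (hann_window((64, 64)) / 64.0)[None].astype(complex)
        expected = w.ifft_recon(kwin)
        assert rec.frames == pytest.approx(expected.frames, abs=1e-12)

    def test_hann_never_increases_kspace_magnitude(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        m = w.make_sampling_mask(noisy_series.n_images, 64, 1, "fgre", 0)
        out = w.apply_mask(k, m, hann=True)
        assert np.all(np.abs(out.frames) <= np.abs(k.frames) + 1e-12)

    def test_dimension_mismatch_rejected(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        m = w.make_sampling_mask(noisy_series.n_images + 1, 64, 10, "fgre", 0)
        with pytest.raises(ValueError):
            w.apply_mask(k, m)


class TestXCentric:
    def test_split_then_merge_is_lossless(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        kp, kn = w.split_xcentric(k)
        merged = w.merge_xcentric(kp, kn)
        assert np.array_equal(merged.frames, k.frames)

    def test_each_half_covers_33_of_64_readout_samples(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        kp, kn = w.split_xcentric(k)
        for half in (kp, kn):
            cover = half.observed[0, 0]
            assert cover.sum() == 33            # ~50.5% of the readout window
            assert cover[k.dc_index[1]]

    def test_merge_with_empty_half_rejected(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        kp, kn = w.split_xcentric(k)
        kn.observed = np.zeros_like(kn.observed)
        with pytest.raises(ValueError):
            w.merge_xcentric(kp, kn)

    def test_merge_requires_coverage_masks(self, noisy_series):
        k = w.forward_kspace(noisy_series)
        kp, kn = w.split_xcentric(k)
        kn.observed = None
        with pytest.raises(ValueError):
            w.merge_xcentric(kp, kn)
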