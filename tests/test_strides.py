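"""Stride segmentation, resampling, median profiling, FMD depth and
representative-stride selection, checked against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from marchrisk import cohort as co
from marchrisk import strides as sd
from marchrisk.config import CohortConfig


def make_stride(values, duration=1.0, start=0.0, trial_id="t"):
    values = np.asarray(values, dtype=float)
    s = sd.Stride(
        source_trial_id=trial_id,
        start_time=start,
        duration=duration,
        stance_duration=duration / 2,
        raw_time=start + np.linspace(0.0, duration, len(values)),
        raw_grf=values,
    )
    s.grf_resampled = values if len(values) == 100 else None
    return s


def brute_median(mat):
    """Independent per-index sort-and-pick median (mean of central pair)."""
    out = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        col = np.sort(mat[:, j])
        n = len(col)
        out[j] = col[n // 2] if n % 2 else 0.5 * (col[n // 2 - 1] + col[n // 2])
    return out


def brute_depth(values, med):
    """Trapezoid rule written out longhand over normalized time."""
    d = np.abs(values - med)
    dx = 1.0 / (len(values) - 1)
    return sum(0.5 * (d[i] + d[i + 1]) * dx for i in range(len(d) - 1))


class TestLowpassFilter:
    fs = 1000.0

    def test_constant_signal_unchanged(self):
        x = np.full(2000, 7.5)
        assert np.allclose(sd.lowpass_filter(x, self.fs, 20.0), x)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 5, 1 / self.fs)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = sd.lowpass_filter(x, self.fs, 20.0)
        mid = slice(500, -500)
        assert np.abs(y[mid]).max() > 0.99

    def test_stopband_sinusoid_rejected(self):
        t = np.arange(0, 5, 1 / self.fs)
        x = np.sin(2 * np.pi * 200.0 * t)
        y = sd.lowpass_filter(x, self.fs, 20.0)
        assert np.abs(y[500:-500]).max() < 0.01

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sd.lowpass_filter(np.zeros(100), self.fs, 500.0)


class TestSegmentation:
    def test_square_wave_boundaries(self):
        fs = 1000.0
        dt = 1 / fs
        block = np.concatenate([np.full(250, 300.0), np.zeros(450)])
        grf = np.concatenate([np.zeros(100)] + [block] * 22)
        time = np.arange(len(grf)) * dt
        strides = sd.segment_strides(time, grf)
        assert len(strides) == 21
        for s in strides:
            assert s.duration == pytest.approx(0.70, abs=1e-9)
            assert s.stance_duration == pytest.approx(0.25, abs=2 * dt)

    def test_all_zero_signal_raises(self):
        time = np.arange(0, 5, 0.001)
        with pytest.raises(ValueError, match="no complete stride"):
            sd.segment_strides(time, np.zeros_like(time))

    def test_subthreshold_noise_raises(self):
        rng = np.random.default_rng(0)
        time = np.arange(0, 5, 0.001)
        noise = np.clip(rng.normal(0, 7, len(time)), -20, 20)
        with pytest.raises(ValueError, match="no complete stride"):
            sd.segment_strides(time, noise)

    def test_debounce_merges_micro_crossings(self):
        fs = 1000.0
        block = np.concatenate([np.full(250, 300.0), np.zeros(450)])
        grf = np.concatenate([np.zeros(100)] + [block] * 5)
        # a 10 ms dropout inside one stance must not split the contact
        grf[100 + 700 + 100 : 100 + 700 + 110] = 0.0
        time = np.arange(len(grf)) * (1 / fs)
        strides = sd.segment_strides(time, grf)
        assert len(strides) == 4
        assert all(abs(s.duration - 0.70) < 0.02 for s in strides)


class TestResampling:
    def test_linear_ramp_is_exact(self):
        s = make_stride(np.arange(0.0, 100.0), duration=1.0)
        s.grf_resampled = None
        sd.resample_stride(s, 100)
        grid = np.arange(100) * 1.0 / 100
        expected = np.interp(grid, np.linspace(0, 1, 100), np.arange(0.0, 100.0))
        assert np.allclose(s.grf_resampled, expected)
        assert s.grf_resampled[0] == 0.0  # first point is foot-strike

    def test_constant_stride(self):
        s = make_stride(np.full(700, 500.0), duration=0.7)
        sd.resample_stride(s, 100)
        assert np.all(s.grf_resampled == 500.0)

    def test_sine_interpolation_error_bound(self):
        duration = 0.7
        t = np.linspace(0, duration, 701)
        s = make_stride(np.sin(2 * np.pi * t / duration) * 1000, duration=duration)
        s.raw_time = t
        sd.resample_stride(s, 100)
        grid = np.arange(100) * duration / 100
        exact = np.sin(2 * np.pi * grid / duration) * 1000
        assert np.abs(s.grf_resampled - exact).max() < 0.005 * 1000

    def test_too_few_points_rejected(self):
        s = make_stride(np.arange(10.0))
        with pytest.raises(ValueError):
            sd.resample_stride(s, 1)


class TestMedianAndDepth:
    def test_single_stride_profile_is_itself(self, rng):
        s = make_stride(rng.normal(size=100))
        profile = sd.median_profile([s])
        assert np.array_equal(profile.values, s.grf_resampled)

    def test_median_robust_to_outlier(self):
        strides = [make_stride(np.full(100, v)) for v in (1.0, 2.0, 100.0)]
        profile = sd.median_profile(strides)
        assert np.all(profile.values == 2.0)

    def test_median_matches_brute_force(self, rng):
        mat = rng.normal(size=(20, 100))
        strides = [make_stride(row) for row in mat]
        profile = sd.median_profile(strides)
        assert np.allclose(profile.values, brute_median(mat))

    def test_depth_zero_iff_equal_to_profile(self, rng):
        values = rng.normal(size=100)
        profile = sd.MedianProfile(values=values.copy())
        assert sd.fmd_depth(values, profile) == 0.0
        assert sd.fmd_depth(values + 1e-3, profile) > 0.0

    def test_constant_offset_integrates_to_offset(self, rng):
        values = rng.normal(size=100)
        profile = sd.MedianProfile(values=values.copy())
        assert sd.fmd_depth(values + 10.0, profile) == pytest.approx(10.0)

    def test_depth_matches_brute_force(self, rng):
        mat = rng.normal(size=(15, 100))
        strides = [make_stride(row) for row in mat]
        profile = sd.median_profile(strides)
        med = brute_median(mat)
        for row in mat:
            assert sd.fmd_depth(row, profile) == pytest.approx(brute_depth(row, med))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sd.fmd_depth(np.zeros(99), sd.MedianProfile(values=np.zeros(100)))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        scale=hst.floats(min_value=0.1, max_value=100.0),
        seed=hst.integers(min_value=0, max_value=2**16),
    )
    def test_depth_scales_linearly_with_amplitude(self, scale, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=100)
        dev = rng.normal(size=100)
        profile = sd.MedianProfile(values=base)
        d1 = sd.fmd_depth(base + dev, profile)
        d2 = sd.fmd_depth(base + scale * dev, profile)
        assert d2 == pytest.approx(scale * d1, rel=1e-9)


class TestSelection:
    def test_identical_strides_select_first_with_zero_depth(self):
        strides = [make_stride(np.full(100, 3.0)) for _ in range(5)]
        result = sd.select_representative(strides)
        assert result.selected_index == 0
        assert result.depths[0] == 0.0

    def test_median_member_is_selected(self):
        strides = [make_stride(np.full(100, v)) for v in (3.0, 1.0, 2.0, 5.0, 4.0)]
        result = sd.select_representative(strides)
        assert result.selected_index == 0  # the constant-3 stride IS the median

    def test_selection_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            mat = rng.normal(size=(rng.integers(2, 26), 100))
            strides = [make_stride(row) for row in mat]
            result = sd.select_representative(strides)
            med = brute_median(mat)
            depths = [brute_depth(row, med) for row in mat]
            assert result.selected_index == int(np.argmin(depths))

    def test_shuffling_preserves_selected_content(self, rng):
        mat = rng.normal(size=(12, 100))
        strides = [make_stride(row) for row in mat]
        chosen = strides[sd.select_representative(strides).selected_index]
        order = rng.permutation(len(strides))
        shuffled = [strides[i] for i in order]
        chosen2 = shuffled[sd.select_representative(shuffled).selected_index]
        assert np.array_equal(chosen.grf_resampled, chosen2.grf_resampled)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sd.select_representative([])


class TestSpatiotemporal:
    def test_stride_length_arithmetic(self):
        s = make_stride(np.zeros(100), duration=0.70)
        s.stance_duration = 0.25
        summary = sd.spatiotemporal_summary(s, height=1.65, speed=3.0)
        assert summary.stride_length == pytest.approx(2.10)
        assert summary.normalized_stride_length == pytest.approx(1.27, abs=0.01)

    def test_doubling_height_halves_normalized_length(self):
        s = make_stride(np.zeros(100), duration=0.70)
        a = sd.spatiotemporal_summary(s, height=1.6)
        b = sd.spatiotemporal_summary(s, height=3.2)
        assert b.normalized_stride_length == pytest.approx(a.normalized_stride_length / 2)

    def test_zero_height_rejected(self):
        with pytest.raises(ValueError):
            sd.spatiotemporal_summary(make_stride(np.zeros(100)), height=0.0)

    def test_generator_round_trip_recovers_configured_stance(
        self, degenerate_cohort_config, rng
    ):
        cfg = degenerate_cohort_config
        dt = 1.0 / cfg.grf_sampling_rate
        subject = co.generate_subjects(cfg, rng)[0]
        for load, stance_mean in ((0.0, 0.25), (22.7, 0.29)):
            trial = co.generate_grf_trial(subject, load, cfg, rng)
            rep, _, _ = sd.representative_stride(trial.time, trial.vertical_grf)
            assert abs(rep.stance_duration - stance_mean) <= dt
            nsl = cfg.group_params["normalized_stride_length"][subject.sex][load][0]
            expected_duration = nsl * subject.height / cfg.speed
            assert rep.duration == pytest.approx(expected_duration, abs=2 * dt)
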