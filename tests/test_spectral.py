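"""Analytic checks of the filterbank-Hilbert power chain and the
epoch/normalize/select/summarize operations."""

import numpy as np
import pandas as pd
import pytest

from stopgamma import spectral as spc

RATE = 1000.0


class TestBandPower:
    def test_tone_power_equals_amplitude_squared(self):
        # amplitude A at band center -> envelope^2 ~ A^2 away from edges
        t = np.arange(int(20 * RATE)) / RATE
        for amp, f in [(1.0, 20.0), (2.5, 70.0)]:
            x = amp * np.sin(2 * np.pi * f * t)
            p = spc.band_power(x, RATE, (f - 5, f + 5))
            mid = p[int(5 * RATE): int(15 * RATE)]
            np.testing.assert_allclose(mid, amp**2, rtol=0.02)

    def test_zero_input_zero_power(self):
        assert np.all(spc.band_power(np.zeros(2000), RATE, (10, 20)) == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            spc.band_power(np.zeros(1000), 200.0, (90, 110))

    def test_envelope_flag(self):
        t = np.arange(int(8 * RATE)) / RATE
        x = 3.0 * np.sin(2 * np.pi * 30.0 * t)
        env = spc.band_power(x, RATE, (25, 35), squared=False)
        np.testing.assert_allclose(env[3000:5000], 3.0, rtol=0.02)

    def test_disjoint_bands_uncorrelated_on_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(30 * RATE))
        p1 = spc.band_power(x, RATE, (10, 16))
        p2 = spc.band_power(x, RATE, (60, 80))
        r = np.corrcoef(p1[5000:-5000], p2[5000:-5000])[0, 1]
        assert abs(r) < 0.1

    def test_band_limited_input_energy_captured(self):
        # filterbank energy invariant: input entirely inside one band
        rng = np.random.default_rng(1)
        n = int(20 * RATE)
        white = rng.standard_normal(n)
        x = spc.bandpass(white, RATE, (20, 24))
        p = spc.band_power(x, RATE, (18, 26))
        mid = slice(int(2 * RATE), int(18 * RATE))
        # mean envelope^2 == 2 x signal variance for a narrowband signal
        assert np.mean(p[mid]) / (2 * np.var(x[mid])) == pytest.approx(1.0, abs=0.1)


class TestSmoothPower:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(spc.smooth_power(np.full(500, 2.0), RATE), 2.0)

    def test_impulse_becomes_rectangle(self):
        x = np.zeros(1000)
        x[500] = 1.0
        y = spc.smooth_power(x, 1000.0, 100.0)
        assert np.isclose(y.max(), 1.0 / 100)
        assert np.sum(y > 1e-12) == 100
        assert y.sum() == pytest.approx(1.0)  # interior mass conserved


class TestEpoching:
    def _tf(self):
        vals = np.arange(3 * 400, dtype=float).reshape(3, 400)
        return spc.TFMap(vals, np.array([10.0, 20.0, 30.0]),
                         np.arange(400) / 200.0)

    def test_alignment_sample(self):
        tf = self._tf()
        ep, rel, kept = spc.epoch_tf(tf, [1.0], (-0.5, 0.5))
        i0 = np.argmin(np.abs(rel))
        assert rel[i0] == pytest.approx(0.0, abs=2.5e-3)
        np.testing.assert_array_equal(ep[0][:, i0], tf.values[:, 200])

    def test_out_of_range_dropped(self):
        tf = self._tf()
        ep, _, kept = spc.epoch_tf(tf, [0.1, 1.0, 1.95], (-0.5, 0.5))
        assert kept == [1]
        assert ep.shape[0] == 1

    def test_virtual_stop_definition(self, tiny_events):
        # taps at 0.97 and 1.88, cue at 2.587 -> virtual stop = 0.97 + 0.707
        vs = spc.virtual_stop_times(tiny_events, stop_delay_s=0.707)
        assert vs.loc[0] == pytest.approx(0.97 + 0.707)
        # with the measured per-trial delay the answer is the same here
        vs2 = spc.virtual_stop_times(tiny_events)
        assert vs2.loc[0] == pytest.approx(0.97 + (2.587 - 1.88))

    def test_regular_taps_exclude_first_and_last(self):
        rows = []
        for k, t in enumerate([1.0, 1.9, 2.8, 3.7], start=1):
            rows.append(("metronome", t, 0, k))
            rows.append(("tap_onset", t, 0, k))
        rows.append(("stop_cue", 4.4, 0, 0))
        ev = pd.DataFrame(rows, columns=["event_type", "time", "trial_idx", "tap_idx"])
        taps = spc.regular_tap_times(ev)
        np.testing.assert_allclose(taps, [1.9, 2.8])


class TestNormalization:
    def test_identity_and_doubling(self):
        base = np.ones((4, 5, 20)) * 2.0
        same = spc.normalize_to_regular_taps(base.copy(), base)
        np.testing.assert_allclose(same, 0.0)
        double = spc.normalize_to_regular_taps(2 * base, base)
        np.testing.assert_allclose(double, 100.0)

    def test_baseline_uses_only_given_epochs(self):
        # inflating an epoch that is excluded from the baseline set must not
        # change the normalization; including it must (direct mean oracle)
        rng = np.random.default_rng(0)
        taps = rng.uniform(1, 2, size=(6, 3, 10))
        target = rng.uniform(1, 2, size=(2, 3, 10))
        ref = spc.normalize_to_regular_taps(target, taps)
        inflated = np.concatenate([taps, 10 * taps[:1]], axis=0)
        changed = spc.normalize_to_regular_taps(target, inflated)
        expected = 100.0 * (target / inflated.mean(axis=(0, 2))[None, :, None] - 1.0)
        assert not np.allclose(ref, changed)
        np.testing.assert_allclose(changed, expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            spc.normalize_to_regular_taps(np.ones((1, 2, 3)), np.zeros((2, 2, 3)))

    def test_self_normalization_near_zero_mean(self):
        rng = np.random.default_rng(2)
        taps = rng.uniform(0.5, 1.5, size=(20, 4, 30))
        normed = spc.normalize_to_regular_taps(taps, taps)
        assert abs(normed.mean()) < 1e-9


class TestSelectBipolar:
    def test_flat_power_zero_index(self):
        from unittest import mock

        with mock.patch.object(spc, "band_power",
                               return_value=np.full(int(20 * RATE), 3.0)), \
             mock.patch.object(spc, "smooth_power", side_effect=lambda p, *_a, **_k: p):
            taps = np.arange(5.0, 15.0, 1.0)
            name, idx = spc.select_bipolar({"b1": np.zeros(int(20 * RATE))}, RATE,
                                           taps, 0.9)
        assert name == "b1"
        assert idx["b1"] == 0.0

    def test_raised_cosine_index_closed_form(self):
        # median time course m + (r/2) cos(...) -> (max-min)/mean = r/m
        from unittest import mock

        interval = 1.0
        rate = 200.0
        tgrid = np.arange(int(2 * interval * rate)) / rate
        m, r = 2.0, 0.8
        course = m + (r / 2) * np.cos(2 * np.pi * tgrid / (2 * interval))
        with mock.patch.object(spc, "band_power", return_value=np.tile(course, 10)), \
             mock.patch.object(spc, "smooth_power", side_effect=lambda p, *_a, **_k: p):
            taps = (np.arange(8) * 2 * interval) + interval
            _, idx = spc.select_bipolar({"b": np.zeros(int(20 * rate))}, rate, taps,
                                        interval)
        assert idx["b"] == pytest.approx(r / m, rel=1e-6)

    def test_modulated_pair_wins(self):
        # tap-locked 75 Hz modulation on pair 2 only -> pair 2 selected
        rng = np.random.default_rng(4)
        n = int(40 * RATE)
        t = np.arange(n) / RATE
        taps = np.arange(4.0, 36.0, 0.9)
        quiet = rng.standard_normal(n) * 0.3
        mod = rng.standard_normal(n) * 0.3
        for tap in taps:
            env = np.exp(-0.5 * ((t - tap) / 0.1) ** 2)
            mod += 0.8 * env * np.sin(2 * np.pi * 75.0 * t)
        name, idx = spc.select_bipolar({"p1": quiet, "p2": mod}, RATE, taps, 0.9)
        assert name == "p2"
        assert idx["p2"] > idx["p1"]


class TestBandSummaries:
    def test_band_timecourse_selection(self):
        vals = np.array([[1.0] * 4, [3.0] * 4, [10.0] * 4])
        freqs = np.array([10.0, 20.0, 30.0])
        np.testing.assert_allclose(
            spc.band_timecourse(vals, freqs, (15, 25)), 3.0)
        np.testing.assert_allclose(
            spc.band_timecourse(vals, freqs, (5, 25)), 2.0)  # (1+3)/2
        with pytest.raises(ValueError):
            spc.band_timecourse(vals, freqs, (40, 50))

    def test_peak_latency_gaussian_bump(self):
        times = np.arange(-0.5, 0.4, 0.005)
        tc = np.exp(-0.5 * ((times - 0.106) / 0.04) ** 2)
        assert spc.peak_latency(tc, times, (0.0, 0.32)) == pytest.approx(106.0, abs=5.0)

    def test_monotone_series_peaks_at_window_end(self):
        times = np.arange(0, 1.0, 0.005)
        lat = spc.peak_latency(times.copy(), times, (0.0, 0.5))
        assert lat == pytest.approx(495.0, abs=2.6)

    def test_flat_series_tie_breaks_earliest(self):
        times = np.arange(0, 1.0, 0.005)
        assert spc.peak_latency(np.ones_like(times), times, (0.1, 0.5)) == pytest.approx(100.0)

    def test_all_nan_window_missing(self):
        times = np.arange(0, 1.0, 0.01)
        tc = np.full_like(times, np.nan)
        assert np.isnan(spc.peak_latency(tc, times, (0.2, 0.4)))
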