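"""Behavioral quantification: tap detection, movement extent, outcome
classes, arrhythmia rule and per-tap covariates."""

import numpy as np
import pandas as pd
import pytest

from stopgamma.behavior import (
    BehaviorConfig,
    classify_outcome,
    derive_trial_table,
    detect_taps,
    exclude_arrhythmic,
    movement_extent,
    tap_metrics,
)

RATE = 1000.0


def _pulse_train(times, rate=RATE, dur=0.12, amp=1.0, total=None):
    total = total or (max(times) + 1.0)
    x = np.zeros(int(total * rate))
    for t in times:
        i0, i1 = int(t * rate), int((t + dur) * rate)
        x[i0:i1] = amp * np.sin(np.pi * np.arange(i1 - i0) / (i1 - i0))
    return x


class TestDetectTaps:
    def test_known_onsets_recovered_within_one_sample(self):
        # sharp-onset pulses: threshold crossing lands on the first sample
        times = [0.5, 1.4, 2.3, 3.2]
        x = np.zeros(int(4.5 * RATE))
        for t in times:
            x[int(t * RATE): int((t + 0.12) * RATE)] = 1.0
        taps = detect_taps(x, RATE)
        assert len(taps) == 4
        np.testing.assert_allclose(taps["onset"], times, atol=1.5 / RATE)

    def test_smooth_pulses_recovered_within_rise_time(self):
        times = [0.5, 1.4, 2.3, 3.2]
        taps = detect_taps(_pulse_train(times), RATE)
        assert len(taps) == 4
        np.testing.assert_allclose(taps["onset"], times, atol=0.02)

    def test_flat_pressure_gives_empty(self):
        taps = detect_taps(np.zeros(5000), RATE)
        assert len(taps) == 0

    def test_single_pulse_down_time(self):
        taps = detect_taps(_pulse_train([1.0], dur=0.12), RATE)
        assert len(taps) == 1
        # sinusoidal pulse crosses the hysteresis thresholds inside the
        # 120 ms contact; duration recovered within ~15%
        assert taps["down_time"].iloc[0] == pytest.approx(120.0, rel=0.2)


class TestMovementExtent:
    def _gon(self, depth_after, rate=RATE):
        """Full tap at 1.0 s (depth 60), post-cue bump of given depth at 2.6 s."""
        n = int(4.0 * rate)
        t = np.arange(n) / rate
        x = np.zeros(n)
        for c, d in [(1.0, 60.0), (2.6, depth_after)]:
            m = np.abs(t - c) < 0.225
            x[m] -= d * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 0.45))
        return x

    def test_full_tap_is_100_percent(self):
        ext = movement_extent(self._gon(60.0), RATE, 1.0, 2.4)
        assert ext == pytest.approx(100.0, abs=2.0)

    def test_no_movement_is_zero(self):
        ext = movement_extent(self._gon(0.0), RATE, 1.0, 2.4)
        assert ext == pytest.approx(0.0, abs=2.0)

    def test_halfway_interruption_is_50(self):
        # up 60 units, down 30 -> 50%
        ext = movement_extent(self._gon(30.0), RATE, 1.0, 2.4)
        assert ext == pytest.approx(50.0, abs=2.0)

    def test_degenerate_upward_amplitude_flagged(self):
        ext = movement_extent(np.zeros(4000), RATE, 1.0, 2.4)
        assert np.isnan(ext)

    def test_recovers_generator_latent_extent(self, small_dataset):
        # on synthetic data the measured extent matches the latent draw
        rec, events, trials, truth = small_dataset[0]
        gon = rec.channel("goniometer")
        errs = []
        for tr in truth["trials"]:
            ext = movement_extent(gon, rec.sample_rate, tr["tap_times"][-1],
                                  tr["stop_time"])
            errs.append(abs(ext - tr["movement_extent"]))
        assert np.median(errs) < 2.0


class TestClassifyOutcome:
    @pytest.mark.parametrize(
        "extent,touched,expected",
        [
            (7.0, False, "full"),
            (55.0, False, "intermediate"),
            (98.0, True, "failed"),
            (5.0, True, "failed"),  # touching the sensor always fails
            (9.999, False, "full"),
            (10.0, False, "intermediate"),
        ],
    )
    def test_partition(self, extent, touched, expected):
        assert classify_outcome(extent, touched) == expected


class TestArrhythmia:
    def _events(self, tap_offset_ms):
        rows = [
            ("metronome", 1.0, 0, 1), ("tap_onset", 1.0 + tap_offset_ms / 1000, 0, 1),
            ("metronome", 1.9, 0, 2), ("tap_onset", 1.9, 0, 2),
            ("stop_cue", 2.6, 0, 0),
        ]
        return pd.DataFrame(rows, columns=["event_type", "time", "trial_idx", "tap_idx"])

    def test_late_tap_flagged_and_trial_excluded(self):
        flagged, excluded = exclude_arrhythmic(self._events(310.0))
        assert flagged["flagged"].sum() == 1
        assert excluded == {0}

    def test_within_threshold_kept(self):
        flagged, excluded = exclude_arrhythmic(self._events(-290.0))
        assert flagged["flagged"].sum() == 0 and excluded == set()

    def test_on_grid_no_exclusions(self, behavior_draw):
        cfg, events, _, _ = behavior_draw
        grid = events.copy()
        # snap taps onto their metronome sounds
        metro = grid[grid["event_type"] == "metronome"].set_index(["trial_idx", "tap_idx"])["time"]
        is_tap = grid["event_type"] == "tap_onset"
        grid.loc[is_tap, "time"] = [
            metro[(r["trial_idx"], r["tap_idx"])] for _, r in grid[is_tap].iterrows()
        ]
        _, excluded = exclude_arrhythmic(grid)
        assert excluded == set()


class TestTapMetrics:
    def test_metrics_on_synthetic_subject(self, small_dataset):
        rec, events, trials, truth = small_dataset[0]
        tm = tap_metrics(events, rec)
        assert len(tm) == len(trials)
        # tapNr equals the generator's tap count per trial
        counts = {t["trial_idx"]: t["n_taps"] for t in truth["trials"]}
        for _, row in tm.iterrows():
            assert row["tapNr"] == counts[row["trial_idx"]]
        # soundOffset mean matches the anticipatory configuration (about -30 ms)
        assert -70 < tm["soundOffset"].mean() < 0
        assert (tm["peakVelDown"].dropna() < 0).all()
        assert (tm["maxPres"].dropna() > 0.5).all()

    def test_sound_offset_zero_for_on_grid_tap(self):
        rows = [
            ("metronome", 1.0, 0, 1), ("tap_onset", 1.0, 0, 1),
            ("metronome", 1.9, 0, 2), ("tap_onset", 1.9, 0, 2),
            ("stop_cue", 2.6, 0, 0),
        ]
        events = pd.DataFrame(rows, columns=["event_type", "time", "trial_idx", "tap_idx"])
        from stopgamma.core_io import Recording

        pres = _pulse_train([1.0, 1.9], total=4.0)
        gon = np.zeros(int(4 * RATE))
        t = np.arange(len(gon)) / RATE
        for c in (1.0, 1.9):
            m = np.abs(t - c) < 0.225
            gon[m] -= 60 * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - c) / 0.45))
        rec = Recording("s", ["pressure", "goniometer"], ["pressure", "goniometer"],
                        RATE, np.vstack([pres, gon]))
        tm = tap_metrics(events, rec)
        assert tm["soundOffset"].iloc[0] == pytest.approx(0.0, abs=1.0)
        assert tm["tapNr"].iloc[0] == 2


class TestDeriveTrialTable:
    def test_outcomes_match_generator(self, small_dataset):
        rec, events, trials, truth = small_dataset[1]
        derived = derive_trial_table(events, rec)
        merged = derived.merge(trials, on="trial_idx", suffixes=("_got", "_true"))
        agree = (merged["outcome_got"] == merged["outcome_true"]).mean()
        assert agree >= 0.9
        ok = ~merged["movement_extent_got"].isna()
        err = (merged.loc[ok, "movement_extent_got"]
               - merged.loc[ok, "movement_extent_true"]).abs()
        assert err.median() < 2.0

    def test_stop_delay_measured(self, small_dataset):
        rec, events, trials, _ = small_dataset[0]
        derived = derive_trial_table(events, rec)
        np.testing.assert_allclose(derived["stop_delay"], 707.0, atol=1.0)
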