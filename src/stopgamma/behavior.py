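"""Behavioral quantification: tap detection, movement extent, outcome
classification, arrhythmia exclusion and per-tap covariates.

Stopping performance is graded, not binary: *movement extent* is the
post-cue downward goniometer excursion as a percentage of the preceding
upward movement amplitude (0% = full stop, ~100% = failed stop, values may
exceed 100).  Stop trials partition into ``full`` (< 10% extent),
``intermediate`` (>= 10% but the pressure sensor was not touched) and
``failed`` (sensor touched).  Taps deviating more than 300 ms from their
metronome sound mark a trial arrhythmic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Recording, validate_trials

__all__ = [
    "BehaviorConfig",
    "detect_taps",
    "movement_extent",
    "classify_outcome",
    "exclude_arrhythmic",
    "tap_metrics",
    "derive_trial_table",
]

log = logging.getLogger(__name__)


@dataclass
class BehaviorConfig:
    arrhythmia_threshold: float = 300.0  # ms
    full_stop_threshold: float = 10.0  # percent
    pressure_onset_threshold: float = 0.3  # sensor units
    pressure_release_fraction: float = 0.5  # hysteresis: release below this x onset
    goniometer_smoothing: float = 20.0  # ms

    def validate(self) -> None:
        if self.arrhythmia_threshold <= 0 or self.full_stop_threshold <= 0:
            raise ValueError("thresholds must be > 0")


def detect_taps(
    pressure: np.ndarray, rate: float, cfg: BehaviorConfig | None = None
) -> pd.DataFrame:
    """Detect tap onsets/offsets from the force-sensor trace.

    Onsets are upward crossings of ``pressure_onset_threshold``; the
    matching offset is the fall below ``release_fraction * threshold``
    (hysteresis avoids double triggers on noisy plateaus).  Returns a frame
    with ``onset``, ``offset`` (s) and ``down_time`` (ms); empty if the
    sensor was never touched.
    """
    cfg = cfg or BehaviorConfig()
    x = np.asarray(pressure, dtype=np.float64)
    hi = cfg.pressure_onset_threshold
    lo = hi * cfg.pressure_release_fraction
    above = x >= hi
    onsets: list[int] = []
    offsets: list[int] = []
    in_tap = False
    for i in range(1, len(x)):
        if not in_tap and above[i] and not above[i - 1]:
            onsets.append(i)
            in_tap = True
        elif in_tap and x[i] < lo:
            offsets.append(i)
            in_tap = False
    if in_tap:
        offsets.append(len(x) - 1)
    rows = [
        dict(onset=i / rate, offset=j / rate, down_time=(j - i) / rate * 1000.0)
        for i, j in zip(onsets, offsets)
    ]
    return pd.DataFrame(rows, columns=["onset", "offset", "down_time"])


def _smooth(x: np.ndarray, rate: float, ms: float) -> np.ndarray:
    w = max(1, int(round(ms / 1000.0 * rate)))
    if w <= 1:
        return x
    return np.convolve(x, np.ones(w) / w, mode="same")


def movement_extent(
    gon: np.ndarray,
    rate: float,
    last_tap_time: float,
    stop_time: float,
    search_window_s: float = 0.9,
    cfg: BehaviorConfig | None = None,
) -> float:
    """Post-cue downward excursion as % of the preceding upward amplitude.

    The preceding upward amplitude is the rise from the last tap's flexion
    minimum to the apex reached before the stop cue; the downward excursion
    is measured from that apex level to the minimum within
    ``[stop_time, stop_time + search_window_s)`` (one metronome interval by
    default).  Returns NaN (trial to be flagged) when the preceding upward
    amplitude is degenerate.
    """
    cfg = cfg or BehaviorConfig()
    x = _smooth(np.asarray(gon, dtype=np.float64), rate, cfg.goniometer_smoothing)
    n = len(x)

    def seg(t0, t1):
        i0 = int(np.clip(round(t0 * rate), 0, n))
        i1 = int(np.clip(round(t1 * rate), 0, n))
        return x[i0:i1]

    prev = seg(last_tap_time - 0.35, last_tap_time + 0.35)
    pre_cue = seg(last_tap_time, stop_time)
    post = seg(stop_time, stop_time + search_window_s)
    if len(prev) == 0 or len(pre_cue) == 0 or len(post) == 0:
        return float("nan")
    apex = float(pre_cue.max())
    up_amp = apex - float(prev.min())
    if up_amp <= 1e-9:
        return float("nan")
    down = max(0.0, apex - float(post.min()))
    return 100.0 * down / up_amp


def classify_outcome(
    extent: float, pressure_touched: bool, cfg: BehaviorConfig | None = None
) -> str:
    """``failed`` iff the sensor was touched; else ``full`` iff extent < 10%."""
    cfg = cfg or BehaviorConfig()
    if pressure_touched:
        return "failed"
    if np.isnan(extent):
        return "intermediate"
    return "full" if extent < cfg.full_stop_threshold else "intermediate"


def exclude_arrhythmic(
    events: pd.DataFrame, cfg: BehaviorConfig | None = None
) -> tuple[pd.DataFrame, set[int]]:
    """Flag taps deviating > 300 ms from their metronome sound.

    Taps are paired with metronome events by ``(trial_idx, tap_idx)``.  The
    returned event table carries a boolean ``flagged`` column; the second
    return value is the set of trials with a flagged tap before the stop
    cue (those trials are excluded from analysis).
    """
    cfg = cfg or BehaviorConfig()
    events = events.copy()
    events["flagged"] = False
    thr = cfg.arrhythmia_threshold / 1000.0
    metro = events[events["event_type"] == "metronome"].set_index(["trial_idx", "tap_idx"])
    excluded: set[int] = set()
    stops = events[events["event_type"] == "stop_cue"].set_index("trial_idx")["time"]
    for i, row in events[events["event_type"] == "tap_onset"].iterrows():
        key = (row["trial_idx"], row["tap_idx"])
        if key not in metro.index:
            continue
        dev = abs(row["time"] - metro.loc[key, "time"])
        if dev > thr:
            events.loc[i, "flagged"] = True
            stop_t = stops.get(row["trial_idx"], np.inf)
            if row["time"] < stop_t:
                excluded.add(int(row["trial_idx"]))
    return events, excluded


def _peak_velocities(gon, rate, t0, t1, cfg):
    """Central-difference extrema of the (smoothed) goniometer in [t0, t1)."""
    x = _smooth(np.asarray(gon, dtype=np.float64), rate, cfg.goniometer_smoothing)
    i0 = int(np.clip(round(t0 * rate), 1, len(x) - 2))
    i1 = int(np.clip(round(t1 * rate), 1, len(x) - 2))
    if i1 <= i0:
        return np.nan, np.nan
    v = (x[i0 + 1 : i1 + 1] - x[i0 - 1 : i1 - 1]) * rate / 2.0
    return float(v.min()), float(v.max())  # down = most negative, up = most positive


def tap_metrics(
    events: pd.DataFrame,
    rec: Recording,
    cfg: BehaviorConfig | None = None,
) -> pd.DataFrame:
    """Covariates of the last regular tap of every stop trial.

    Columns: ``soundOffset`` (ms; negative = tap before the sound),
    ``downTime`` (ms contact duration), ``maxPres`` (peak pressure),
    ``tapNr`` (taps preceding the stop cue), ``peakVelDown`` / ``peakVelUp``
    (goniometer first-difference extrema) and ``upMvmt`` (upward movement
    amplitude after the tap).  Metrics whose source channel is missing come
    back NaN and are logged.
    """
    cfg = cfg or BehaviorConfig()
    cfg.validate()
    rate = rec.sample_rate
    have_pres = bool(rec.pick("pressure"))
    have_gon = bool(rec.pick("goniometer"))
    if not have_pres:
        log.warning("no pressure channel: downTime/maxPres missing")
    if not have_gon:
        log.warning("no goniometer channel: velocity/upMvmt missing")
    pres = rec.channel(rec.pick("pressure")[0]) if have_pres else None
    gon = rec.channel(rec.pick("goniometer")[0]) if have_gon else None
    taps_detected = detect_taps(pres, rate, cfg) if have_pres else pd.DataFrame()

    rows = []
    for trial, grp in events.groupby("trial_idx"):
        stops = grp[grp["event_type"] == "stop_cue"]
        if stops.empty:
            continue
        stop_t = float(stops["time"].iloc[0])
        taps = grp[(grp["event_type"] == "tap_onset") & (grp["time"] < stop_t)]
        if taps.empty:
            continue
        last = taps.loc[taps["time"].idxmax()]
        metro = grp[
            (grp["event_type"] == "metronome") & (grp["tap_idx"] == last["tap_idx"])
        ]
        sound_offset = (
            (last["time"] - float(metro["time"].iloc[0])) * 1000.0
            if len(metro)
            else np.nan
        )
        down_time = max_pres = np.nan
        if have_pres and len(taps_detected):
            near = (taps_detected["onset"] - last["time"]).abs()
            j = int(near.idxmin())
            if near[j] < 0.3:
                row = taps_detected.loc[j]
                down_time = float(row["down_time"])
                i0, i1 = int(row["onset"] * rate), int(row["offset"] * rate) + 1
                max_pres = float(np.max(pres[i0:i1]))
        vel_down = vel_up = up_mvmt = np.nan
        if have_gon:
            vel_down, _ = _peak_velocities(gon, rate, last["time"] - 0.3, last["time"] + 0.1, cfg)
            _, vel_up = _peak_velocities(gon, rate, last["time"], stop_t, cfg)
            x = _smooth(gon, rate, cfg.goniometer_smoothing)
            i0 = int(np.clip(round((last["time"] - 0.35) * rate), 0, len(x)))
            i1 = int(np.clip(round(stop_t * rate), 0, len(x)))
            if i1 > i0:
                lo = float(np.min(x[i0:i1]))
                i_lo = i0 + int(np.argmin(x[i0:i1]))
                up_mvmt = float(np.max(x[i_lo:i1]) - lo) if i1 > i_lo else np.nan
        rows.append(
            dict(
                trial_idx=int(trial),
                soundOffset=sound_offset,
                downTime=down_time,
                maxPres=max_pres,
                tapNr=int(taps["tap_idx"].max()),
                peakVelDown=vel_down,
                upMvmt=up_mvmt,
                peakVelUp=vel_up,
            )
        )
    return pd.DataFrame(rows)


def derive_trial_table(
    events: pd.DataFrame,
    rec: Recording,
    cfg: BehaviorConfig | None = None,
    search_window_s: float | None = None,
) -> pd.DataFrame:
    """Build the per-stop-trial outcome table from signals and events.

    For each stop trial: movement extent from the goniometer, sensor touch
    from post-cue pressure pulses, outcome classification, the tap-to-sound
    offset of the last regular tap, and the exclusion flag from the
    arrhythmia rule (or a degenerate extent).
    """
    cfg = cfg or BehaviorConfig()
    cfg.validate()
    rate = rec.sample_rate
    gon = rec.channel(rec.pick("goniometer")[0])
    pres = rec.channel(rec.pick("pressure")[0])
    taps_detected = detect_taps(pres, rate, cfg)
    _, excluded_trials = exclude_arrhythmic(events, cfg)

    # metronome interval estimated from the event stream (defines the
    # post-cue search window when not given)
    metro_t = events.loc[events["event_type"] == "metronome", "time"].to_numpy()
    if search_window_s is None:
        diffs = np.diff(np.sort(metro_t))
        search_window_s = float(np.median(diffs[diffs < 2.0])) if len(diffs) else 0.9

    rows = []
    for trial, grp in events.groupby("trial_idx"):
        stops = grp[grp["event_type"] == "stop_cue"]
        if stops.empty:
            continue
        stop_t = float(stops["time"].iloc[0])
        taps = grp[(grp["event_type"] == "tap_onset") & (grp["time"] < stop_t)]
        if taps.empty:
            continue
        last = taps.loc[taps["time"].idxmax()]
        last_t = float(last["time"])
        extent = movement_extent(gon, rate, last_t, stop_t, search_window_s, cfg)
        touched = bool(
            ((taps_detected["onset"] >= stop_t)
             & (taps_detected["onset"] < stop_t + search_window_s)).any()
        ) if len(taps_detected) else False
        outcome = classify_outcome(extent, touched, cfg)
        metro = grp[(grp["event_type"] == "metronome") & (grp["tap_idx"] == last["tap_idx"])]
        offset = (last_t - float(metro["time"].iloc[0])) * 1000.0 if len(metro) else np.nan
        rows.append(
            dict(
                trial_idx=int(trial),
                stop_time=stop_t,
                last_tap_time=last_t,
                stop_delay=(stop_t - last_t) * 1000.0,
                movement_extent=extent if not np.isnan(extent) else np.nan,
                outcome=outcome,
                tap_sound_offset=offset,
                excluded=bool(trial in excluded_trials or np.isnan(extent)),
            )
        )
    return validate_trials(pd.DataFrame(rows))
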