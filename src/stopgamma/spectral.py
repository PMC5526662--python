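"""Filterbank-Hilbert time-frequency power, epoching, baseline
normalization, bipolar selection and band summaries.

The filterbank follows the two-resolution scheme used for STN/EEG stop
data: 3 Hz-wide bands stepped by 1 Hz covering 3-40 Hz, and 10 Hz-wide
bands stepped by 2 Hz covering 50-120 Hz.  Each band is isolated with an
order-6 Butterworth high-pass plus low-pass, both applied forward and
backward (zero phase); power is the squared magnitude of the analytic
(Hilbert) signal, smoothed with a 100 ms centered moving average and
down-sampled to 200 Hz for all epoch-level work.

Per-trial epochs can be aligned to the stop cue, to tap onsets, or to the
*virtual stop* — the time the stop cue would have occurred had it been
delivered one tap earlier (second-to-last tap + stop delay), which provides
a movement-matched reference for the stop-cue response.

Percent-change normalization divides, per subject and frequency, by the
average power across all regular taps (excluding the first tap of a trial
and the tap directly followed by the stop cue).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import next_fast_len

from .preprocess import resample

__all__ = [
    "FilterbankSpec",
    "TFMap",
    "bandpass",
    "band_power",
    "smooth_power",
    "tf_power",
    "epoch_tf",
    "virtual_stop_times",
    "regular_tap_times",
    "baseline_from_epochs",
    "normalize_to_regular_taps",
    "select_bipolar",
    "band_timecourse",
    "peak_latency",
]

log = logging.getLogger(__name__)


@dataclass
class FilterbankSpec:
    """Two-resolution filterbank: (low, high) center frequencies and widths."""

    low_step: float = 1.0
    low_width: float = 3.0
    low_range: tuple[float, float] = (3.0, 40.0)
    high_step: float = 2.0
    high_width: float = 10.0
    high_range: tuple[float, float] = (50.0, 120.0)
    order: int = 6

    def low_centers(self) -> np.ndarray:
        lo, hi = self.low_range
        return np.arange(lo, hi + 1e-9, self.low_step)

    def high_centers(self) -> np.ndarray:
        lo, hi = self.high_range
        return np.arange(lo, hi + 1e-9, self.high_step)

    def bands(self, which: str = "both") -> list[tuple[float, float]]:
        """Band edges ``(lo, hi)`` for ``"low"``, ``"high"`` or ``"both"``."""
        out = []
        if which in ("low", "both"):
            out += [(c - self.low_width / 2, c + self.low_width / 2)
                    for c in self.low_centers()]
        if which in ("high", "both"):
            out += [(c - self.high_width / 2, c + self.high_width / 2)
                    for c in self.high_centers()]
        return out

    def centers(self, which: str = "both") -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.bands(which)])


@dataclass
class TFMap:
    """Frequency x time matrix with axis metadata.

    ``times`` are seconds relative to the alignment event (or absolute
    recording time for full-length maps); ``units`` is one of
    ``raw_power``, ``percent_change`` or ``ispc_change``.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    alignment: str = ""
    units: str = "raw_power"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.values.shape[-2:] != (len(self.freqs), len(self.times)):
            raise ValueError("values shape must match freqs x times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def bandpass(x: np.ndarray, rate: float, band: tuple[float, float], order: int = 6,
             ) -> np.ndarray:
    """Zero-phase band isolation: order-6 Butterworth band-pass, two-pass.

    A single band-pass design keeps the gain at the band center at unity
    (maximally flat passband), so a tone of amplitude A at the center
    survives with its amplitude intact; separate high-/low-pass stages at
    these narrow band widths would attenuate the passband center itself.
    """
    lo, hi = band
    nyq = rate / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"invalid band {band}")
    if hi >= nyq:
        raise ValueError(f"band {band} reaches Nyquist ({nyq} Hz)")
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(order, (lo, hi), btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def _analytic(x: np.ndarray) -> np.ndarray:
    n = len(x)
    return sps.hilbert(x, N=next_fast_len(n))[:n]


def band_power(x: np.ndarray, rate: float, band: tuple[float, float],
               order: int = 6, squared: bool = True) -> np.ndarray:
    """Hilbert power in one band: envelope**2 of the band-passed signal.

    ``squared=False`` returns the plain envelope (sensitivity probe).
    A pure tone of amplitude A at the band center yields ~A**2 away from
    the filter edges.
    """
    env = np.abs(_analytic(bandpass(x, rate, band, order)))
    return env**2 if squared else env


def smooth_power(power: np.ndarray, rate: float, window_ms: float = 100.0) -> np.ndarray:
    """Centered moving average (100 ms default).  Constant in, constant out.

    Edges are renormalized by the kernel mass actually inside the signal,
    so a constant stays constant everywhere; an interior impulse becomes a
    flat rectangle of width ``window`` and height ``1/window``.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    power = np.asarray(power, dtype=np.float64)
    w = max(1, int(round(window_ms / 1000.0 * rate)))
    if w == 1:
        return power.copy()
    kern = np.ones(w) / w
    mass = np.convolve(np.ones(power.shape[-1]), kern, mode="same")
    return np.apply_along_axis(
        lambda row: np.convolve(row, kern, mode="same") / mass, -1, power
    )


def tf_power(
    x: np.ndarray,
    rate: float,
    spec: FilterbankSpec | None = None,
    which: str = "both",
    smooth_ms: float = 100.0,
    out_rate: float = 200.0,
    subject_id: str = "",
) -> TFMap:
    """Full-recording time-frequency power map at the export rate (200 Hz).

    Band filtering and Hilbert power run at the input rate (high bands need
    >= 250 Hz Nyquist headroom); smoothing precedes the final downsampling.
    """
    spec = spec or FilterbankSpec()
    bands = spec.bands(which)
    rows = np.stack([band_power(x, rate, b, spec.order) for b in bands])
    rows = smooth_power(rows, rate, smooth_ms)
    if out_rate < rate:
        rows = resample(rows, rate, out_rate)
    times = np.arange(rows.shape[1]) / out_rate
    return TFMap(rows, spec.centers(which), times, alignment="recording",
                 units="raw_power", subject_id=subject_id)


# ---------------------------------------------------------------------------
# epoching and alignment
# ---------------------------------------------------------------------------


def epoch_tf(
    tf: TFMap, align_times: np.ndarray, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Cut per-trial epochs out of a full-recording map.

    Returns ``(epochs, rel_times, kept)`` where *epochs* is
    ``(n_kept, n_freq, n_t)``; trials whose window leaves the recording are
    dropped with a log entry.  ``rel_times`` obeys the half-open window
    convention; the sample at relative time 0 is the map sample nearest the
    alignment time.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window end must exceed start")
    dt = tf.times[1] - tf.times[0]
    fs = 1.0 / dt
    n_t = int(round((t1 - t0) * fs))
    rel = t0 + np.arange(n_t) / fs
    epochs, kept = [], []
    for k, at in enumerate(np.asarray(align_times, dtype=float)):
        i0 = int(round((at + t0 - tf.times[0]) * fs))
        if i0 < 0 or i0 + n_t > tf.values.shape[-1]:
            log.info("epoch %d at t=%.3f s outside recording; dropped", k, at)
            continue
        epochs.append(tf.values[..., i0 : i0 + n_t])
        kept.append(k)
    out = np.stack(epochs) if epochs else np.empty((0, len(tf.freqs), n_t))
    return out, rel, kept


def virtual_stop_times(events: pd.DataFrame, stop_delay_s: float | None = None
                       ) -> pd.Series:
    """Per stop trial: where the cue would have fallen one tap earlier.

    Virtual stop = second-to-last pre-cue tap + stop delay (per-trial
    measured delay if *stop_delay_s* is None).  Trials with fewer than two
    pre-cue taps are omitted.
    """
    out = {}
    for trial, grp in events.groupby("trial_idx"):
        stops = grp[grp["event_type"] == "stop_cue"]
        if stops.empty:
            continue
        stop_t = float(stops["time"].iloc[0])
        taps = np.sort(
            grp.loc[(grp["event_type"] == "tap_onset") & (grp["time"] < stop_t), "time"]
            .to_numpy()
        )
        if len(taps) < 2:
            continue
        delay = stop_delay_s if stop_delay_s is not None else stop_t - taps[-1]
        out[int(trial)] = taps[-2] + delay
    return pd.Series(out, name="virtual_stop", dtype=float)


def regular_tap_times(events: pd.DataFrame) -> np.ndarray:
    """Onsets of regular taps: all pre-cue taps except tap 1 and the tap
    directly followed by the stop cue (the baseline population)."""
    times = []
    for _, grp in events.groupby("trial_idx"):
        stops = grp[grp["event_type"] == "stop_cue"]
        stop_t = float(stops["time"].iloc[0]) if len(stops) else np.inf
        taps = grp[(grp["event_type"] == "tap_onset") & (grp["time"] < stop_t)]
        taps = taps.sort_values("time")
        if len(taps) <= 2:
            continue
        times.extend(taps["time"].iloc[1:-1].tolist())
    return np.asarray(times, dtype=float)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def baseline_from_epochs(tap_epochs: np.ndarray) -> np.ndarray:
    """Per-frequency mean over all regular-tap epochs and times."""
    if tap_epochs.ndim != 3 or tap_epochs.shape[0] == 0:
        raise ValueError("need at least one regular-tap epoch (trials x freq x time)")
    return tap_epochs.mean(axis=(0, 2))


def normalize_to_regular_taps(epochs: np.ndarray, tap_epochs: np.ndarray) -> np.ndarray:
    """Percent change relative to the regular-tap baseline.

    ``100 * (P / baseline_f - 1)`` with one baseline value per frequency.
    Raises on a zero/negative baseline (undefined normalization).
    """
    baseline = baseline_from_epochs(tap_epochs)
    if np.any(baseline <= 0):
        raise ValueError("regular-tap baseline must be positive for all frequencies")
    return 100.0 * (np.asarray(epochs, dtype=np.float64) / baseline[None, :, None] - 1.0)


# ---------------------------------------------------------------------------
# bipolar selection, band summaries
# ---------------------------------------------------------------------------


def select_bipolar(
    candidates: dict[str, np.ndarray],
    rate: float,
    tap_times: np.ndarray,
    tapping_interval_s: float,
    band: tuple[float, float] = (60.0, 90.0),
    smooth_ms: float = 100.0,
) -> tuple[str, dict[str, float]]:
    """Pick the bipolar contact pair with the strongest tap-locked gamma.

    Per candidate: 60-90 Hz Hilbert power, smoothed, median across taps of
    the time course in ``[tap - interval, tap + interval)`` (a window
    spanning twice the tapping interval); the modulation index is
    ``(max - min) / mean`` of that median time course.  Returns the argmax
    candidate and the index per candidate.
    """
    if not candidates:
        raise ValueError("need at least one candidate bipolar")
    tap_times = np.asarray(tap_times, dtype=float)
    if len(tap_times) < 2:
        raise ValueError("need at least two taps for bipolar selection")
    half = int(round(tapping_interval_s * rate))
    indices: dict[str, float] = {}
    for name, sig in candidates.items():
        p = smooth_power(band_power(sig, rate, band), rate, smooth_ms)
        segs = []
        for t in tap_times:
            i = int(round(t * rate))
            if i - half < 0 or i + half > len(p):
                continue
            segs.append(p[i - half : i + half])
        if not segs:
            raise ValueError("no tap window fits inside the recording")
        med = np.median(np.stack(segs), axis=0)
        m = med.mean()
        indices[name] = float((med.max() - med.min()) / m) if m > 0 else 0.0
    best = max(indices, key=indices.get)
    return best, indices


def band_timecourse(values: np.ndarray, freqs: np.ndarray,
                    band: tuple[float, float]) -> np.ndarray:
    """Mean over the frequency rows whose centers lie in ``[lo, hi]``."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} selects no frequency rows")
    return np.asarray(values, dtype=np.float64)[..., mask, :].mean(axis=-2)


def peak_latency(timecourse: np.ndarray, times: np.ndarray,
                 window: tuple[float, float]) -> float:
    """Latency (ms) of the maximum inside ``[start, end)``; ties -> earliest.

    NaN when the window contains no finite samples.
    """
    t0, t1 = window
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise ValueError("window selects no samples")
    seg = np.asarray(timecourse, dtype=np.float64)[mask]
    if np.all(np.isnan(seg)):
        return float("nan")
    return float(times[mask][np.nanargmax(seg)] * 1000.0)
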