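"""Intersite phase clustering (ISPC) between an STN seed and EEG targets.

ISPC over time: within a sliding window of n samples, take the phase
difference between the two band-passed, Hilbert-transformed signals at
every sample, map each onto the unit circle and measure the length of the
mean vector,

    ISPC = | sum_t exp(i * (phi_seed_t - phi_target_t)) / n |,

so 0 means uniformly scattered phase differences (no phase coupling) and 1
a fixed phase relation.  Amplitude does not enter.  Windows are 200 ms for
the 50-120 Hz bands and 250 ms for 6-40 Hz (more cycles at low
frequencies), stepped by 10 ms; bands below 6 Hz are excluded because a
250 ms window would contain barely one cycle.  Per-trial window values are
averaged over trials, then normalized by subtracting, per frequency, the
mean over the pre-cue baseline (-350 to 0 ms), keeping the no-change null
at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import FilterbankSpec, TFMap, bandpass, _analytic

__all__ = [
    "ISPCSpec",
    "instantaneous_phase",
    "ispc",
    "ispc_windows",
    "ispc_map",
    "normalize_ispc",
]


@dataclass
class ISPCSpec:
    window_high: float = 200.0  # ms, for bands >= split_hz
    window_low: float = 250.0  # ms
    step: float = 10.0  # ms
    low_freq_cutoff: float = 6.0  # Hz; lower bands are dropped
    split_hz: float = 50.0
    baseline: tuple[float, float] = (-0.350, 0.0)  # s relative to the cue

    def validate(self) -> None:
        if min(self.window_high, self.window_low, self.step) <= 0:
            raise ValueError("windows and step must be > 0")
        if self.step > min(self.window_high, self.window_low):
            raise ValueError("step must not exceed the window width")

    def window_for(self, center_freq: float) -> float:
        """Window width in seconds for a band centered at *center_freq*."""
        w = self.window_high if center_freq >= self.split_hz else self.window_low
        return w / 1000.0


def instantaneous_phase(x: np.ndarray, rate: float, band: tuple[float, float],
                        order: int = 6) -> np.ndarray:
    """Phase (radians, wrapped to (-pi, pi]) of the band-passed analytic signal."""
    return np.angle(_analytic(bandpass(x, rate, band, order)))


def ispc(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Mean-resultant length of the phase differences; in [0, 1].

    Invariant under adding any common constant to both series.
    """
    phase_a = np.asarray(phase_a, dtype=np.float64)
    phase_b = np.asarray(phase_b, dtype=np.float64)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    n = phase_a.size
    if n < 2:
        raise ValueError("need at least two samples")
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def ispc_windows(dphi_epochs: np.ndarray, rate: float, window_s: float,
                 step_s: float, rel_times: np.ndarray):
    """Sliding-window ISPC over per-trial phase-difference epochs.

    *dphi_epochs* is ``(n_trials, n_samples)``.  Windows of ``window_s``
    are stepped by ``step_s``; each value is timestamped at the window
    center.  Returns ``(values, centers)`` with *values*
    ``(n_trials, n_windows)``.
    """
    dphi = np.asarray(dphi_epochs, dtype=np.float64)
    w = max(2, int(round(window_s * rate)))
    s = max(1, int(round(step_s * rate)))
    n = dphi.shape[-1]
    if w > n:
        raise ValueError("epoch shorter than the ISPC window")
    starts = np.arange(0, n - w + 1, s)
    # cumulative sums of the unit phasors make every window an O(1) lookup
    z = np.exp(1j * dphi)
    cz = np.concatenate([np.zeros((*z.shape[:-1], 1), complex), np.cumsum(z, -1)], -1)
    vals = np.abs((cz[..., starts + w] - cz[..., starts]) / w)
    centers = rel_times[starts] + (w - 1) / (2.0 * rate)
    return vals, centers


def ispc_map(
    seed: np.ndarray,
    target: np.ndarray,
    rate: float,
    align_times: np.ndarray,
    epoch_window: tuple[float, float],
    spec: ISPCSpec | None = None,
    fbank: FilterbankSpec | None = None,
    which: str = "both",
) -> TFMap:
    """Trial-averaged ISPC between *seed* and *target* over sliding windows.

    Per band: phase of both signals over the whole recording, per-trial
    epochs around *align_times*, windowed ISPC per trial, then the mean
    over trials.  All bands share a 10 ms-step time grid of window centers;
    cells where a band's (wider) window does not fit are NaN.  Bands whose
    center is below ``spec.low_freq_cutoff`` are dropped.
    """
    spec = spec or ISPCSpec()
    spec.validate()
    fbank = fbank or FilterbankSpec()
    t0, t1 = epoch_window
    if not t1 > t0:
        raise ValueError("epoch window end must exceed start")
    align_times = np.asarray(align_times, dtype=float)
    n_samp = int(round((t1 - t0) * rate))
    rel = t0 + np.arange(n_samp) / rate

    bands = [b for b in fbank.bands(which)
             if (b[0] + b[1]) / 2.0 >= spec.low_freq_cutoff]
    centers_hz = np.array([(lo + hi) / 2 for lo, hi in bands])

    # common output grid: centers of the narrow (high-band) windows
    step_s = spec.step / 1000.0
    w_ref = min(spec.window_high, spec.window_low) / 1000.0
    w_ref_n = max(2, int(round(w_ref * rate)))
    ref_starts = np.arange(0, n_samp - w_ref_n + 1, max(1, int(round(step_s * rate))))
    grid = rel[ref_starts] + (w_ref_n - 1) / (2.0 * rate)

    n_total = len(seed)
    out = np.full((len(bands), len(grid)), np.nan)
    for bi, band in enumerate(bands):
        dphi_full = instantaneous_phase(seed, rate, band, fbank.order) - \
            instantaneous_phase(target, rate, band, fbank.order)
        epochs = []
        for at in align_times:
            i0 = int(round((at + t0) * rate))
            if i0 < 0 or i0 + n_samp > n_total:
                continue
            epochs.append(dphi_full[i0 : i0 + n_samp])
        if not epochs:
            raise ValueError("no epoch fits inside the recording")
        dphi = np.stack(epochs)
        vals, centers = ispc_windows(dphi, rate, spec.window_for(centers_hz[bi]),
                                     step_s, rel)
        mean_tc = vals.mean(axis=0)
        # place on the common grid by nearest center (same 10 ms step)
        for v, c in zip(mean_tc, centers):
            j = int(np.argmin(np.abs(grid - c)))
            if abs(grid[j] - c) < step_s:
                out[bi, j] = v
    return TFMap(out, centers_hz, grid, alignment="stop_cue", units="raw_power")


def normalize_ispc(tf: TFMap, baseline: tuple[float, float] = (-0.350, 0.0),
                   mode: str = "subtract") -> TFMap:
    """Baseline-normalize an ISPC map per frequency.

    ``subtract`` (default) keeps the no-change null at zero for the
    against-zero cluster test; ``ratio`` divides instead.
    """
    t0, t1 = baseline
    mask = (tf.times >= t0) & (tf.times < t1)
    if not mask.any():
        raise ValueError("baseline window selects no map columns")
    base = np.nanmean(tf.values[..., mask], axis=-1, keepdims=True)
    if mode == "subtract":
        vals = tf.values - base
    elif mode == "ratio":
        vals = tf.values / base
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TFMap(vals, tf.freqs, tf.times, alignment=tf.alignment,
                 units="ispc_change", subject_id=tf.subject_id)
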