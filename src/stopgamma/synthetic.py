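"""Synthetic stop-signal finger-tapping sessions with known ground truth.

Emulates the statistical structure the analysis assumes: a subject taps in
anticipation of an isochronous metronome (900 ms interval); after 5-9 taps a
stop cue is played at a fixed delay (707 ms) after the last registered tap,
timed so that stopping succeeds in roughly 55% of trials.  Channels carry
1/f background activity plus:

* a movement-locked beta (20 Hz) amplitude dip and a broad gamma increase on
  contralateral motor channels and the contralateral STN around every
  executed tap,
* a stop-locked gamma burst (70 Hz sinusoid under a Gaussian envelope) on
  the contralateral STN whose amplitude and peak latency depend on stopping
  outcome (earlier/larger on successful stops: 106 vs 179 ms),
* a slow 3-5 Hz evoked wave on Cz after every stop cue regardless of
  outcome (salience response),
* blink artifacts on the EOG channel leaked into EEG channels with fixed
  per-channel coefficients,
* goniometer flexion cycles truncated according to the latent movement
  extent, pressure pulses only for executed (regular or failed-stop) taps,
  and EMG bursts mirroring movement.

Every latent draw (outcome, burst amplitude/latency, extent, tap jitter) is
recorded in a ground-truth structure so downstream stages can be tested by
parameter recovery rather than against fixed patient data.

Determinism contract: identical :class:`SimConfig` (including ``seed``)
yields bit-identical outputs; per-subject streams are spawned from the
top-level seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import Recording, validate_events, validate_trials

__all__ = [
    "GammaBurstSpec",
    "SimConfig",
    "simulate_behavior",
    "simulate_signals",
    "simulate_dataset",
    "EEG_CHANNELS",
    "DEFAULT_EOG_LEAK",
]

EEG_CHANNELS = ["C3", "C4", "Cz", "Fz", "Pz", "Oz"]

#: Blink leakage coefficients: frontal channels pick up most of the EOG.
DEFAULT_EOG_LEAK = {"Fz": 0.15, "Cz": 0.08, "C3": 0.05, "C4": 0.05, "Pz": 0.03, "Oz": 0.01}


@dataclass
class GammaBurstSpec:
    """Stop-locked STN gamma burst parameters.

    Latencies are measured from the stop cue to the envelope peak;
    amplitudes are peak sinusoid amplitudes in units of the background
    signal SD.  Between-subject SDs perturb the subject-level means;
    trial SDs perturb individual bursts around the subject mean.
    """

    center_freq: float = 70.0  # Hz
    latency_success: float = 106.0  # ms
    latency_fail: float = 179.0  # ms
    latency_trial_sd: float = 25.0  # ms
    latency_subject_sd: float = 12.0  # ms
    amp_success: float = 0.6
    amp_fail: float = 0.25
    amp_trial_sd: float = 0.12
    amp_subject_sd: float = 0.08
    duration: float = 90.0  # ms, FWHM of the Gaussian envelope


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated cohort.

    Defaults mirror the task design: nine subjects, a 900 ms metronome,
    5-9 taps before the stop cue, a 707 ms cue delay after the last tap,
    ~55% stopping success, anticipatory taps (negative mean tap-to-sound
    offset) and a 2048 Hz acquisition rate.
    """

    n_subjects: int = 9
    n_stop_trials: int = 100
    metronome_interval: float = 900.0  # ms
    taps_per_trial: tuple[int, int] = (5, 9)
    stop_delay: float = 707.0  # ms
    success_prob: float = 0.55
    full_stop_prob: float = 0.3  # share of successful stops that are full (<10%)
    tap_offset_mean: float = -30.0  # ms; negative = anticipatory
    tap_jitter_sd: float = 40.0  # ms
    gamma_burst: GammaBurstSpec = field(default_factory=GammaBurstSpec)
    stop_locked_gamma: bool = True  # False = control condition (cue without stopping)
    beta_amp: float = 0.35
    beta_desync_depth: float = 0.6  # fractional amplitude drop around taps
    movement_gamma_amp: float = 0.2  # broader and weaker than the stop burst
    slow_evoked_amp: float = 1.2
    blink_rate: float = 10.0  # per minute
    blink_amp: float = 20.0
    eog_leak: dict = field(default_factory=lambda: dict(DEFAULT_EOG_LEAK))
    noise_exponent: float = 1.0  # 1/f^exponent background
    noise_amp: float = 1.0  # background SD
    # optional shared gamma carrier between STN and contralateral M1 that
    # collapses for 300 ms after each stop cue (ISPC-drop ground truth).
    # Off by default: the carrier itself is stop-locked band power and
    # would be conflated with the burst effects in the power contrasts.
    gamma_coupling_amp: float = 0.0
    gamma_coupling_band: tuple[float, float] = (65.0, 75.0)
    goniometer_amp: float = 60.0  # full-tap downward excursion, arbitrary units
    goniometer_noise_sd: float = 0.3
    pressure_amp: float = 1.0
    sample_rate: float = 2048.0
    intertrial_gap: float = 2.0  # s between stop cue and next trial's metronome
    lead_in: float = 5.0  # s of signal before the first metronome
    tapping_hand: str = "right"
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.success_prob <= 1.0 and 0.0 <= self.full_stop_prob <= 1.0):
            raise ValueError("probabilities must be in [0, 1]")
        lo, hi = self.taps_per_trial
        if not (1 <= lo <= hi):
            raise ValueError("taps_per_trial must be an increasing range >= 1")
        for name in ("metronome_interval", "stop_delay", "sample_rate"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.tap_jitter_sd < 0 or self.blink_rate < 0:
            raise ValueError("rates and SDs must be >= 0")


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def simulate_behavior(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Draw the behavioral event stream for one subject.

    Returns ``(events, trials, truth)``: a validated event table (metronome,
    tap onsets, stop cues), the latent per-trial outcome table, and a
    ground-truth dict recording every draw.  Taps sit at metronome times
    plus a Gaussian anticipatory offset; the stop cue follows the last
    registered tap by ``cfg.stop_delay``; the outcome is
    Bernoulli(``success_prob``); movement extent is drawn < 10% (full),
    in (10, 100] (intermediate) or near 100% (failed).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    interval = cfg.metronome_interval / 1000.0
    delay = cfg.stop_delay / 1000.0
    lo, hi = cfg.taps_per_trial

    ev_rows: list[tuple] = []
    tr_rows: list[dict] = []
    truth_trials: list[dict] = []
    t = cfg.lead_in
    for trial in range(cfg.n_stop_trials):
        n_taps = int(rng.integers(lo, hi + 1))
        metro = t + interval * np.arange(n_taps)
        offsets = cfg.tap_offset_mean / 1000.0 + rng.normal(
            0.0, cfg.tap_jitter_sd / 1000.0, size=n_taps
        )
        taps = metro + offsets
        for k in range(n_taps):
            ev_rows.append(("metronome", metro[k], trial, k + 1))
            ev_rows.append(("tap_onset", taps[k], trial, k + 1))
        last_tap = taps[-1]
        stop_time = last_tap + delay
        success = bool(rng.random() < cfg.success_prob)
        if success:
            if rng.random() < cfg.full_stop_prob:
                outcome = "full"
                extent = float(rng.uniform(0.0, 9.0))
            else:
                outcome = "intermediate"
                extent = float(rng.uniform(15.0, 75.0))
        else:
            outcome = "failed"
            extent = float(np.clip(rng.normal(97.0, 4.0), 80.0, 110.0))
        # the inhibited tap would have landed one metronome interval after
        # the last tap (plus its own anticipatory jitter)
        next_offset = cfg.tap_offset_mean / 1000.0 + rng.normal(
            0.0, cfg.tap_jitter_sd / 1000.0
        )
        would_be_tap = last_tap + interval + next_offset
        ev_rows.append(("stop_cue", stop_time, trial, 0))
        tr_rows.append(
            dict(
                trial_idx=trial,
                stop_time=stop_time,
                last_tap_time=last_tap,
                stop_delay=cfg.stop_delay,
                movement_extent=extent,
                outcome=outcome,
                tap_sound_offset=offsets[-1] * 1000.0,
                excluded=False,
            )
        )
        truth_trials.append(
            dict(
                trial_idx=trial,
                n_taps=n_taps,
                tap_times=taps,
                metronome_times=metro,
                stop_time=stop_time,
                success=success,
                outcome=outcome,
                movement_extent=extent,
                would_be_tap=would_be_tap,
            )
        )
        t = stop_time + cfg.intertrial_gap

    events = validate_events(
        pd.DataFrame(ev_rows, columns=["event_type", "time", "trial_idx", "tap_idx"])
    ).sort_values("time", kind="stable", ignore_index=True)
    trials = validate_trials(pd.DataFrame(tr_rows))
    truth = {
        "trials": truth_trials,
        "duration": t + 1.0,
        "config": cfg,
    }
    return events, trials, truth


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------


def _one_over_f_noise(rng, n, rate, exponent, amp):
    """Spectrally shaped Gaussian noise with PSD ~ 1/f**exponent, unit-free SD=amp."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    # flatten below 0.5 Hz so variance stays finite and drifts stay modest
    low = (freqs > 0) & (freqs < 0.5)
    shape[low] = 0.5 ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _gauss_envelope(times, center, fwhm_s):
    sigma = fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((times - center) / sigma) ** 2)


def _add_burst(sig, times, rate, center_t, freq, amp, fwhm_s, rng):
    """Add an amplitude-modulated sinusoid with Gaussian envelope in place."""
    if amp <= 0:
        return
    half = 4.0 * fwhm_s
    i0 = max(0, int((center_t - half) * rate))
    i1 = min(len(sig), int((center_t + half) * rate) + 1)
    if i1 <= i0:
        return
    tt = times[i0:i1]
    phase = rng.uniform(0, 2 * np.pi)
    sig[i0:i1] += amp * _gauss_envelope(tt, center_t, fwhm_s) * np.cos(
        2 * np.pi * freq * (tt - center_t) + phase
    )


def _add_bandnoise_burst(sig, rate, center_t, band, amp, fwhm_s, rng):
    """Broad-band noise burst (movement gamma): band-limited noise x envelope."""
    if amp <= 0:
        return
    half = 3.0 * fwhm_s
    i0 = max(0, int((center_t - half) * rate))
    i1 = min(len(sig), int((center_t + half) * rate) + 1)
    n = i1 - i0
    if n < 8:
        return
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    burst = np.fft.irfft(spec, n=n)
    sd = burst.std()
    if sd > 0:
        burst *= amp / sd
    tt = np.arange(i0, i1) / rate
    sig[i0:i1] += burst * _gauss_envelope(tt, center_t, fwhm_s)


def _blink_waveform(rate):
    # ~250 ms smooth positive deflection
    n = int(0.25 * rate)
    return np.hanning(n)


def _tap_bump(times, center, width_s):
    """Raised-cosine downward flexion bump of unit depth (0 outside)."""
    out = np.zeros_like(times)
    mask = np.abs(times - center) < width_s / 2.0
    out[mask] = 0.5 * (1.0 + np.cos(2.0 * np.pi * (times[mask] - center) / width_s))
    return out


def simulate_signals(cfg: SimConfig, events: pd.DataFrame, truth: dict) -> Recording:
    """Render the multichannel recording implied by a behavioral draw.

    Channel set: six scalp EEG (C3, C4, Cz, Fz, Pz, Oz), two bipolar STN
    LFPs (``STN_contra``/``STN_ipsi``), EOG, FDI EMG, pressure, goniometer.
    See the module docstring for the injected effect structure.  The stream
    of random draws is a deterministic function of the generator passed in
    ``truth["signal_rng"]`` (or ``cfg.seed`` when absent).
    """
    cfg.validate()
    rng = truth.get("signal_rng") or np.random.default_rng(cfg.seed + 1)
    rate = cfg.sample_rate
    n = int(np.ceil(truth["duration"] * rate))
    times = np.arange(n) / rate

    names = EEG_CHANNELS + ["STN_contra", "STN_ipsi", "EOG", "FDI", "pressure", "goniometer"]
    kinds = (
        ["eeg"] * 6 + ["lfp_bipolar"] * 2 + ["eog"] + ["emg"] + ["pressure"] + ["goniometer"]
    )
    data = np.zeros((len(names), n))
    idx = {nm: i for i, nm in enumerate(names)}

    # background 1/f on neural channels, white noise floor on the rest
    for nm in EEG_CHANNELS + ["STN_contra", "STN_ipsi"]:
        data[idx[nm]] = _one_over_f_noise(rng, n, rate, cfg.noise_exponent, cfg.noise_amp)
    data[idx["EOG"]] = rng.normal(0.0, 0.3 * cfg.noise_amp, n)
    data[idx["FDI"]] = rng.normal(0.0, 0.05, n)
    data[idx["goniometer"]] = rng.normal(0.0, cfg.goniometer_noise_sd, n)

    contra_m1 = "C3" if cfg.tapping_hand == "right" else "C4"

    # executed taps: regular taps in every trial, plus the inhibited tap of
    # failed stops (pressure touched) and partial flexion for intermediates
    gon = data[idx["goniometer"]]
    pres = data[idx["pressure"]]
    emg = data[idx["FDI"]]
    interval = cfg.metronome_interval / 1000.0
    burst = truth.setdefault("subject_effects", {})
    amp_succ = burst.get("amp_success", cfg.gamma_burst.amp_success)
    amp_fail = burst.get("amp_fail", cfg.gamma_burst.amp_fail)
    lat_succ = burst.get("latency_success", cfg.gamma_burst.latency_success)
    lat_fail = burst.get("latency_fail", cfg.gamma_burst.latency_fail)

    beta_env = np.ones(n)
    truth_bursts = []
    for tr in truth["trials"]:
        executed = [(tt, 1.0) for tt in tr["tap_times"]]
        extent = tr["movement_extent"]
        if extent > 1.0:  # any post-cue downward movement shows on the goniometer
            executed.append((tr["would_be_tap"], extent / 100.0))
        for tap_t, depth in executed:
            gon -= cfg.goniometer_amp * depth * _tap_bump(times, tap_t, 0.45)
            # movement-locked beta desynchronization + broad gamma on motor channels
            i0 = max(0, int((tap_t - 0.6) * rate))
            i1 = min(n, int((tap_t + 0.6) * rate) + 1)
            beta_env[i0:i1] *= 1.0 - cfg.beta_desync_depth * _gauss_envelope(
                times[i0:i1], tap_t, 0.25
            )
            for nm in (contra_m1, "STN_contra"):
                _add_bandnoise_burst(
                    data[idx[nm]], rate, tap_t, (55.0, 95.0),
                    cfg.movement_gamma_amp * depth, 0.3, rng,
                )
            if depth > 0.10:  # EMG mirrors actual movement
                _add_bandnoise_burst(emg, rate, tap_t, (30.0, min(150.0, rate / 2 - 5)),
                                     1.0 * depth, 0.15, rng)
            # pressure pulse only when the finger reaches the sensor
            touched = depth >= 0.80
            if touched:
                w = 0.12
                j0 = max(0, int(tap_t * rate))
                j1 = min(n, int((tap_t + w) * rate))
                peak = cfg.pressure_amp * float(np.clip(rng.normal(1.0, 0.1), 0.6, 1.5))
                pres[j0:j1] += peak * np.sin(np.pi * (np.arange(j1 - j0) / rate) / w)

        # stop-locked effects
        stop_t = tr["stop_time"]
        # slow (3-5 Hz) evoked wave on Cz, outcome-independent salience response
        _add_burst(
            data[idx["Cz"]], times, rate, stop_t + 0.15, 4.0, cfg.slow_evoked_amp, 0.30, rng
        )
        if cfg.stop_locked_gamma:
            if tr["success"]:
                mean_lat, mean_amp = lat_succ, amp_succ
            else:
                mean_lat, mean_amp = lat_fail, amp_fail
            lat = rng.normal(mean_lat, cfg.gamma_burst.latency_trial_sd) / 1000.0
            amp = max(0.0, rng.normal(mean_amp, cfg.gamma_burst.amp_trial_sd))
            _add_burst(
                data[idx["STN_contra"]],
                times,
                rate,
                stop_t + lat,
                cfg.gamma_burst.center_freq,
                amp,
                cfg.gamma_burst.duration / 1000.0,
                rng,
            )
            truth_bursts.append(
                dict(trial_idx=tr["trial_idx"], latency_ms=lat * 1000.0, amp=amp,
                     success=tr["success"])
            )
    truth["stop_bursts"] = truth_bursts

    # ongoing beta with movement-locked dips on motor structures
    beta_phase = rng.uniform(0, 2 * np.pi)
    beta = np.cos(2 * np.pi * 20.0 * times + beta_phase)
    for nm in (contra_m1, "STN_contra"):
        data[idx[nm]] += cfg.beta_amp * beta_env * beta

    # shared STN-M1 gamma carrier whose coherence (and power) collapses
    # briefly after each stop cue
    if cfg.gamma_coupling_amp > 0:
        white = rng.standard_normal(n)
        spec_w = np.fft.rfft(white)
        fgrid = np.fft.rfftfreq(n, d=1.0 / rate)
        lo_c, hi_c = cfg.gamma_coupling_band
        spec_w[(fgrid < lo_c) | (fgrid > hi_c)] = 0.0
        carrier = np.fft.irfft(spec_w, n=n)
        sd = carrier.std()
        if sd > 0:
            carrier *= cfg.gamma_coupling_amp / sd
        mask = np.ones(n)
        for tr in truth["trials"]:
            j0 = int(tr["stop_time"] * rate)
            j1 = min(n, j0 + int(0.3 * rate))
            mask[j0:j1] = 0.0
        data[idx["STN_contra"]] += carrier * mask
        data[idx[contra_m1]] += carrier * mask

    # blinks: shared waveform on EOG, leaked into EEG
    if cfg.blink_rate > 0:
        wave = _blink_waveform(rate)
        n_blinks = rng.poisson(cfg.blink_rate * times[-1] / 60.0)
        starts = rng.uniform(0, times[-1] - 0.3, size=n_blinks)
        eog = np.zeros(n)
        for s in np.sort(starts):
            j0 = int(s * rate)
            j1 = min(n, j0 + len(wave))
            eog[j0:j1] += cfg.blink_amp * wave[: j1 - j0]
        data[idx["EOG"]] += eog
        for nm, coef in cfg.eog_leak.items():
            if nm in idx:
                data[idx[nm]] += coef * eog

    return Recording(
        subject_id=str(truth.get("subject_id", "S0")),
        channel_names=names,
        channel_kinds=kinds,
        sample_rate=rate,
        data=data,
        tapping_hand=cfg.tapping_hand,
        reference="raw",
        meta={"synthetic": True, "seed": int(truth.get("seed", cfg.seed))},
    )


def simulate_dataset(cfg: SimConfig):
    """Simulate a cohort: one (Recording, events, trials, truth) per subject.

    Per-subject seeds are spawned deterministically from ``cfg.seed``;
    subject-level burst amplitude and latency means are drawn from normal
    distributions with the configured between-subject SDs.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_subjects)
    out = []
    for s, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        gb = cfg.gamma_burst
        effects = {
            "amp_success": max(0.0, rng.normal(gb.amp_success, gb.amp_subject_sd)),
            "amp_fail": max(0.0, rng.normal(gb.amp_fail, gb.amp_subject_sd)),
            "latency_success": rng.normal(gb.latency_success, gb.latency_subject_sd),
            "latency_fail": rng.normal(gb.latency_fail, gb.latency_subject_sd),
        }
        events, trials, truth = simulate_behavior(cfg, rng)
        truth["subject_id"] = f"S{s + 1}"
        truth["seed"] = cfg.seed
        truth["subject_effects"] = effects
        truth["signal_rng"] = rng
        rec = simulate_signals(cfg, events, truth)
        truth.pop("signal_rng")
        out.append((rec, events, trials, truth))
    return out


def control_config(cfg: SimConfig) -> SimConfig:
    """Control-condition variant: same cue stream, no stop-locked gamma."""
    return replace(cfg, stop_locked_gamma=False)
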