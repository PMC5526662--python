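"""Shared data model and on-disk formats for signals and task events.

A recording session is a channels-by-samples matrix with per-channel kind
labels (EEG, bipolar LFP, EOG, EMG, pressure sensor, goniometer, ...) plus
subject metadata.  Task events (metronome sounds, tap onsets, stop /
continue cues) and per-stop-trial behavioral outcomes live in plain pandas
DataFrames validated against a small schema.

Conventions used throughout the package:

* all times are seconds from recording start (display unit is ms),
* sample indices are 0-based,
* windows are half-open ``[start, end)``.

Signals are stored as a JSON sidecar header (channel names, kinds, rate,
metadata) next to a flat float64 channel-major binary payload; events and
trial tables are tab-separated text with a header row.  Both round-trip
exactly and produce deterministic bytes for identical input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CHANNEL_KINDS",
    "EVENT_TYPES",
    "OUTCOMES",
    "FormatError",
    "IntegrityError",
    "Recording",
    "read_signals",
    "write_signals",
    "read_events",
    "write_events",
    "read_trials",
    "write_trials",
    "validate_events",
    "validate_trials",
]

CHANNEL_KINDS = frozenset(
    {"eeg", "lfp_bipolar", "lfp_mono", "eog", "emg", "pressure", "goniometer", "sound"}
)
EVENT_TYPES = frozenset({"metronome", "tap_onset", "stop_cue", "continue_cue"})
OUTCOMES = frozenset({"full", "intermediate", "failed"})

EVENT_COLUMNS = ["event_type", "time", "trial_idx", "tap_idx"]
TRIAL_COLUMNS = [
    "trial_idx",
    "stop_time",
    "last_tap_time",
    "stop_delay",
    "movement_extent",
    "outcome",
    "tap_sound_offset",
    "excluded",
]


class FormatError(ValueError):
    """A file or table does not conform to the declared format."""


class IntegrityError(ValueError):
    """Header metadata and payload disagree (e.g. channel count mismatch)."""


@dataclass
class Recording:
    """Multichannel time series with per-channel kind labels.

    Parameters
    ----------
    subject_id
        Free-form subject label.
    channel_names, channel_kinds
        Parallel lists; names must be unique, kinds members of
        :data:`CHANNEL_KINDS`.
    sample_rate
        Sampling rate in Hz, > 0.
    data
        ``(n_channels, n_samples)`` real matrix.
    tapping_hand
        ``"left"`` or ``"right"``; resolves contra/ipsilateral labels.
    reference
        EEG reference state: ``"raw"``, ``"linked_earlobes"`` or
        ``"common_average"``.
    """

    subject_id: str
    channel_names: list[str]
    channel_kinds: list[str]
    sample_rate: float
    data: np.ndarray
    tapping_hand: str = "right"
    reference: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("data must be a channels x samples matrix")
        if len(self.channel_names) == 0:
            raise FormatError("recording must declare at least one channel")
        if len(self.channel_names) != len(self.channel_kinds):
            raise IntegrityError("channel_names and channel_kinds differ in length")
        if self.data.shape[0] != len(self.channel_names):
            raise IntegrityError(
                f"header declares {len(self.channel_names)} channels but payload "
                f"has {self.data.shape[0]} rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel names must be unique")
        for kind in self.channel_kinds:
            if kind not in CHANNEL_KINDS:
                raise FormatError(f"unknown channel kind {kind!r}")
        if not self.sample_rate > 0:
            raise FormatError("sample_rate must be > 0")
        if self.tapping_hand not in {"left", "right"}:
            raise FormatError("tapping_hand must be 'left' or 'right'")

    # -- convenience accessors -------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None
        return self.data[i]

    def kind_of(self, name: str) -> str:
        return self.channel_kinds[self.channel_names.index(name)]

    def pick(self, kind: str) -> list[str]:
        """Names of all channels of the given kind, in recording order."""
        return [n for n, k in zip(self.channel_names, self.channel_kinds) if k == kind]

    def with_data(self, data: np.ndarray, **changes) -> "Recording":
        """Copy with replaced payload (and optional metadata changes)."""
        return replace(self, data=np.asarray(data, dtype=np.float64), **changes)

    def add_channel(self, name: str, kind: str, samples: np.ndarray) -> "Recording":
        samples = np.asarray(samples, dtype=np.float64)
        if samples.shape != (self.n_samples,):
            raise IntegrityError("new channel length must match recording")
        return Recording(
            subject_id=self.subject_id,
            channel_names=self.channel_names + [name],
            channel_kinds=self.channel_kinds + [kind],
            sample_rate=self.sample_rate,
            data=np.vstack([self.data, samples[None, :]]),
            tapping_hand=self.tapping_hand,
            reference=self.reference,
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# signal container: JSON header + flat float64 payload
# ---------------------------------------------------------------------------


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".dat")


def write_signals(rec: Recording, path) -> None:
    """Write *rec* as ``<path>.json`` header + ``<path>.dat`` payload.

    Output bytes are deterministic for identical input (sorted JSON keys,
    channel-major little-endian float64 payload).
    """
    header_path, payload_path = _paths(path)
    header = {
        "format": "stopgamma-signals-v1",
        "subject_id": rec.subject_id,
        "channel_names": rec.channel_names,
        "channel_kinds": rec.channel_kinds,
        "sample_rate": rec.sample_rate,
        "n_samples": rec.n_samples,
        "tapping_hand": rec.tapping_hand,
        "reference": rec.reference,
        "dtype": "<f8",
        "meta": rec.meta,
    }
    header_path.write_text(json.dumps(header, sort_keys=True, indent=1) + "\n")
    payload_path.write_bytes(np.ascontiguousarray(rec.data, dtype="<f8").tobytes())


def read_signals(path) -> Recording:
    """Read a recording written by :func:`write_signals` (round-trip exact)."""
    header_path, payload_path = _paths(path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    header = json.loads(header_path.read_text())
    for key in ("channel_names", "channel_kinds", "sample_rate", "n_samples"):
        if key not in header:
            raise FormatError(f"header missing required field {key!r}")
    raw = np.frombuffer(payload_path.read_bytes(), dtype=header.get("dtype", "<f8"))
    n_chan = len(header["channel_names"])
    n_samp = int(header["n_samples"])
    if raw.size != n_chan * n_samp:
        raise IntegrityError(
            f"payload has {raw.size} values, header declares {n_chan}x{n_samp}"
        )
    return Recording(
        subject_id=header.get("subject_id", ""),
        channel_names=list(header["channel_names"]),
        channel_kinds=list(header["channel_kinds"]),
        sample_rate=float(header["sample_rate"]),
        data=raw.reshape(n_chan, n_samp).copy(),
        tapping_hand=header.get("tapping_hand", "right"),
        reference=header.get("reference", "raw"),
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# event / trial tables: TSV with header row
# ---------------------------------------------------------------------------


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an event table; returns it with canonical dtypes.

    Required columns: ``event_type`` (member of :data:`EVENT_TYPES`),
    ``time`` (s, >= 0), ``trial_idx`` (int >= 0), ``tap_idx`` (int; >= 1 for
    metronome/tap rows, 0 for cue rows).  Times must be non-decreasing within
    each trial and every stop cue must be preceded by a tap in its trial.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    events = events.copy()
    bad = set(events["event_type"]) - EVENT_TYPES
    if bad:
        raise FormatError(f"unknown event_type values {sorted(bad)}")
    events["time"] = events["time"].astype(float)
    events["trial_idx"] = events["trial_idx"].astype(int)
    events["tap_idx"] = events["tap_idx"].astype(int)
    if (events["time"] < 0).any():
        raise FormatError("event times must be non-negative")
    if (events["trial_idx"] < 0).any():
        raise FormatError("trial_idx must be >= 0")
    taps = events["event_type"].isin(["metronome", "tap_onset"])
    if (events.loc[taps, "tap_idx"] < 1).any():
        raise FormatError("tap_idx must be >= 1 for metronome/tap rows")
    for trial, grp in events.groupby("trial_idx"):
        t = grp["time"].to_numpy()
        if np.any(np.diff(np.sort(t)) < 0):  # pragma: no cover - sort is safe
            raise IntegrityError(f"times not sortable in trial {trial}")
        stops = grp[grp["event_type"] == "stop_cue"]
        if len(stops):
            first_stop = stops["time"].min()
            pre_taps = grp[(grp["event_type"] == "tap_onset") & (grp["time"] < first_stop)]
            if pre_taps.empty:
                raise IntegrityError(f"stop cue without preceding tap in trial {trial}")
    return events


def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events)[EVENT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_events(path) -> pd.DataFrame:
    """Read an event TSV; rows come back sorted ascending by time."""
    events = pd.read_csv(path, sep="\t")
    events = validate_events(events)
    return events.sort_values("time", kind="stable", ignore_index=True)


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise FormatError(f"trial table missing columns {missing}")
    trials = trials.copy()
    bad = set(trials["outcome"].dropna()) - OUTCOMES
    if bad:
        raise FormatError(f"unknown outcome values {sorted(bad)}")
    trials["excluded"] = trials["excluded"].astype(bool)
    ext = trials["movement_extent"].astype(float)
    if (ext.dropna() < 0).any():
        raise FormatError("movement_extent must be >= 0")
    full = trials["outcome"] == "full"
    if (ext[full].dropna() >= 10).any():
        raise IntegrityError("outcome 'full' requires movement_extent < 10")
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    cols = TRIAL_COLUMNS + [c for c in trials.columns if c not in TRIAL_COLUMNS]
    validate_trials(trials)[cols].to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_trials(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path, sep="\t"))
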