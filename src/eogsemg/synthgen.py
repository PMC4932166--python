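"""Seeded synthetic EOG-sEMG recordings with the structure the recognizer assumes.

The emulated device measures six synchronized channels at 1 kHz:

* ch1_dc / ch2_dc — the two cross-channel EOG DC traces.  Each electrode pair
  sees a mixture of the horizontal and vertical gaze components, so that
  CH1 - CH2 isolates the horizontal signal and CH1 + CH2 the vertical one.
* ch3_ac / ch4_ac — AC (high-passed) counterparts of CH1/CH2: transient
  deflections at saccade onset and offset, immune to slow baseline drift.
* ch5_emg / ch6_emg — right- and left-side facial sEMG.  A voluntary right
  blink energizes ch5 only, a left blink ch6 only, a bite both; an
  involuntary (normal) blink energizes both at a sub-threshold fraction of
  the voluntary amplitude and adds a vertical EOG transient.

Amplitudes are arbitrary normalized units; thresholds downstream are
expressed in the same units.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidScheduleError, RecordingParseError
from . import preprocess

LABELS = ("right", "left", "up", "down", "right_blink", "left_blink",
          "bite", "normal_blink", "none")

#: labels that the four-command interface must recognize, plus bite
COMMAND_LABELS = ("right", "left", "right_blink", "left_blink", "bite")

#: default event durations in seconds: gaze holds are longer than muscle bursts
DEFAULT_DURATIONS = {
    "right": 0.8, "left": 0.8, "up": 0.8, "down": 0.8,
    "right_blink": 0.3, "left_blink": 0.3, "bite": 0.3,
    "normal_blink": 0.2, "none": 0.5,
}


@dataclass
class EventSpec:
    """One scheduled action: a label, an onset, a duration and a relative
    amplitude scale (1.0 = the configured class amplitude)."""

    label: str
    onset: float
    duration: float
    amplitude_scale: float = 1.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {LABELS}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenConfig:
    """Generator parameters (all amplitudes in normalized signal units).

    The defaults are the study conditions used throughout the tests: a clean
    but non-trivial recording with slow drift, 60 Hz mains pickup, broadband
    sensor noise, horizontal saccades stronger than vertical ones, and
    involuntary blinks at 40% of the voluntary sEMG amplitude.
    """

    sampling_rate: float = 1000.0
    drift_rate: float = 0.01            # linear drift, units/s
    drift_walk_sigma: float = 0.005     # random-walk innovation, units/sqrt(s)
    line_noise_amp: float = 0.05        # 60 Hz mains amplitude
    white_noise_sigma: float = 0.02     # broadband sensor noise, per channel
    saccade_amplitude_h: float = 1.0    # horizontal gaze deflection
    saccade_amplitude_v: float = 0.6    # vertical deflection (weaker, slower)
    emg_burst_amp: float = 1.0          # voluntary burst RMS
    normal_blink_amp_fraction: float = 0.4
    seed: int = 0
    # shape parameters (qualitative morphology)
    h_rise: float = 0.040               # horizontal saccade rise time, s
    v_rise: float = 0.060               # vertical rise time (slower), s
    emg_ramp: float = 0.050             # raised-cosine burst ramp, s
    blink_v_fraction: float = 0.8       # vertical EOG transient of a blink,
                                        # as a fraction of saccade_amplitude_v
    emg_band: tuple = (66.7, 450.0)     # burst band, Hz
    eog_ac_cutoff: float = 0.5          # device AC-element high-pass, Hz
    tail: float = 2.0                   # quiet padding after the last event, s

    def __post_init__(self):
        for name in ("drift_walk_sigma", "line_noise_amp", "white_noise_sigma",
                     "saccade_amplitude_h", "saccade_amplitude_v",
                     "emg_burst_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not 0.0 < self.normal_blink_amp_fraction < 1.0:
            raise ValueError("normal_blink_amp_fraction must be in (0, 1)")
        if self.saccade_amplitude_h > 0 and \
                self.saccade_amplitude_v >= self.saccade_amplitude_h:
            raise ValueError("vertical saccade amplitude must be below horizontal")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["emg_band"] = list(d["emg_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(
                f"unknown GenConfig fields: {sorted(unknown)}; "
                f"allowed: {sorted(cls.__dataclass_fields__)}")
        d = dict(d)
        if "emg_band" in d:
            d["emg_band"] = tuple(d["emg_band"])
        return cls(**d)


@dataclass
class MultiChannelRecording:
    """Six synchronized traces plus the sampling rate."""

    ch1_dc: np.ndarray
    ch2_dc: np.ndarray
    ch3_ac: np.ndarray
    ch4_ac: np.ndarray
    ch5_emg: np.ndarray
    ch6_emg: np.ndarray
    sampling_rate: float

    CHANNELS = ("ch1_dc", "ch2_dc", "ch3_ac", "ch4_ac", "ch5_emg", "ch6_emg")

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        traces = [np.asarray(getattr(self, c), dtype=float) for c in self.CHANNELS]
        n = traces[0].size
        for c, tr in zip(self.CHANNELS, traces):
            if tr.ndim != 1:
                raise ValueError(f"{c} must be 1-D")
            if tr.size != n:
                raise ValueError("all six traces must have identical length")
            if tr.size and not np.all(np.isfinite(tr)):
                raise ValueError(f"{c} contains non-finite values")
            setattr(self, c, tr)

    @property
    def n_samples(self) -> int:
        return self.ch1_dc.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def make_schedule(labels: Sequence[str], repeats: int, interval: float,
                  seed: int = 0, shuffle: bool = False,
                  durations: dict | None = None,
                  amplitude_scale: float = 1.0) -> list[EventSpec]:
    """Build a non-overlapping schedule of ``repeats`` x ``len(labels)`` events.

    Onsets are spaced ``interval`` seconds apart starting at ``interval``
    (the recording opens with a quiet calibration-friendly stretch).  With
    ``shuffle=False`` the label sequence is repeated in blocks; with
    ``shuffle=True`` the full multiset of labels is permuted (seeded).
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if interval <= 0:
        raise ValueError("interval must be > 0")
    durs = dict(DEFAULT_DURATIONS)
    if durations:
        durs.update(durations)
    seq = [lab for _ in range(repeats) for lab in labels]
    max_dur = max(durs[lab] for lab in seq) if seq else 0.0
    if interval <= max_dur:
        raise ValueError(
            f"interval {interval}s must exceed the maximum event duration {max_dur}s")
    if shuffle:
        rng = np.random.default_rng(seed)
        seq = [seq[i] for i in rng.permutation(len(seq))]
    return [EventSpec(lab, interval * (i + 1), durs[lab], amplitude_scale)
            for i, lab in enumerate(seq)]


def _check_schedule(schedule: Iterable[EventSpec]) -> list[EventSpec]:
    events = sorted(schedule, key=lambda e: e.onset)
    for a, b in zip(events, events[1:]):
        if a.onset + a.duration > b.onset:
            raise InvalidScheduleError(
                f"events overlap: {a.label}@{a.onset}s (dur {a.duration}s) "
                f"runs into {b.label}@{b.onset}s")
    return events


def _add_plateau(trace: np.ndarray, fs: float, onset: float, duration: float,
                 rise: float, amp: float) -> None:
    """Step-hold-return gaze deflection: linear rise, hold, linear return."""
    n = trace.size
    t0, t1 = onset, onset + rise
    t2, t3 = onset + duration, onset + duration + rise
    i0, i3 = int(np.ceil(t0 * fs)), min(int(np.floor(t3 * fs)) + 1, n)
    if i0 >= i3:
        return
    tt = np.arange(i0, i3) / fs
    y = np.where(tt < t1, (tt - t0) / rise,
                 np.where(tt <= t2, 1.0, np.clip((t3 - tt) / rise, 0.0, 1.0)))
    trace[i0:i3] += amp * y


def _add_bump(trace: np.ndarray, fs: float, onset: float, duration: float,
              amp: float) -> None:
    """Raised-cosine bump (blink artifact in the vertical EOG)."""
    n = trace.size
    i0, i1 = int(np.ceil(onset * fs)), min(int(np.floor((onset + duration) * fs)) + 1, n)
    if i0 >= i1:
        return
    tt = np.arange(i0, i1) / fs
    phase = (tt - onset) / duration
    trace[i0:i1] += amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def gaze_traces(schedule: Iterable[EventSpec], config: GenConfig,
                n_samples: int) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free internal horizontal/vertical gaze traces h(t), v(t)."""
    fs = config.sampling_rate
    h = np.zeros(n_samples)
    v = np.zeros(n_samples)
    for ev in schedule:
        a = ev.amplitude_scale
        if ev.label == "right":
            _add_plateau(h, fs, ev.onset, ev.duration, config.h_rise,
                         +config.saccade_amplitude_h * a)
        elif ev.label == "left":
            _add_plateau(h, fs, ev.onset, ev.duration, config.h_rise,
                         -config.saccade_amplitude_h * a)
        elif ev.label == "up":
            _add_plateau(v, fs, ev.onset, ev.duration, config.v_rise,
                         +config.saccade_amplitude_v * a)
        elif ev.label == "down":
            _add_plateau(v, fs, ev.onset, ev.duration, config.v_rise,
                         -config.saccade_amplitude_v * a)
        elif ev.label in ("right_blink", "left_blink", "bite", "normal_blink"):
            # lid motion leaves a transient in the vertical EOG
            _add_bump(v, fs, ev.onset, ev.duration,
                      config.blink_v_fraction * config.saccade_amplitude_v * a)
    return h, v


def _burst(rng: np.random.Generator, n_samp: int, fs: float,
           band: tuple, ramp: float, amp: float) -> np.ndarray:
    """Band-limited noise burst with raised-cosine on/off ramps, unit-RMS
    core scaled to ``amp``."""
    x = rng.standard_normal(n_samp)
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2.0)
    from scipy import signal as _sig
    sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    if n_samp > 24:  # sosfiltfilt needs more samples than its padding
        x = _sig.sosfiltfilt(sos, x)
    sd = x.std()
    if sd > 0:
        x = x / sd
    env = np.ones(n_samp)
    nr = min(int(ramp * fs), n_samp // 2)
    if nr > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        env[:nr] = r
        env[n_samp - nr:] = r[::-1]
    return amp * env * x


def synthesize(schedule: Iterable[EventSpec], config: GenConfig
               ) -> tuple[MultiChannelRecording, list[EventSpec]]:
    """Render a schedule into a six-channel recording plus its ground truth.

    CH1 = +h(t) + v(t) + drift1 + noise, CH2 = -h(t) + v(t) + drift2 + noise,
    so (CH1-CH2)/2 recovers h(t) and (CH1+CH2)/2 recovers v(t) exactly when
    noise and drift are zero.  CH3/CH4 are high-passed copies of CH1/CH2.
    Deterministic given (schedule, config.seed).
    """
    events = _check_schedule(schedule)
    fs = config.sampling_rate
    total = (events[-1].onset + events[-1].duration + config.tail) if events \
        else config.tail
    n = int(round(total * fs))
    rng = np.random.default_rng(config.seed)
    t = np.arange(n) / fs

    h, v = gaze_traces(events, config, n)

    def drift():
        if config.drift_rate == 0 and config.drift_walk_sigma == 0:
            return np.zeros(n)
        walk = np.cumsum(rng.normal(0.0, config.drift_walk_sigma / np.sqrt(fs), n))
        return config.drift_rate * t + walk

    def noise():
        if config.white_noise_sigma == 0:
            return np.zeros(n)
        return rng.normal(0.0, config.white_noise_sigma, n)

    def line():
        if config.line_noise_amp == 0:
            return np.zeros(n)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return config.line_noise_amp * np.sin(2.0 * np.pi * 60.0 * t + phase)

    drift1, drift2 = drift(), drift()
    ch1 = h + v
    ch1 += drift1
    ch1 += noise()
    ch1 += line()
    ch2 = v - h
    ch2 += drift2
    ch2 += noise()
    ch2 += line()

    if n > 24 and (np.any(ch1) or np.any(ch2)):
        ch3 = preprocess.highpass(ch1, config.eog_ac_cutoff, fs, 2)
        ch4 = preprocess.highpass(ch2, config.eog_ac_cutoff, fs, 2)
    else:
        ch3, ch4 = np.zeros(n), np.zeros(n)

    ch5 = noise() + line()
    ch6 = noise() + line()
    for ev in events:
        nb = int(round(ev.duration * fs))
        i0 = int(np.ceil(ev.onset * fs))
        i1 = min(i0 + nb, n)
        if i1 <= i0:
            continue
        if ev.label == "right_blink":
            targets, amp = ("ch5",), config.emg_burst_amp
        elif ev.label == "left_blink":
            targets, amp = ("ch6",), config.emg_burst_amp
        elif ev.label == "bite":
            targets, amp = ("ch5", "ch6"), config.emg_burst_amp
        elif ev.label == "normal_blink":
            targets = ("ch5", "ch6")
            amp = config.emg_burst_amp * config.normal_blink_amp_fraction
        else:
            continue
        for tgt in targets:
            b = _burst(rng, i1 - i0, fs, config.emg_band, config.emg_ramp,
                       amp * ev.amplitude_scale)
            if tgt == "ch5":
                ch5[i0:i1] += b
            else:
                ch6[i0:i1] += b

    rec = MultiChannelRecording(ch1, ch2, ch3, ch4, ch5, ch6, fs)
    return rec, list(events)


# ---------------------------------------------------------------------------
# Recording / ground-truth I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("t",) + MultiChannelRecording.CHANNELS


def write_recording(rec: MultiChannelRecording, path, meta: dict | None = None) -> None:
    """Write a recording as CSV (time column + six channel columns).

    Metadata (sampling rate, seed, config hash) goes into ``#``-prefixed
    header comment lines so the table itself stays plain CSV.
    """
    header = dict(meta or {})
    header["sampling_rate"] = rec.sampling_rate
    df = pd.DataFrame({"t": np.arange(rec.n_samples) / rec.sampling_rate})
    for c in rec.CHANNELS:
        df[c] = getattr(rec, c)
    with open(path, "w", encoding="utf-8") as f:
        f.write("# " + json.dumps(header) + "\n")
        df.to_csv(f, index=False)


def read_recording(path) -> MultiChannelRecording:
    """Read a recording CSV written by :func:`write_recording`.

    Raises :class:`RecordingParseError` on a malformed header, a missing
    channel column, or ragged rows (the underlying parser error names the
    offending line).
    """
    meta = {}
    with open(path, "r", encoding="utf-8") as f:
        first = f.readline()
    if first.startswith("#"):
        try:
            meta = json.loads(first.lstrip("#").strip())
        except json.JSONDecodeError as e:
            raise RecordingParseError(f"malformed metadata header line 1: {e}") from e
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError as e:
        raise RecordingParseError(f"{path}: no CSV header found") from e
    except pd.errors.ParserError as e:
        raise RecordingParseError(f"{path}: {e}") from e
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RecordingParseError(
            f"{path}: missing column(s) {missing} in header line")
    fs = meta.get("sampling_rate")
    if fs is None:
        tt = df["t"].to_numpy(dtype=float)
        if tt.size < 2:
            raise RecordingParseError(
                f"{path}: no sampling_rate metadata and too few rows to infer it")
        fs = 1.0 / float(np.median(np.diff(tt)))
    return MultiChannelRecording(
        *(df[c].to_numpy(dtype=float) for c in MultiChannelRecording.CHANNELS),
        sampling_rate=float(fs))


def write_truth(events: Iterable[EventSpec], path, meta: dict | None = None) -> None:
    """Write ground truth as JSONL, one event per line."""
    with open(path, "w", encoding="utf-8") as f:
        if meta:
            f.write(json.dumps({"_meta": meta}) + "\n")
        for ev in events:
            f.write(json.dumps(ev.to_dict()) + "\n")


def read_truth(path) -> list[EventSpec]:
    events = []
    with open(path, "r", encoding="utf-8") as f:
        for ln, line in enumerate(f, 1):
            line = line.strip()
            if not line:
                continue
            try:
                d = json.loads(line)
            except json.JSONDecodeError as e:
                raise RecordingParseError(f"{path} line {ln}: {e}") from e
            if "_meta" in d:
                continue
            try:
                events.append(EventSpec(**d))
            except (TypeError, ValueError) as e:
                raise RecordingParseError(f"{path} line {ln}: {e}") from e
    return events
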