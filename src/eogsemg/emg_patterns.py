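"""sEMG episode extraction, per-user threshold calibration and
right-blink / left-blink / bite classification.

The channel-pattern rule: activity on ch5 (right side) only is a voluntary
right blink, on ch6 (left side) only a left blink, and on both channels a
bite (or equivalently a strong bilateral blink — scored as the single class
``bite``).  Involuntary blinks are bilateral but weak; calibration places the
thresholds between the normal-blink peak and the weakest voluntary peak so
the system simply does not react to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, InvalidEpisodeError
from .preprocess import (PreprocessConfig, highpass, lowpass,
                         rectified_moving_average, detect_active)
from .synthgen import MultiChannelRecording, EventSpec


@dataclass
class UserCalibration:
    """Per-user thresholds, all in normalized signal units.

    ``emg_threshold_ch5/ch6`` gate the rectified-moving-average sEMG traces;
    ``eog_dc_threshold`` / ``eog_ac_threshold`` gate the derived horizontal
    EOG deviation and its AC element.  ``overlap_window`` is the tolerance
    for merging near-simultaneous activity on the two sEMG channels into one
    episode.
    """

    emg_threshold_ch5: float
    emg_threshold_ch6: float
    eog_dc_threshold: float
    eog_ac_threshold: float
    overlap_window: float = 0.05

    def __post_init__(self):
        for name in ("emg_threshold_ch5", "emg_threshold_ch6",
                     "eog_dc_threshold", "eog_ac_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "UserCalibration":
        with open(path, "r", encoding="utf-8") as f:
            return cls(**json.load(f))


@dataclass
class EmgEpisode:
    """One contiguous stretch of supra-threshold sEMG activity."""

    start: float
    end: float
    ch5_active: bool
    ch6_active: bool
    peak_ch5: float
    peak_ch6: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("episode start must precede end")
        if not (self.ch5_active or self.ch6_active):
            raise InvalidEpisodeError("episode has no active channel")


def classify_episode(episode: EmgEpisode) -> str:
    """ch5-only -> right_blink; ch6-only -> left_blink; both -> bite."""
    if episode.ch5_active and episode.ch6_active:
        return "bite"
    if episode.ch5_active:
        return "right_blink"
    if episode.ch6_active:
        return "left_blink"
    raise InvalidEpisodeError("episode has no active channel")


def emg_envelope(trace, pp: PreprocessConfig, fs: float) -> np.ndarray:
    """High-pass then rectified moving average — the sEMG processing chain."""
    return rectified_moving_average(
        highpass(trace, pp.emg_highpass_cutoff, fs, pp.filter_order),
        pp.ma_window)


def extract_episodes(ch5, ch6, cal: UserCalibration, pp: PreprocessConfig,
                     fs: float) -> list[EmgEpisode]:
    """Detect supra-threshold activity per channel and merge across channels.

    Per-channel intervals whose overlap or gap is at most
    ``cal.overlap_window`` are merged into a single episode carrying joint
    channel flags.  Sub-threshold activity (normal blinks) yields nothing.
    """
    ch5 = np.asarray(ch5, dtype=float)
    ch6 = np.asarray(ch6, dtype=float)
    if ch5.size != ch6.size:
        raise ValueError("ch5 and ch6 must have equal length")
    env5 = emg_envelope(ch5, pp, fs)
    env6 = emg_envelope(ch6, pp, fs)
    iv5 = detect_active(env5, cal.emg_threshold_ch5, pp.min_active_duration, fs)
    iv6 = detect_active(env6, cal.emg_threshold_ch6, pp.min_active_duration, fs)
    tagged = sorted([(s, e, 5) for s, e in iv5] + [(s, e, 6) for s, e in iv6])
    episodes: list[EmgEpisode] = []
    for s, e, ch in tagged:
        if episodes and s <= episodes[-1].end + cal.overlap_window:
            ep = episodes[-1]
            ep.end = max(ep.end, e)
            if ch == 5:
                ep.ch5_active = True
            else:
                ep.ch6_active = True
        else:
            episodes.append(EmgEpisode(s, e, ch == 5, ch == 6, 0.0, 0.0))
    for ep in episodes:
        i0, i1 = int(ep.start * fs), max(int(ep.end * fs), int(ep.start * fs) + 1)
        ep.peak_ch5 = float(env5[i0:i1].max())
        ep.peak_ch6 = float(env6[i0:i1].max())
    return episodes


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_CH5_CLASSES = ("right_blink", "bite")
_CH6_CLASSES = ("left_blink", "bite")


def _peak_in(trace: np.ndarray, fs: float, t0: float, t1: float) -> float:
    i0 = max(int(t0 * fs), 0)
    i1 = min(int(t1 * fs), trace.size)
    if i1 <= i0:
        return 0.0
    return float(np.abs(trace[i0:i1]).max())


def _rest_mask(n: int, fs: float, truth: Sequence[EventSpec],
               pad: float = 0.5) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    for ev in truth:
        i0 = max(int((ev.onset - pad) * fs), 0)
        i1 = min(int((ev.onset + ev.duration + pad) * fs), n)
        mask[i0:i1] = False
    return mask


def calibrate_thresholds(calibration_recording: MultiChannelRecording,
                         calibration_truth: Sequence[EventSpec],
                         k_sigma: float = 5.0,
                         pp: PreprocessConfig | None = None) -> UserCalibration:
    """Set all four per-user thresholds from a labeled calibration recording.

    Per sEMG channel the threshold is
    ``max(rest_mean + k_sigma * rest_sd, midpoint(normal-blink peak, weakest
    voluntary peak))`` so that all calibration normal blinks are rejected and
    all voluntary events accepted.  EOG thresholds are set at half the
    weakest saccade excursion (DC deviation from the pre-event baseline, and
    AC peak), floored at ``k_sigma`` times the rest noise level.
    """
    pp = pp or PreprocessConfig()
    rec = calibration_recording
    truth = list(calibration_truth)
    fs = rec.sampling_rate
    pp.validate(fs)

    def events(*labels):
        return [ev for ev in truth if ev.label in labels]

    for lab in ("right_blink", "left_blink", "bite", "normal_blink",
                "right", "left"):
        if not events(lab):
            raise CalibrationError(
                f"calibration recording must contain at least one {lab!r} event")

    env5 = emg_envelope(rec.ch5_emg, pp, fs)
    env6 = emg_envelope(rec.ch6_emg, pp, fs)
    rest = _rest_mask(rec.n_samples, fs, truth)
    if not rest.any():
        raise CalibrationError("no rest segments between calibration events")

    emg_thr = {}
    for name, env, classes in (("ch5", env5, _CH5_CLASSES),
                               ("ch6", env6, _CH6_CLASSES)):
        vol = [_peak_in(env, fs, ev.onset, ev.onset + ev.duration + 0.1)
               for ev in events(*classes)]
        nb = [_peak_in(env, fs, ev.onset, ev.onset + ev.duration + 0.1)
              for ev in events("normal_blink")]
        if min(vol) <= max(nb):
            raise CalibrationError(
                f"{name}: voluntary peak {min(vol):.3g} does not exceed "
                f"normal-blink peak {max(nb):.3g}; thresholds infeasible")
        floor = float(env[rest].mean() + k_sigma * env[rest].std())
        emg_thr[name] = max(floor, 0.5 * (max(nb) + min(vol)))

    # EOG: derived horizontal traces, DC and AC elements
    ch1f = lowpass(rec.ch1_dc, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch2f = lowpass(rec.ch2_dc, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch3f = lowpass(rec.ch3_ac, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch4f = lowpass(rec.ch4_ac, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    h_dc = ch1f - ch2f
    h_ac = ch3f - ch4f

    dc_peaks, ac_peaks = [], []
    for ev in events("right", "left"):
        base = float(np.mean(h_dc[max(int((ev.onset - 0.5) * fs), 0):
                                  max(int((ev.onset - 0.1) * fs), 1)]))
        i0 = int(ev.onset * fs)
        i1 = min(int((ev.onset + ev.duration + 0.2) * fs), rec.n_samples)
        dc_peaks.append(float(np.abs(h_dc[i0:i1] - base).max()))
        ac_peaks.append(_peak_in(h_ac, fs, ev.onset, ev.onset + ev.duration + 0.2))

    # rest noise: per-segment detrended DC residuals, plain AC residuals
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], rest.astype(np.int8), [0]))))
    dc_resid = []
    for s, e in zip(edges[::2], edges[1::2]):
        seg = h_dc[s:e]
        if seg.size > 1:
            dc_resid.append(seg - seg.mean())
    sd_dc = float(np.concatenate(dc_resid).std()) if dc_resid else 0.0
    sd_ac = float(h_ac[rest].std())

    min_dc, min_ac = min(dc_peaks), min(ac_peaks)
    if min_dc <= 2 * k_sigma * sd_dc or min_ac <= 2 * k_sigma * sd_ac:
        raise CalibrationError(
            "saccade excursions are not separable from rest noise")
    return UserCalibration(
        emg_threshold_ch5=emg_thr["ch5"],
        emg_threshold_ch6=emg_thr["ch6"],
        eog_dc_threshold=max(k_sigma * sd_dc, 0.5 * min_dc),
        eog_ac_threshold=max(k_sigma * sd_ac, 0.5 * min_ac),
    )
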