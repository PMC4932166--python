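"""Filtering and activity-detection primitives shared by both modalities.

The sEMG chain is: high-pass (removes DC level and 50/60 Hz line noise),
rectified moving average over the previous ``n`` samples, then a per-user
threshold that marks the trace "active" or "inactive".  The EOG chain uses a
low-pass for the DC (gaze-position) element; the AC element arrives from the
device already high-passed and is only smoothed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal


@dataclass
class PreprocessConfig:
    """Filter and detection parameters, serialized in the user config file.

    ``emg_highpass_cutoff`` is the sEMG high-pass corner (Hz): high enough to
    reject mains interference, low enough to keep most of the EMG band.
    ``ma_window`` is the rectified-moving-average length in samples (50 at
    1 kHz = 50 ms).  ``min_active_duration`` gates out supra-threshold blips
    shorter than a physiological burst.
    """

    emg_highpass_cutoff: float = 66.7
    eog_ac_highpass_cutoff: float = 0.5
    eog_dc_lowpass_cutoff: float = 10.0
    filter_order: int = 2
    ma_window: int = 50
    min_active_duration: float = 0.05

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for name in ("emg_highpass_cutoff", "eog_ac_highpass_cutoff",
                     "eog_dc_lowpass_cutoff"):
            c = getattr(self, name)
            if not 0.0 < c < nyq:
                raise ValueError(f"{name}={c} must lie in (0, {nyq})")
        if self.ma_window < 1:
            raise ValueError("ma_window must be >= 1")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(
                f"unknown PreprocessConfig fields: {sorted(unknown)}; "
                f"allowed: {sorted(cls.__dataclass_fields__)}")
        return cls(**d)


def _design(cutoff: float, fs: float, order: int, btype: str) -> np.ndarray:
    nyq = fs / 2.0
    if not 0.0 < cutoff < nyq:
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq})")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    return signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")


def _zerophase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    # forward-backward application: zero phase, squared magnitude response
    return signal.sosfiltfilt(sos, x)


def highpass(x, cutoff: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass; output length equals input length."""
    return _zerophase(_design(cutoff, fs, order, "highpass"), x)


def lowpass(x, cutoff: float, fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass; output length equals input length."""
    return _zerophase(_design(cutoff, fs, order, "lowpass"), x)


def butter_mag(f: float, cutoff: float, order: int, btype: str) -> float:
    """Analytic single-pass Butterworth magnitude |H(f)| (zero-phase use is
    |H|^2).  Exposed for tests that check attenuation ratios."""
    r = (f / cutoff) ** (2 * order)
    if btype == "lowpass":
        return 1.0 / np.sqrt(1.0 + r)
    if btype == "highpass":
        return np.sqrt(r / (1.0 + r))
    raise ValueError(btype)


def rectified_moving_average(x, n: int) -> np.ndarray:
    """Causal mean of |x| over the previous ``n`` samples.

    For the first ``n - 1`` samples the mean is taken over the available
    prefix (avoids spurious onset activity from zero padding).
    """
    if n < 1:
        raise ValueError("moving-average window n must be >= 1")
    ax = np.abs(np.asarray(x, dtype=float))
    m = ax.size
    y = np.empty(m, dtype=float)
    if m == 0:
        return y
    k = min(n, m)
    run = 0.0
    for i in range(k - 1):  # warm-up prefix, at most n-1 samples
        run += ax[i]
        y[i] = run / (i + 1)
    if m >= n:
        windows = np.lib.stride_tricks.sliding_window_view(ax, n)
        y[n - 1:] = windows.mean(axis=1)
    else:
        y[m - 1] = ax.mean()
    return y


def detect_active(y, threshold: float, min_duration: float, fs: float):
    """Maximal runs of ``y > threshold`` lasting at least ``min_duration``.

    Returns half-open ``(start, end)`` intervals in seconds, disjoint and
    sorted.  An empty list means no supra-threshold activity.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    y = np.asarray(y, dtype=float)
    mask = (y > threshold).astype(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    starts, ends = edges[::2], edges[1::2]
    min_len = int(np.ceil(min_duration * fs))
    return [(s / fs, e / fs) for s, e in zip(starts, ends) if e - s >= min_len]
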