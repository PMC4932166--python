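"""EOG saccade recognition on the cross-channel geometry.

The two EOG channels each see a mixture of the horizontal and vertical gaze
components, so their difference isolates the horizontal signal and their sum
the vertical one.  Recognition combines two elements per axis:

* the DC element — gaze-position-proportional but subject to slow baseline
  drift, corrected by "renewal": whenever the AC element is quiet and the
  sEMG inactive for a full quiet window, the eyes are taken to be looking
  straight ahead and the DC reference is reset to the current value;
* the AC element — a high-passed copy that spikes at saccade onset and
  offset and is immune to drift.

A saccade is accepted through a four-phase state machine: (1) DC deviation
and AC excursion exceed the direction threshold together (onset, label
emitted); (2) DC stays deflected while AC returns to baseline (gaze held);
(3) an opposite-sign AC excursion marks the return to center; (4) both
elements settle back into their baseline bands, and the baseline is renewed.
Candidates whose vertical change dominates the horizontal one are labeled
``vertical`` and never become commands (blink artifacts live on the vertical
axis, and most users cannot control upward saccades reliably).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .emg_patterns import UserCalibration


@dataclass
class DerivedEog:
    """Vertical/horizontal traces derived from the two cross channels."""

    v: np.ndarray
    h: np.ndarray
    v_ac: np.ndarray | None = None
    h_ac: np.ndarray | None = None


def derive_vh(ch1, ch2) -> DerivedEog:
    """v = ch1 + ch2 (vertical), h = ch1 - ch2 (horizontal)."""
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if ch1.shape != ch2.shape:
        raise ValueError("ch1 and ch2 must have equal length")
    return DerivedEog(v=ch1 + ch2, h=ch1 - ch2)


def recover_channels(v, h) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`derive_vh`: ch1 = (v+h)/2, ch2 = (v-h)/2."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != h.shape:
        raise ValueError("v and h must have equal length")
    return (v + h) / 2.0, (v - h) / 2.0


def vertical_gate(delta_v: float, delta_h: float) -> str:
    """Compare the changing ranges of the two axes; ties go to vertical
    (the vertical EOG resembles the blink pattern, so ambiguity is treated
    conservatively and emits no horizontal command)."""
    return "horizontal" if abs(delta_h) > abs(delta_v) else "vertical"


@dataclass
class BaselineState:
    """EOG DC reference ("eyes looking at the front") and renewal bookkeeping."""

    h_ref: float = 0.0
    v_ref: float = 0.0
    last_renewal: float = 0.0
    quiet_window: float = 0.5
    quiet_since: float | None = None

    def __post_init__(self):
        if self.last_renewal < 0:
            raise ValueError("last_renewal must be >= 0")


def renew_baseline(state: BaselineState, h_dc: float, v_dc: float,
                   ac_quiet: bool, emg_inactive: bool, t: float) -> BaselineState:
    """Advance the renewal rule by one observation.

    If the AC element has not changed (eyes not moving) and the sEMG is not
    active, and both have held for at least ``quiet_window``, the DC
    reference is reset to the current values.  Otherwise the state is
    unchanged (apart from quiet-run bookkeeping).
    """
    if ac_quiet and emg_inactive:
        if state.quiet_since is None:
            state.quiet_since = t
        elif t - state.quiet_since >= state.quiet_window:
            state.h_ref = h_dc
            state.v_ref = v_dc
            state.last_renewal = t
    else:
        state.quiet_since = None
    return state


@dataclass
class SaccadeEvent:
    label: str                 # right | left | vertical
    onset: float
    offset: float
    peak_dc_excursion: float

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("onset must precede offset")


@dataclass
class SaccadeConfig:
    """Numeric conventions of the state machine.

    ``ac_band_frac`` / ``dc_band_frac``: "returned to baseline" means the
    element is within this fraction of its threshold.  ``refractory``
    suppresses double-triggering after an accepted event.  ``vertical_frac``
    scales the horizontal thresholds for admitting vertical candidates
    (vertical EOG deflections are weaker).  ``coincidence_window`` is the
    tolerance for the DC and AC elements crossing threshold "simultaneously"
    at onset.  ``max_event_duration`` is a watchdog against stuck states.
    """

    ac_band_frac: float = 0.2
    dc_band_frac: float = 0.2
    refractory: float = 0.3
    vertical_frac: float = 0.6
    coincidence_window: float = 0.05
    max_event_duration: float = 5.0


_IDLE, _ONSET, _HOLD, _RETURN = range(4)


def _causal_max(x: np.ndarray, w: int) -> np.ndarray:
    """Running max over the trailing window [i-w+1, i]."""
    if w <= 1:
        return x
    size = w if w % 2 == 1 else w + 1
    return ndimage.maximum_filter1d(x, size=size, mode="nearest",
                                    origin=-(size // 2))


def detect_saccades(h_dc, h_ac, v_dc, state: BaselineState,
                    cal: UserCalibration, fs: float, *,
                    v_ac=None, emg_active=None,
                    config: SaccadeConfig | None = None,
                    state_trace: list | None = None) -> list[SaccadeEvent]:
    """Run the four-phase DC/AC state machine over derived EOG traces.

    ``emg_active`` is an optional boolean sample mask; while it is set the
    machine is held in its idle phase (sEMG has priority) and the baseline
    is re-initialized by renewal once quiet resumes.  Passing
    ``state_trace`` (a list) records the phase per sample for debugging.
    """
    cfg = config or SaccadeConfig()
    h_dc = np.asarray(h_dc, dtype=float)
    h_ac = np.asarray(h_ac, dtype=float)
    v_dc = np.asarray(v_dc, dtype=float)
    n = h_dc.size
    if h_ac.size != n or v_dc.size != n:
        raise ValueError("traces must have equal length")
    v_ac = np.zeros(n) if v_ac is None else np.asarray(v_ac, dtype=float)
    emg = np.zeros(n, dtype=bool) if emg_active is None else \
        np.asarray(emg_active, dtype=bool)

    thr_dc = cal.eog_dc_threshold
    thr_ac = cal.eog_ac_threshold
    ac_band = cfg.ac_band_frac * thr_ac
    dc_band = cfg.dc_band_frac * thr_dc
    vthr_dc = cfg.vertical_frac * thr_dc
    vthr_ac = cfg.vertical_frac * thr_ac

    w = max(1, int(round(cfg.coincidence_window * fs)))
    hmax = _causal_max(h_ac, w)
    hmin = -_causal_max(-h_ac, w)
    vmax = _causal_max(v_ac, w)
    vmin = -_causal_max(-v_ac, w)

    quiet_need = max(1, int(round(state.quiet_window * fs)))
    events: list[SaccadeEvent] = []
    phase = _IDLE
    quiet = 0
    refrac_until = -np.inf
    sign = 0
    axis = "h"
    label = ""
    onset_t = 0.0
    peak = 0.0

    for i in range(n):
        t = i / fs
        if state_trace is not None:
            state_trace.append(phase)
        if emg[i]:
            phase = _IDLE
            quiet = 0
            state.quiet_since = None
            continue
        dh = h_dc[i] - state.h_ref
        dv = v_dc[i] - state.v_ref
        ach = h_ac[i]
        acv = v_ac[i]
        ac_quiet = abs(ach) < ac_band and abs(acv) < ac_band

        if phase == _IDLE:
            if ac_quiet:
                quiet += 1
                if quiet >= quiet_need:
                    state.h_ref = h_dc[i]
                    state.v_ref = v_dc[i]
                    state.last_renewal = t
            else:
                quiet = 0
            if t < refrac_until:
                continue
            cand_h = 0
            if dh > thr_dc and hmax[i] > thr_ac:
                cand_h = 1
            elif -dh > thr_dc and -hmin[i] > thr_ac:
                cand_h = -1
            cand_v = 0
            if dv > vthr_dc and vmax[i] > vthr_ac:
                cand_v = 1
            elif -dv > vthr_dc and -vmin[i] > vthr_ac:
                cand_v = -1
            if cand_h and vertical_gate(dv, dh) == "horizontal":
                sign, axis = cand_h, "h"
                label = "right" if sign > 0 else "left"
            elif cand_v or cand_h:
                # vertical-dominated candidate: tracked but never a command
                sign = cand_v if cand_v else cand_h
                axis = "v" if cand_v else "h"
                label = "vertical"
            else:
                continue
            phase = _ONSET
            onset_t = t
            peak = abs(dh if axis == "h" else dv)
            quiet = 0
            continue

        d = dh if axis == "h" else dv
        a = ach if axis == "h" else acv
        peak = max(peak, abs(d))
        if t - onset_t > cfg.max_event_duration:
            phase = _IDLE  # watchdog: abandon without emitting
            continue
        if phase == _ONSET:
            if abs(a) < ac_band:
                phase = _HOLD
            elif sign * d < dc_band:
                phase = _IDLE  # transient that never held: not a saccade
        elif phase == _HOLD:
            if -sign * a > thr_ac:
                phase = _RETURN
            elif abs(d) < dc_band and abs(a) < ac_band:
                phase = _emit(events, state, h_dc[i], v_dc[i], label,
                              onset_t, t, peak)
                refrac_until = t + cfg.refractory
                quiet = 0
        elif phase == _RETURN:
            if abs(d) < dc_band and abs(a) < ac_band:
                phase = _emit(events, state, h_dc[i], v_dc[i], label,
                              onset_t, t, peak)
                refrac_until = t + cfg.refractory
                quiet = 0
    return events


def _emit(events: list, state: BaselineState, h_now: float, v_now: float,
          label: str, onset_t: float, t: float, peak: float) -> int:
    """Step 4: both elements back at baseline — record the event and update
    the baseline."""
    state.h_ref = h_now
    state.v_ref = v_now
    state.last_renewal = t
    events.append(SaccadeEvent(label, onset_t, t, peak))
    return _IDLE
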