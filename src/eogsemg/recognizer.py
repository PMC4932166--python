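"""Integrated dual-modality recognition flow, trial evaluation and summary
statistics.

sEMG has priority: supra-threshold muscle activity is classified by the
channel-pattern rule and masks concurrent EOG processing (a hard blink or
bite contaminates the EOG, so no saccade may be emitted while it lasts), and
the EOG DC references are re-initialized once the activity is over.  Outside
sEMG episodes the saccade state machine runs with continuous baseline
renewal.  Five classes are emitted: right/left (EOG) and right blink / left
blink / bite (sEMG).

Evaluation follows the presented-stimulus convention: each scheduled action
is matched to the nearest prediction within a window; a matching label is
*correct*, a wrong label a *miss*, and no response a *reject*.  The 5-point
performance index is (5*correct + 2*reject + 0*miss) / trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np

from .errors import InsufficientDataError
from .preprocess import PreprocessConfig, lowpass
from .synthgen import MultiChannelRecording, EventSpec, COMMAND_LABELS
from .emg_patterns import UserCalibration, extract_episodes, classify_episode
from .eog_patterns import (BaselineState, SaccadeConfig, derive_vh,
                           detect_saccades)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (2.5 -> 3), used for printed percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassifiedEvent:
    """One recognized command with its modality and channel evidence."""

    label: str
    onset: float
    modality: str            # "EOG" | "sEMG"
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in COMMAND_LABELS:
            raise ValueError(f"label must be one of {COMMAND_LABELS}")
        expected = "EOG" if self.label in ("right", "left") else "sEMG"
        if self.modality != expected:
            raise ValueError(f"label {self.label!r} implies modality {expected}")

    def to_dict(self) -> dict:
        return {"label": self.label, "onset": self.onset,
                "modality": self.modality, "evidence": self.evidence}


@dataclass
class TrialOutcome:
    """Outcome of one presented action.

    ``correct``: matching response.  ``reject``: no response (for actions
    that expect none — normal blinks — this is the desired outcome).
    ``miss``: wrong response, including any response to a normal blink.
    """

    truth_label: str
    outcome: str             # correct | reject | miss
    predicted_label: str | None = None
    truth_onset: float = 0.0

    def __post_init__(self):
        if self.outcome not in ("correct", "reject", "miss"):
            raise ValueError("outcome must be correct|reject|miss")


def run_recognition(rec: MultiChannelRecording, cal: UserCalibration,
                    pp: PreprocessConfig | None = None, *,
                    sacc_config: SaccadeConfig | None = None,
                    quiet_window: float = 0.5) -> list[ClassifiedEvent]:
    """Full dual-modality pass over one recording.

    Returns the merged, time-sorted stream of classified command events.
    Saccade candidates labeled ``vertical`` by the gate are dropped here:
    up/down are detected but never emitted as commands.
    """
    pp = pp or PreprocessConfig()
    fs = rec.sampling_rate
    pp.validate(fs)
    n = rec.n_samples
    if n < quiet_window * fs:
        raise InsufficientDataError(
            f"recording of {n / fs:.3g}s is shorter than the quiet window "
            f"({quiet_window}s)")

    episodes = extract_episodes(rec.ch5_emg, rec.ch6_emg, cal, pp, fs)
    emg_events = [
        ClassifiedEvent(classify_episode(ep), ep.start, "sEMG",
                        {"peak_ch5": ep.peak_ch5, "peak_ch6": ep.peak_ch6})
        for ep in episodes
    ]

    # sEMG masks concurrent EOG processing (with a small guard band)
    mask = np.zeros(n, dtype=bool)
    for ep in episodes:
        i0 = max(int((ep.start - 0.05) * fs), 0)
        i1 = min(int((ep.end + 0.2) * fs), n)
        mask[i0:i1] = True

    ch1f = lowpass(rec.ch1_dc, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch2f = lowpass(rec.ch2_dc, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch3f = lowpass(rec.ch3_ac, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    ch4f = lowpass(rec.ch4_ac, pp.eog_dc_lowpass_cutoff, fs, pp.filter_order)
    dc = derive_vh(ch1f, ch2f)
    ac = derive_vh(ch3f, ch4f)

    n0 = max(1, min(int(0.2 * fs), n))
    state = BaselineState(h_ref=float(dc.h[:n0].mean()),
                          v_ref=float(dc.v[:n0].mean()),
                          quiet_window=quiet_window)
    saccades = detect_saccades(dc.h, ac.h, dc.v, state, cal, fs,
                               v_ac=ac.v, emg_active=mask, config=sacc_config)
    eog_events = [
        ClassifiedEvent(s.label, s.onset, "EOG",
                        {"peak_dc_excursion": s.peak_dc_excursion})
        for s in saccades if s.label in ("right", "left")
    ]
    return sorted(eog_events + emg_events, key=lambda e: e.onset)


def evaluate(events: Sequence[ClassifiedEvent], truth: Sequence[EventSpec],
             match_window: float = 1.5
             ) -> tuple[list[TrialOutcome], list[ClassifiedEvent]]:
    """Match predictions to presented actions (greedy, one-to-one).

    Truth events are walked earliest-first; each takes the nearest unused
    prediction within ``match_window`` seconds of its onset.  Actions that
    expect no response (normal blinks, up/down, none) score ``correct`` when
    unmatched and ``miss`` when any prediction lands on them.  Predictions
    left unmatched are returned separately as spurious.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    preds = sorted(events, key=lambda e: e.onset)
    used = [False] * len(preds)
    outcomes: list[TrialOutcome] = []
    for ev in sorted(truth, key=lambda e: e.onset):
        best = None
        best_dt = match_window
        for j, p in enumerate(preds):
            if used[j]:
                continue
            dt = abs(p.onset - ev.onset)
            if dt < best_dt or (best is None and dt == best_dt):
                best, best_dt = j, dt
        expects_command = ev.label in COMMAND_LABELS
        if best is None:
            outcomes.append(TrialOutcome(
                ev.label, "reject" if expects_command else "correct",
                None, ev.onset))
            continue
        used[best] = True
        plabel = preds[best].label
        if not expects_command:
            outcome = "miss"          # rejection failure: it should not react
        elif plabel == ev.label:
            outcome = "correct"
        else:
            outcome = "miss"
        outcomes.append(TrialOutcome(ev.label, outcome, plabel, ev.onset))
    spurious = [p for j, p in enumerate(preds) if not used[j]]
    return outcomes, spurious


def pe_score(correct: int, reject: int, miss: int) -> float:
    """5-point performance index: correct 5, reject 2, miss 0 points."""
    if min(correct, reject, miss) < 0:
        raise ValueError("counts must be >= 0")
    total = correct + reject + miss
    if total == 0:
        raise ValueError("at least one trial is required")
    return (5.0 * correct + 2.0 * reject) / total


@dataclass
class PatternStats:
    correct: int
    reject: int
    miss: int

    @property
    def n(self) -> int:
        return self.correct + self.reject + self.miss

    @property
    def accuracy(self) -> float:
        return 100.0 * self.correct / self.n

    @property
    def reject_rate(self) -> float:
        return 100.0 * self.reject / self.n

    @property
    def miss_rate(self) -> float:
        return 100.0 * self.miss / self.n

    @property
    def pe(self) -> float:
        return pe_score(self.correct, self.reject, self.miss)

    def to_dict(self) -> dict:
        return {"correct": self.correct, "reject": self.reject,
                "miss": self.miss, "n": self.n,
                "accuracy_pct": self.accuracy,
                "reject_rate_pct": self.reject_rate,
                "miss_rate_pct": self.miss_rate,
                "pe": self.pe}


@dataclass
class RecognitionSummary:
    """Per-pattern and pooled counts/rates.  Overall rates pool raw counts
    over all trials (274/288-style), not the mean of per-pattern rates."""

    per_pattern: dict
    overall: PatternStats

    def to_dict(self) -> dict:
        return {"per_pattern": {k: v.to_dict() for k, v in self.per_pattern.items()},
                "overall": self.overall.to_dict()}

    def render(self) -> str:
        lines = [f"{'pattern':<14}{'n':>5}{'correct':>9}{'reject':>8}"
                 f"{'miss':>6}{'acc%':>8}{'PE':>7}"]
        rows = list(self.per_pattern.items()) + [("overall", self.overall)]
        for name, s in rows:
            lines.append(
                f"{name:<14}{s.n:>5}{s.correct:>9}{s.reject:>8}{s.miss:>6}"
                f"{round_half_up(s.accuracy, 1):>8.1f}{s.pe:>7.2f}")
        return "\n".join(lines)


def summarize(outcomes: Iterable[TrialOutcome]) -> RecognitionSummary:
    """Tally outcomes per pattern and pooled over all supplied trials."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("outcomes must cover at least one pattern")
    per: dict[str, PatternStats] = {}
    for o in outcomes:
        s = per.setdefault(o.truth_label, PatternStats(0, 0, 0))
        setattr(s, o.outcome, getattr(s, o.outcome) + 1)
    overall = PatternStats(
        sum(s.correct for s in per.values()),
        sum(s.reject for s in per.values()),
        sum(s.miss for s in per.values()))
    return RecognitionSummary(per_pattern=per, overall=overall)
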