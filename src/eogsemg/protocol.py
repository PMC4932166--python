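"""Simulation of the pattern-recognition study protocol on synthetic users.

A "user" is a draw of generator parameters (signal amplitudes vary between
people; thresholds are therefore calibrated per user).  Each user provides a
calibration recording (three repetitions of every action class plus normal
blinks) and then performs the test protocol: nine repetitions of each of the
four command classes — right, left, right blink, left blink — presented in
shuffled order at 3-second intervals.  A separate rejection protocol
presents involuntary (normal) blinks only and counts how many produce no
command.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthgen import GenConfig, make_schedule, synthesize
from .emg_patterns import UserCalibration, calibrate_thresholds
from .recognizer import run_recognition, evaluate, TrialOutcome

FOUR_COMMANDS = ("right", "left", "right_blink", "left_blink")
CALIBRATION_LABELS = ("right", "left", "right_blink", "left_blink",
                      "bite", "normal_blink")
ACTION_INTERVAL = 3.0      # seconds between presented actions
TRIALS_PER_CLASS = 9
N_USERS = 8


def user_config(rng: np.random.Generator, base: GenConfig | None = None
                ) -> GenConfig:
    """Draw one synthetic user: +-20% inter-individual spread on the EOG and
    sEMG amplitudes around the study defaults."""
    base = base or GenConfig()
    h = base.saccade_amplitude_h * rng.uniform(0.8, 1.2)
    return replace(
        base,
        seed=int(rng.integers(0, 2**31 - 1)),
        saccade_amplitude_h=h,
        saccade_amplitude_v=min(base.saccade_amplitude_v * rng.uniform(0.8, 1.2),
                                0.95 * h),
        emg_burst_amp=base.emg_burst_amp * rng.uniform(0.8, 1.2),
    )


def calibrate_user(cfg: GenConfig, rng: np.random.Generator
                   ) -> UserCalibration:
    """Generate this user's calibration recording and fit thresholds."""
    cal_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
    sched = make_schedule(CALIBRATION_LABELS, repeats=3,
                          interval=ACTION_INTERVAL)
    rec, truth = synthesize(sched, cal_cfg)
    return calibrate_thresholds(rec, truth)


def run_user_trial(cfg: GenConfig, cal: UserCalibration,
                   rng: np.random.Generator,
                   labels=FOUR_COMMANDS, repeats: int = TRIALS_PER_CLASS,
                   match_window: float = 1.5):
    """One test session: shuffled protocol recording -> recognizer -> outcomes."""
    sched_seed = int(rng.integers(0, 2**31 - 1))
    trial_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
    sched = make_schedule(labels, repeats=repeats, interval=ACTION_INTERVAL,
                          seed=sched_seed, shuffle=True)
    rec, truth = synthesize(sched, trial_cfg)
    events = run_recognition(rec, cal)
    return evaluate(events, truth, match_window)


@dataclass
class PooledResult:
    correct: int
    reject: int
    miss: int
    n: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.correct / self.n


def pattern_recognition_experiment(seed: int, n_seeds: int = 20,
                                   n_users: int = N_USERS,
                                   repeats: int = TRIALS_PER_CLASS,
                                   base: GenConfig | None = None
                                   ) -> PooledResult:
    """Pooled four-class recognition over ``n_seeds`` replicates of the
    eight-user protocol (correct/reject/miss counts pooled over all trials)."""
    correct = reject = miss = 0
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, k])
        for _ in range(n_users):
            cfg = user_config(rng, base)
            cal = calibrate_user(cfg, rng)
            outcomes, _ = run_user_trial(cfg, cal, rng, repeats=repeats)
            for o in outcomes:
                correct += o.outcome == "correct"
                reject += o.outcome == "reject"
                miss += o.outcome == "miss"
    n = correct + reject + miss
    return PooledResult(correct, reject, miss, n)


def blink_rejection_experiment(seed: int, n_seeds: int = 10,
                               n_users: int = N_USERS,
                               blinks_per_recording: int = 3,
                               base: GenConfig | None = None
                               ) -> tuple[int, int]:
    """Present involuntary blinks only; return (rejected, total).

    A blink counts as rejected when no command is matched to it within the
    standard window — the interface must not react to a normal blink.
    """
    rejected = total = 0
    for k in range(n_seeds):
        rng = np.random.default_rng([seed, 10_000 + k])
        for _ in range(n_users):
            cfg = user_config(rng, base)
            cal = calibrate_user(cfg, rng)
            trial_cfg = replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
            sched = make_schedule(["normal_blink"],
                                  repeats=blinks_per_recording,
                                  interval=ACTION_INTERVAL)
            rec, truth = synthesize(sched, trial_cfg)
            events = run_recognition(rec, cal)
            outcomes, _ = evaluate(events, truth)
            for o in outcomes:
                total += 1
                rejected += o.outcome == "correct"  # no reaction = success
    return rejected, total
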