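"""Division-selection speller simulation and single-click auto-scan input.

In the k-division method each command narrows the candidate set by a factor
k (screen quadrants for k = 4) until a single symbol remains, so an
|alphabet| of at most k^d costs d operations per character.  The four
commands map to quadrants: right (EOG) -> lower right, left (EOG) -> lower
left, right blink (sEMG) -> upper right, left blink (sEMG) -> upper left.
The 2-division variants use a single modality (right/left saccades, or
right/left blinks).

The auto-scan mode is for users who can produce only one reliable pattern:
software highlights symbols in sequence and a single recognized pattern
(click) selects the highlighted one.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np

#: branch order upper-left, upper-right, lower-left, lower-right
BRANCH_COMMANDS = {
    4: ("left_blink", "right_blink", "left", "right"),
    2: ("left", "right"),
}


def default_alphabet() -> list[str]:
    """65 symbols: 26 letters, 10 digits, space, punctuation and control
    tokens — the smallest round set giving depth 4 at k=4 and depth 7 at k=2."""
    symbols = list(string.ascii_lowercase) + list(string.digits) + [" "]
    symbols += list(".,!?;:'\"-()&@/+=*#")
    symbols += ["<del>", "<enter>", "<shift>", "<caps>", "<tab>",
                "<esc>", "<home>", "<end>", "<pgup>", "<pgdn>"]
    assert len(symbols) == 65
    return symbols


@dataclass
class SelectionTree:
    """Balanced k-ary division tree with symbols at the leaves in order."""

    k: int
    alphabet: tuple
    depth: int
    paths: dict            # symbol -> tuple of branch indices
    commands: tuple        # command name per branch index

    def depth_of(self, symbol: str) -> int:
        return len(self.paths[symbol])


def build_tree(alphabet, k: int, commands: tuple | None = None) -> SelectionTree:
    """Build the division tree: depth = ceil(log_k |alphabet|)."""
    alphabet = list(alphabet)
    if not alphabet:
        raise ValueError("alphabet must be non-empty")
    if k not in (2, 4):
        raise ValueError("k must be 2 or 4")
    if len(set(alphabet)) != len(alphabet):
        raise ValueError("alphabet symbols must be unique")
    commands = tuple(commands) if commands else BRANCH_COMMANDS[k]
    if len(commands) != k:
        raise ValueError(f"need exactly {k} commands")
    depth = 1
    while k ** depth < len(alphabet):
        depth += 1
    paths = {}
    for idx, sym in enumerate(alphabet):
        digits = []
        rem = idx
        for _ in range(depth):
            digits.append(rem % k)
            rem //= k
        paths[sym] = tuple(reversed(digits))
    return SelectionTree(k=k, alphabet=tuple(alphabet), depth=depth,
                         paths=paths, commands=commands)


@dataclass
class SpellerConfig:
    """Timing and command-error model for spelling simulations.

    ``per_operation_time`` is the wall time one command costs (decision +
    recognition latency), on top of the ``control_interval`` tick of the
    interface loop.  ``miss_prob`` issues a wrong command (a random other
    branch); ``reject_prob`` loses the command (the step is retried).
    ``command_error_model`` may override both per command name.
    """

    control_interval: float = 0.1
    per_operation_time: float = 1.5625
    miss_prob: float = 0.0
    reject_prob: float = 0.0
    command_error_model: dict = field(default_factory=dict)
    scan_period: float = 1.0
    max_ops_per_char: int = 1000

    def __post_init__(self):
        if self.control_interval <= 0:
            raise ValueError("control_interval must be > 0")
        for p in (self.miss_prob, self.reject_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def probs_for(self, command: str) -> tuple[float, float]:
        d = self.command_error_model.get(command, {})
        return (d.get("miss", self.miss_prob), d.get("reject", self.reject_prob))


@dataclass
class SpellerResult:
    total_time: float
    operations: int
    miss_rate: float       # percent of issued commands that were misses
    transcript: str
    misses: int = 0
    rejects: int = 0
    timed_out: bool = False

    def to_dict(self) -> dict:
        return {"total_time_s": self.total_time, "operations": self.operations,
                "miss_rate_pct": self.miss_rate, "transcript": self.transcript,
                "misses": self.misses, "rejects": self.rejects,
                "timed_out": self.timed_out}


def simulate_spelling(text, tree: SelectionTree, cfg: SpellerConfig,
                      seed: int = 0) -> SpellerResult:
    """Walk the tree once per character, issuing commands with errors.

    A missed (wrong-branch) command restarts the current character's descent
    — the partial path is wasted.  A rejected command is simply repeated.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    ops = misses = rejects = 0
    transcript = []
    timed_out = False
    for ch in text:
        if ch not in tree.paths:
            raise ValueError(f"symbol {ch!r} not in alphabet")
        path = tree.paths[ch]
        pos = 0
        guard = 0
        while pos < len(path):
            guard += 1
            if guard > cfg.max_ops_per_char:
                timed_out = True
                break
            cmd = tree.commands[path[pos]]
            p_miss, p_reject = cfg.probs_for(cmd)
            u = rng.random()
            ops += 1
            if u < p_reject:
                rejects += 1            # command not registered; retry step
            elif u < p_reject + p_miss:
                misses += 1
                pos = 0                 # wrong quadrant; restart this character
            else:
                pos += 1
        if timed_out:
            break
        transcript.append(ch)
    return SpellerResult(
        total_time=ops * cfg.per_operation_time,
        operations=ops,
        miss_rate=100.0 * misses / ops if ops else 0.0,
        transcript="".join(transcript),
        misses=misses, rejects=rejects, timed_out=timed_out)


def simulate_scanner(text, alphabet, scan_period: float,
                     miss_prob: float = 0.0, seed: int = 0,
                     max_cycles: int = 100) -> SpellerResult:
    """Linear auto-scan: the highlight advances every ``scan_period``; one
    recognized pattern selects the highlighted symbol.

    A missed click costs a full extra cycle over the alphabet.  Error-free,
    the time per character equals ``scan_period`` times the symbol's
    1-based position, so uniformly distributed text averages
    ``scan_period * (n + 1) / 2`` per character.
    """
    if scan_period <= 0:
        raise ValueError("scan_period must be > 0")
    alphabet = list(alphabet)
    n = len(alphabet)
    rng = np.random.default_rng(seed)
    time = 0.0
    clicks = failed = 0
    transcript = []
    timed_out = False
    for ch in text:
        if ch not in alphabet:
            raise ValueError(f"symbol {ch!r} not in alphabet")
        pos = alphabet.index(ch) + 1
        cycles = 0
        while True:
            cycles += 1
            if cycles > max_cycles:
                timed_out = True
                break
            time += pos * scan_period       # highlight reaches the target
            if rng.random() >= miss_prob:
                clicks += 1
                break
            failed += 1
            time += (n - pos) * scan_period  # completes the wasted cycle
        if timed_out:
            break
        transcript.append(ch)
    attempts = clicks + failed
    return SpellerResult(
        total_time=time, operations=clicks,
        miss_rate=100.0 * failed / attempts if attempts else 0.0,
        transcript="".join(transcript),
        misses=failed, rejects=0, timed_out=timed_out)
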