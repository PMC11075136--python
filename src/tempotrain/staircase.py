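"""Adaptive time-compression tracking procedure.

One-up/one-down staircase on the time-compression ratio of IEEE sentences:
a sentence with three or more of its five keywords repeated correctly moves
the track up (more compression, faster speech); three or more keywords wrong
moves it down.  The track starts at 20% compression with a 10% step, drops
to a 5% step after the second reversal, and runs for a fixed 30-sentence
block.  Stimuli exist at 5–95% compression in 5% steps, so levels are
clamped to that grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from .psychometric import PsychometricCurve, _prob


class InvalidStateError(ValueError):
    """The staircase was asked to proceed from an off-grid or out-of-range level."""


class ResponderContractError(ValueError):
    """A responder returned something other than an integer keyword count 0..5."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the adaptive procedure (defaults are the study's)."""

    level_min: float = 5.0
    level_max: float = 95.0
    level_step_grid: float = 5.0
    start_level: float = 20.0
    initial_step: float = 10.0
    reduced_step: float = 5.0
    reversals_before_reduction: int = 2
    trials_per_block: int = 30
    keywords_per_sentence: int = 5
    correct_majority: int = 3

    def __post_init__(self) -> None:
        g = self.level_step_grid
        for name in ("start_level", "initial_step", "reduced_step"):
            v = getattr(self, name)
            if abs(v / g - round(v / g)) > 1e-9:
                raise ValueError(f"{name}={v} is not a multiple of the {g}% grid")
        if not (self.level_min < self.start_level < self.level_max):
            raise ValueError("start_level must lie strictly inside [level_min, level_max]")
        if not self.correct_majority > self.keywords_per_sentence / 2:
            raise ValueError("correct_majority must be a strict majority of the keywords")

    def on_grid(self, level: float) -> bool:
        g = self.level_step_grid
        return (
            self.level_min - 1e-9 <= level <= self.level_max + 1e-9
            and abs(level / g - round(level / g)) < 1e-9
        )


@dataclass(frozen=True)
class TrialRecord:
    """One sentence presentation inside a block.

    ``step_in_force`` is the step size under which this trial's level was
    set; ``direction`` is the movement the response prescribes for the next
    trial ('up' iff the keyword majority was correct).
    """

    trial_index: int  # 1-based
    level: float
    n_correct: int
    direction: str  # 'up' | 'down'
    is_reversal: bool
    step_in_force: float
    sentence_id: Optional[int] = None


@dataclass
class SentencePool:
    """The 720-sentence IEEE corpus; blocks draw 30 identifiers without replacement.

    With ``exhaust_pool`` set, identifiers are additionally never reused
    across blocks drawn from the same pool object (study-wide no-repeat).
    """

    n_sentences: int = 720
    exhaust_pool: bool = False
    _used: set = field(default_factory=set, repr=False)

    def draw(self, rng: np.random.Generator, k: int) -> np.ndarray:
        if self.exhaust_pool:
            avail = np.array(sorted(set(range(self.n_sentences)) - self._used))
            if avail.size < k:
                raise ValueError("sentence pool exhausted")
            ids = rng.choice(avail, size=k, replace=False)
            self._used.update(int(i) for i in ids)
        else:
            ids = rng.choice(self.n_sentences, size=k, replace=False)
        return ids


def next_level(current_level: float, n_correct: int, step: float,
               config: StaircaseConfig = StaircaseConfig()) -> float:
    """Level prescribed for the next sentence by the word-majority rule.

    ≥3 of 5 keywords correct → up (harder); otherwise down.  The result is
    clamped to the available stimulus range and snapped to the 5% grid.
    """
    if not config.on_grid(current_level):
        raise InvalidStateError(f"current level {current_level} is off the stimulus grid")
    if not 0 <= n_correct <= config.keywords_per_sentence:
        raise ResponderContractError(f"keyword count {n_correct} outside 0..{config.keywords_per_sentence}")
    if n_correct >= config.correct_majority:
        nxt = current_level + step
    else:
        nxt = current_level - step
    nxt = min(max(nxt, config.level_min), config.level_max)
    g = config.level_step_grid
    return round(nxt / g) * g


def _check_count(n, config: StaircaseConfig) -> int:
    if not isinstance(n, (int, np.integer)) or not 0 <= int(n) <= config.keywords_per_sentence:
        raise ResponderContractError(
            f"responder must return an integer keyword count in 0..{config.keywords_per_sentence}, got {n!r}"
        )
    return int(n)


def run_block(
    responder: Callable[[float], int],
    config: StaircaseConfig = StaircaseConfig(),
    rng: Optional[np.random.Generator] = None,
    pool: Optional[SentencePool] = None,
) -> list[TrialRecord]:
    """Run one fixed-length adaptive block against a responder.

    ``responder`` maps a grid level to a keyword count 0..5.  A reversal is
    flagged on a trial whose prescribed direction differs from the previous
    trial's; the step drops from ``initial_step`` to ``reduced_step``
    starting with the level of the trial after the second reversal, and
    never reverts.  The final trial's response moves nothing.
    """
    rng = np.random.default_rng() if rng is None else rng
    sentence_ids = None
    if pool is not None:
        sentence_ids = pool.draw(rng, config.trials_per_block)

    records: list[TrialRecord] = []
    level = config.start_level
    step = config.initial_step
    prev_dir: Optional[str] = None
    n_reversals = 0

    for i in range(1, config.trials_per_block + 1):
        n = _check_count(responder(level), config)
        direction = "up" if n >= config.correct_majority else "down"
        is_rev = prev_dir is not None and direction != prev_dir
        records.append(
            TrialRecord(
                trial_index=i,
                level=level,
                n_correct=n,
                direction=direction,
                is_reversal=is_rev,
                step_in_force=step,
                sentence_id=None if sentence_ids is None else int(sentence_ids[i - 1]),
            )
        )
        if is_rev:
            n_reversals += 1
        step = (
            config.reduced_step
            if n_reversals >= config.reversals_before_reduction
            else config.initial_step
        )
        level = next_level(level, n, step, config)
        prev_dir = direction

    return records


def run_track(
    responder: Callable[[float], int],
    n_trials: int,
    step: float,
    config: StaircaseConfig = StaircaseConfig(),
    start_level: Optional[float] = None,
) -> np.ndarray:
    """Long fixed-step track; returns the visited levels.

    Used for stationary-behaviour checks: with a constant step the track is
    a random walk on the stimulus grid whose stationary mean sits at the
    level where the up/down rule is balanced (see :func:`equilibrium_level`).
    """
    level = config.start_level if start_level is None else start_level
    levels = np.empty(n_trials)
    for i in range(n_trials):
        levels[i] = level
        n = _check_count(responder(level), config)
        level = next_level(level, n, step, config)
    return levels


def equilibrium_level(curve: PsychometricCurve,
                      config: StaircaseConfig = StaircaseConfig()) -> float:
    """Level at which the majority rule is equally likely to move up or down.

    Solves P(Binomial(5, p(L)) >= 3) = 1/2 by root bracketing.  For a
    zero-lapse curve the binomial median symmetry makes this the level where
    p = 0.5, i.e. exactly ``threshold_c50`` — the analytic oracle for
    staircase convergence.
    """
    n, m = config.keywords_per_sentence, config.correct_majority

    def g(level: float) -> float:
        p = float(_prob(curve, level))
        return float(binom.sf(m - 1, n, p)) - 0.5

    # g is strictly decreasing in level; bracket around the threshold.
    lo = curve.threshold_c50 - 300.0
    hi = curve.threshold_c50 + 300.0
    return float(brentq(g, lo, hi, xtol=1e-10))
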