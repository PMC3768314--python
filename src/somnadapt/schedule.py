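"""Adaptation and test trial schedules.

Adaptation: the observer is repeatedly exposed to the strongly extended face
(k = +6) at a random screen position.  Four presentation durations (0.5, 2,
4, 6 s) are counterbalanced with three image sizes, giving 12 distinct
trials per cycle; four cycles form a block and six blocks are run, for a
total of 288 trials and 900 s of cumulative exposure.  Trial order is
randomized within each cycle (a global shuffle would break the per-cycle
counterbalancing).

Test: the 13 continuum levels are shown once per repetition in randomized
order, 2 s each; the observer judges each image compressed vs extended
(2AFC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .stimulus import LEVELS

__all__ = [
    "DURATIONS",
    "SIZES",
    "CANVAS",
    "AdaptationTrial",
    "TestTrial",
    "TrialSchedule",
    "build_adaptation_schedule",
    "build_test_schedule",
]

DURATIONS = (0.5, 2.0, 4.0, 6.0)  # seconds
SIZES = {"small": (180, 240), "medium": (240, 320), "large": (300, 400)}  # w x h px
CANVAS = (1024, 768)  # screen resolution, px
N_BLOCKS = 6
N_CYCLES = 4
TEST_DURATION = 2.0  # seconds per test stimulus
FIXATION = 1.0  # fixation cross before each adaptation stimulus
BLOCK_BREAK = 30.0  # seconds between adaptation blocks (metadata only)


@dataclass(frozen=True)
class AdaptationTrial:
    duration: float
    size: str
    position: tuple[int, int]  # center of the image on the canvas
    block: int
    cycle: int
    onset: float  # seconds from schedule start, breaks included

    def __post_init__(self):
        if self.duration not in DURATIONS:
            raise ValueError(f"duration {self.duration} not in {DURATIONS}")
        if self.size not in SIZES:
            raise ValueError(f"size {self.size!r} not in {tuple(SIZES)}")
        if not (1 <= self.block <= N_BLOCKS and 1 <= self.cycle <= N_CYCLES):
            raise ValueError("block/cycle out of range")


@dataclass(frozen=True)
class TestTrial:
    k: int
    repetition: int
    duration: float = TEST_DURATION

    def __post_init__(self):
        if self.k not in LEVELS:
            raise ValueError(f"k={self.k} outside [-6, +6]")


@dataclass
class TrialSchedule:
    """An ordered, seed-reproducible list of trials."""

    trials: list
    seed: int
    kind: str  # "adaptation" | "test"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def total_exposure(self) -> float:
        """Cumulative stimulus-on time in seconds."""
        return float(sum(t.duration for t in self.trials))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.trials):
            if isinstance(t, AdaptationTrial):
                rows.append(
                    dict(index=i, block=t.block, cycle=t.cycle, duration=t.duration,
                         size=t.size, x=t.position[0], y=t.position[1], onset=t.onset)
                )
            else:
                rows.append(dict(index=i, repetition=t.repetition, k=t.k, duration=t.duration))
        return pd.DataFrame(rows)


def _random_position(rng: np.random.Generator, size: str) -> tuple[int, int]:
    # uniform over centers that keep the image fully on the canvas
    w, h = SIZES[size]
    cw, ch = CANVAS
    x = int(rng.integers(w // 2, cw - w // 2 + 1))
    y = int(rng.integers(h // 2, ch - h // 2 + 1))
    return (x, y)


def build_adaptation_schedule(seed: int = 0) -> TrialSchedule:
    """6 blocks x 4 cycles x 12 counterbalanced (duration, size) trials.

    Each cycle contains every duration-by-size pair exactly once, shuffled
    independently per cycle; positions are uniform on the canvas.  The
    duration multiset is fixed by the counterbalancing, so the 900-s total
    exposure is invariant to the seed.
    """
    rng = np.random.default_rng(seed)
    pairs = list(product(DURATIONS, SIZES))
    trials: list[AdaptationTrial] = []
    clock = 0.0
    for block in range(1, N_BLOCKS + 1):
        for cycle in range(1, N_CYCLES + 1):
            order = rng.permutation(len(pairs))
            for idx in order:
                duration, size = pairs[idx]
                clock += FIXATION
                trials.append(
                    AdaptationTrial(
                        duration=duration,
                        size=size,
                        position=_random_position(rng, size),
                        block=block,
                        cycle=cycle,
                        onset=clock,
                    )
                )
                clock += duration
        if block < N_BLOCKS:
            clock += BLOCK_BREAK
    return TrialSchedule(
        trials=trials,
        seed=seed,
        kind="adaptation",
        metadata={"block_break_s": BLOCK_BREAK, "fixation_s": FIXATION, "canvas": CANVAS},
    )


def build_test_schedule(repetitions: int, seed: int = 0) -> TrialSchedule:
    """``repetitions`` independent random permutations of the 13 levels."""
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = np.random.default_rng(seed)
    trials: list[TestTrial] = []
    for rep in range(1, repetitions + 1):
        for k in rng.permutation(LEVELS):
            trials.append(TestTrial(k=int(k), repetition=rep))
    return TrialSchedule(trials=trials, seed=seed, kind="test")
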