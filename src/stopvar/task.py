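"""Stop-signal task structure: design parameters, trial records, sessions.

The task presents a speeded two-choice reaction to a left/right arrow.
On a minority of trials (stop trials) the arrow changes colour after a
stop-signal delay (SSD) and the response must be withheld.  The SSD is
staircased (up after a successful stop, down after a failed one) so that
stopping succeeds on roughly half of the stop trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .exceptions import ConfigurationError

Kind = Literal["go", "stop"]
Direction = Literal["left", "right"]
Response = Literal["left", "right", "none"]


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept an int seed, ``None`` or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass(frozen=True)
class TaskDesign:
    """Structural parameters of the stop-signal task.

    Defaults reproduce the standard visual stop-signal protocol: two
    blocks of 128 trials (96 go, 32 stop), stop trials preceded by
    1, 2, 4 or 5 go trials, SSD staircase starting at 250 ms with 50-ms
    steps, a 1500-ms response deadline, and inter-trial fixation
    jittered between 2000 and 4000 ms (extended by 1500 ms minus the RT
    after a response, which equalises trial duration).
    """

    n_blocks: int = 2
    trials_per_block: int = 128
    stop_fraction: float = 0.25
    gap_pattern: tuple[int, ...] = (1, 2, 4, 5)
    ssd_start: float = 250.0
    ssd_step: float = 50.0
    max_rt: float = 1500.0
    iti_jitter: tuple[float, float] = (2000.0, 4000.0)

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.trials_per_block < 1:
            raise ConfigurationError("need at least one block and one trial per block")
        n_stop = self.stop_fraction * self.trials_per_block
        if abs(n_stop - round(n_stop)) > 1e-9:
            raise ConfigurationError(
                f"stop_fraction*trials_per_block must be an integer, got {n_stop}"
            )
        if not 0.0 <= self.stop_fraction < 1.0:
            raise ConfigurationError("stop_fraction must be in [0, 1)")
        if self.ssd_step <= 0:
            raise ConfigurationError("ssd_step must be positive")
        if self.max_rt <= 0:
            raise ConfigurationError("max_rt must be positive")
        if any(g < 1 for g in self.gap_pattern):
            raise ConfigurationError("gap lengths must be >= 1")
        lo, hi = self.iti_jitter
        if lo < 0 or hi < lo:
            raise ConfigurationError("iti_jitter must satisfy 0 <= min <= max")

    @property
    def n_stop_per_block(self) -> int:
        return int(round(self.stop_fraction * self.trials_per_block))

    @property
    def n_go_per_block(self) -> int:
        return self.trials_per_block - self.n_stop_per_block

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class TrialRecord:
    """One trial of a stop-signal session.

    ``ssd`` is present iff the trial is a stop trial; ``rt`` iff a
    response was emitted.  Units: ssd/rt in ms, onset in seconds from
    run start.
    """

    index: int
    block: int
    kind: Kind
    direction: Direction
    ssd: Optional[float] = None
    response: Response = "none"
    rt: Optional[float] = None
    onset: Optional[float] = None

    @property
    def responded(self) -> bool:
        return self.response != "none"

    @property
    def is_successful_stop(self) -> bool:
        return self.kind == "stop" and not self.responded

    @property
    def is_correct_go(self) -> bool:
        return self.kind == "go" and self.responded and self.response == self.direction


@dataclass
class ParticipantSession:
    """One subject's ordered trials plus group label and (simulated) truth."""

    subject_id: str
    group: str
    design: TaskDesign
    trials: list[TrialRecord] = field(default_factory=list)
    truth: Optional[object] = None  # RaceModelParams when simulated

    def __post_init__(self) -> None:
        if self.trials and len(self.trials) != self.design.n_trials:
            raise ConfigurationError(
                f"session has {len(self.trials)} trials, design expects {self.design.n_trials}"
            )

    @property
    def stop_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "stop"]

    @property
    def go_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.kind == "go"]


def _gap_multiset(design: TaskDesign, rng: np.random.Generator) -> np.ndarray:
    """Shuffled go-run lengths preceding each stop trial of one block.

    Each gap value is used equally often; the multiset must tile the
    block exactly (n_stop gaps summing to the block's go-trial count).
    """
    n_stop, n_go = design.n_stop_per_block, design.n_go_per_block
    pattern = design.gap_pattern
    if n_stop % len(pattern) != 0:
        raise ConfigurationError(
            f"{n_stop} stop trials cannot use each gap in {pattern} equally often"
        )
    reps = n_stop // len(pattern)
    if reps * sum(pattern) != n_go:
        raise ConfigurationError(
            f"gap multiset {reps}x{pattern} sums to {reps * sum(pattern)}, "
            f"but the block has {n_go} go trials"
        )
    gaps = np.repeat(pattern, reps)
    rng.shuffle(gaps)
    return gaps


def generate_trial_sequence(design: TaskDesign, rng_seed=None) -> list[TrialRecord]:
    """Pseudo-randomised trial kinds and directions for a full session.

    Each block concatenates [gap go trials..., stop trial] segments so
    every stop trial is preceded by a go-run whose length is drawn
    (balanced) from ``design.gap_pattern``.  Arrow directions are
    balanced left/right within each block to within one trial.
    """
    rng = as_rng(rng_seed)
    trials: list[TrialRecord] = []
    idx = 0
    for block in range(design.n_blocks):
        kinds: list[Kind] = []
        if design.n_stop_per_block == 0:
            kinds = ["go"] * design.trials_per_block
        else:
            for gap in _gap_multiset(design, rng):
                kinds.extend(["go"] * int(gap))
                kinds.append("stop")
        n = len(kinds)
        directions = np.array(["left"] * (n // 2) + ["right"] * (n - n // 2))
        rng.shuffle(directions)
        for kind, direction in zip(kinds, directions):
            trials.append(TrialRecord(index=idx, block=block, kind=kind, direction=str(direction)))
            idx += 1
    return trials
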