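"""Task universe for the four-alternative stimulus-response learning task.

A learning block presents four novel stimuli that map one-to-one onto four
fixed response keys (``d``, ``f``, ``k``, ``l``).  Feedback is deterministic:
a response is rewarded iff it is the stimulus's unique correct response.  A
block ends once every stimulus has been answered correctly eight times, or
after 70 trials.  A session consists of 20 such blocks, each with a fresh
random mapping.

Stimuli and responses are 0-based integer indices internally; all file I/O
and reports use 1-based stimulus labels ``S1..S4`` and the response letters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical keyboard order of the response keys.
DEFAULT_RESPONSE_LABELS: tuple[str, ...] = ("d", "f", "k", "l")

#: A stimulus->response bijection, as a tuple where entry ``i`` is the
#: correct response index for stimulus ``i``.
Mapping = tuple[int, ...]


@dataclass(frozen=True)
class TaskConfig:
    """Structural constants of the learning task.

    Parameters
    ----------
    n_stimuli, n_responses
        Number of stimuli and responses per block (equal; the task is
        one-to-one).
    response_labels
        Ordered response key labels; the canonical order is keyboard order
        ``d < f < k < l``.
    correct_reps_to_finish
        Correct repetitions per stimulus required to end a block (8).
    max_trials
        Hard cap on trials per block (70).
    """

    n_stimuli: int = 4
    n_responses: int = 4
    response_labels: tuple[str, ...] = DEFAULT_RESPONSE_LABELS
    correct_reps_to_finish: int = 8
    max_trials: int = 70

    def __post_init__(self) -> None:
        if self.n_stimuli != self.n_responses:
            raise ValueError("task is one-to-one: n_stimuli must equal n_responses")
        if len(self.response_labels) != self.n_responses:
            raise ValueError("response_labels length must equal n_responses")
        if self.correct_reps_to_finish < 1:
            raise ValueError("correct_reps_to_finish must be >= 1")
        if self.max_trials < self.n_stimuli:
            raise ValueError("max_trials must be >= n_stimuli")


DEFAULT_CONFIG = TaskConfig()


def validate_mapping(mapping: Sequence[int], n: int = 4) -> Mapping:
    """Check that ``mapping`` is a permutation of ``range(n)`` and return it
    as a tuple."""
    m = tuple(int(x) for x in mapping)
    if len(m) != n or sorted(m) != list(range(n)):
        raise ValueError(f"mapping {mapping!r} is not a permutation of range({n})")
    return m


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus/response/feedback event.

    ``block_id`` and ``trial_index`` are 1-based identifiers; ``stimulus``
    and ``response`` are 0-based indices.  ``feedback`` is True for positive
    (correct) feedback.
    """

    block_id: int
    trial_index: int
    stimulus: int
    response: int
    feedback: bool


@dataclass
class Block:
    """A learning block: its ground-truth mapping and ordered trials."""

    block_id: int
    mapping: Mapping
    trials: list[TrialRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class SubjectDataset:
    """All learning blocks of one subject, ordered by block_id."""

    subject_id: str
    blocks: list[Block] = field(default_factory=list)

    def block(self, block_id: int) -> Block:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(f"no block {block_id} for subject {self.subject_id}")

    def select_blocks(self, block_ids: Iterable[int]) -> list[Block]:
        return [self.block(i) for i in block_ids]


def feedback_for(mapping: Sequence[int], stimulus: int, response: int) -> bool:
    """Deterministic feedback rule: positive iff ``response`` is the correct
    response for ``stimulus`` under ``mapping``."""
    n = len(mapping)
    if not (0 <= stimulus < n):
        raise ValueError(f"stimulus index {stimulus} out of range for n={n}")
    if not (0 <= response < n):
        raise ValueError(f"response index {response} out of range for n={n}")
    return mapping[stimulus] == response


def correct_counts(trials: Iterable[TrialRecord], n_stimuli: int = 4) -> np.ndarray:
    """Number of positive-feedback trials per stimulus so far."""
    counts = np.zeros(n_stimuli, dtype=int)
    for t in trials:
        if t.feedback:
            counts[t.stimulus] += 1
    return counts


def block_finished(trials: Sequence[TrialRecord], config: TaskConfig = DEFAULT_CONFIG) -> bool:
    """Block termination rule: every stimulus correct ``correct_reps_to_finish``
    times, or the ``max_trials`` cap reached."""
    if len(trials) >= config.max_trials:
        return True
    counts = correct_counts(trials, config.n_stimuli)
    return bool(np.all(counts >= config.correct_reps_to_finish))


def validate_block(block: Block, config: TaskConfig = DEFAULT_CONFIG) -> None:
    """Raise ValueError if ``block`` violates any structural invariant:
    consecutive 1-based trial indices, the deterministic-feedback rule, and
    the termination rule."""
    validate_mapping(block.mapping, config.n_stimuli)
    for i, t in enumerate(block.trials, start=1):
        if t.trial_index != i:
            raise ValueError(
                f"block {block.block_id}: trial_index {t.trial_index} at position {i}"
            )
        if t.block_id != block.block_id:
            raise ValueError(f"trial {i} carries block_id {t.block_id} != {block.block_id}")
        if t.feedback != feedback_for(block.mapping, t.stimulus, t.response):
            raise ValueError(
                f"block {block.block_id} trial {i}: feedback inconsistent with mapping"
            )
    n = len(block.trials)
    if n > config.max_trials:
        raise ValueError(f"block {block.block_id} has {n} > {config.max_trials} trials")
    if n < config.max_trials:
        counts = correct_counts(block.trials, config.n_stimuli)
        if not np.all(counts == config.correct_reps_to_finish):
            raise ValueError(
                f"block {block.block_id} ended early without "
                f"{config.correct_reps_to_finish} correct reps per stimulus"
            )
    if not block_finished(block.trials, config):
        raise ValueError(f"block {block.block_id} is not finished")


def stimulus_label(index: int) -> str:
    return f"S{index + 1}"


def response_label(index: int, labels: Sequence[str] = DEFAULT_RESPONSE_LABELS) -> str:
    return labels[index]
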