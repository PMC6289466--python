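"""Ideal-observer bookkeeping over one-to-one stimulus-response mappings.

With 4 stimuli and 4 responses there are 4! = 24 candidate mappings.  Under
deterministic feedback every trial either falsifies the tried pair (negative
feedback: drop all mappings containing it) or confirms it (positive
feedback: keep only mappings containing it).  The set of mappings consistent
with the observed stimulus-response-outcome history is the full state of the
ideal observer; per-pair correctness probabilities are exact counting
fractions over that set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np

from .task import Mapping, TrialRecord


class InconsistentHistoryError(ValueError):
    """The conditioning history is compatible with no one-to-one mapping.

    Cannot occur for data produced under deterministic feedback from a true
    mapping; signals corrupted or mislabelled input."""


def enumerate_mappings(n: int) -> list[Mapping]:
    """All n! stimulus->response bijections in lexicographic order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return list(itertools.permutations(range(n)))


@dataclass(frozen=True)
class ConsistencySet:
    """An explicit set of candidate mappings, ordered lexicographically."""

    members: tuple[Mapping, ...]
    n: int = 4

    @classmethod
    def full(cls, n: int = 4) -> "ConsistencySet":
        return cls(members=tuple(enumerate_mappings(n)), n=n)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, mapping: Sequence[int]) -> bool:
        return tuple(mapping) in self.members

    def condition(self, stimulus: int, response: int, feedback: bool) -> "ConsistencySet":
        """Condition on one trial outcome.

        Positive feedback keeps only mappings pairing ``stimulus`` with
        ``response`` (which also blocks that response for every other
        stimulus); negative feedback drops them.
        """
        if feedback:
            kept = tuple(m for m in self.members if m[stimulus] == response)
        else:
            kept = tuple(m for m in self.members if m[stimulus] != response)
        if not kept:
            raise InconsistentHistoryError(
                f"no mapping consistent with history after conditioning on "
                f"stimulus={stimulus}, response={response}, feedback={feedback}"
            )
        return ConsistencySet(members=kept, n=self.n)

    @cached_property
    def counts(self) -> np.ndarray:
        """Integer matrix: counts[i, j] = number of members mapping i -> j."""
        arr = np.asarray(self.members, dtype=int)
        out = np.zeros((self.n, self.n), dtype=int)
        for i in range(self.n):
            out[i] = np.bincount(arr[:, i], minlength=self.n)
        return out

    def marginals(self) -> np.ndarray:
        """Per-pair probability of being correct: counts / |members|.

        Every row sums to 1; entries are exact fractions of the member
        count (computed by counting, not sampling).
        """
        return self.counts / len(self.members)


def update_consistency(
    cset: ConsistencySet, stimulus: int, response: int, feedback: bool
) -> ConsistencySet:
    """Functional alias for :meth:`ConsistencySet.condition`."""
    return cset.condition(stimulus, response, feedback)


def marginal_probabilities(cset: ConsistencySet) -> np.ndarray:
    """Functional alias for :meth:`ConsistencySet.marginals`."""
    if len(cset) == 0:  # pragma: no cover - unreachable via public API
        raise InconsistentHistoryError("empty consistency set")
    return cset.marginals()


def replay_history(trials: Iterable[TrialRecord], n: int = 4) -> list[ConsistencySet]:
    """Prefix states of the consistency set along a block's history.

    Element ``t`` is the set after conditioning on trials ``1..t``; element
    0 is the full n!-member set.
    """
    states = [ConsistencySet.full(n)]
    for tr in trials:
        states.append(states[-1].condition(tr.stimulus, tr.response, tr.feedback))
    return states
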