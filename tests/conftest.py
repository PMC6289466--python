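import numpy as np
import pytest

import drplearn as dl
from drplearn.task import TrialRecord


def make_trials(events, block_id=1):
    """Build TrialRecords from (stimulus, response, feedback) triples."""
    return [
        TrialRecord(block_id=block_id, trial_index=i, stimulus=s, response=r, feedback=bool(fb))
        for i, (s, r, fb) in enumerate(events, start=1)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def worked_history():
    """The three-trial ideal-observer walkthrough: S1->d negative,
    S2->l negative, S3->f positive (consistency sizes 24,18,14,3)."""
    return make_trials([(0, 0, 0), (1, 3, 0), (2, 1, 1)])


@pytest.fixture
def drp_walkthrough():
    """The six-trial dfkl response-pattern walkthrough: mapping
    S1->f, S2->d, S3->l, S4->k with stimulus sequence S1,S2,S1,S3,S3,S4."""
    return {
        "mapping": (1, 0, 3, 2),
        "stimuli": [0, 1, 0, 2, 2, 3],
        "responses": [0, 0, 1, 2, 3, 2],  # d d f k l k
        "feedback": [False, True, True, False, True, True],
    }


def random_consistent_history(rng, max_len=8):
    """A random S-R-O history generated under a random true mapping
    (hence consistent with at least that mapping)."""
    mapping = tuple(int(x) for x in rng.permutation(4))
    length = int(rng.integers(0, max_len + 1))
    events = []
    for _ in range(length):
        s = int(rng.integers(4))
        r = int(rng.integers(4))
        events.append((s, r, mapping[s] == r))
    return make_trials(events), mapping


def mc_marginals(history, n_samples, rng, min_kept=None):
    """Monte-Carlo rejection oracle for ideal-observer marginals: sample
    uniform permutations, keep the history-consistent ones, tabulate.

    When ``min_kept`` is set, batches of ``n_samples`` accumulate until
    that many consistent samples survive, keeping the oracle's own error
    small even for restrictive histories.
    """
    counts = np.zeros((4, 4))
    total_kept = 0
    while True:
        perms = rng.permuted(np.tile(np.arange(4), (n_samples, 1)), axis=1)
        ok = np.ones(n_samples, dtype=bool)
        for tr in history:
            if tr.feedback:
                ok &= perms[:, tr.stimulus] == tr.response
            else:
                ok &= perms[:, tr.stimulus] != tr.response
        kept = perms[ok]
        for i in range(4):
            counts[i] += np.bincount(kept[:, i], minlength=4)
        total_kept += len(kept)
        if min_kept is None or total_kept >= min_kept:
            break
    return counts / total_kept


@pytest.fixture
def tiny_cohort():
    """Three-subject cohort (one DRP, one FOP, one Q) with 20 blocks."""
    spec = dl.CohortSpec(
        groups=(
            dl.CohortGroup(dl.ModelSpec("DRP", 0.2, order="dfkl"), 1),
            dl.CohortGroup(dl.ModelSpec("FOP", 0.2), 1),
            dl.CohortGroup(dl.ModelSpec("Q", 0.25, alpha=0.5), 1),
        ),
        seed=99,
    )
    return dl.generate_cohort(spec)
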