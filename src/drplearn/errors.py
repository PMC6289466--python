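"""Learning curves, error taxonomy, and generative model checks.

Every negative-feedback trial is classified against the *noise-free ideal
observer* evaluated on the observed history prefix (not against the
behaving model's internal state), so the same classifier applies to human
and simulated data alike:

* ``optimal`` - the chosen response had maximal probability of being
  correct;
* ``suboptimal`` - nonzero but not maximal probability;
* zero-probability errors, subdivided by how the impossibility was already
  knowable: ``repeatedly_wrong`` (this exact pair had failed before),
  ``correct_for_different_stimulus`` (the response was already confirmed
  for another stimulus), ``both_rw_and_cfds``, and
  ``neither_rw_nor_cfds`` (only an indirect inference revealed the correct
  response - e.g. three responses ruled out leaves one).

These six labels partition the errors; the overlapping seventh label
``after_first_correct`` marks errors on a stimulus that had already been
answered correctly.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import generate_block
from .consistency import ConsistencySet
from .fitting import DEFAULT_BLOCK_IDS, initial_phase_end, likelihood_window
from .models import ModelSpec
from .task import DEFAULT_CONFIG, Block, SubjectDataset, TaskConfig, TrialRecord


class ErrorCategory(str, Enum):
    OPTIMAL = "optimal"
    SUBOPTIMAL = "suboptimal"
    REPEATEDLY_WRONG = "repeatedly_wrong"
    CORRECT_FOR_DIFFERENT_STIMULUS = "correct_for_different_stimulus"
    BOTH_RW_AND_CFDS = "both_rw_and_cfds"
    NEITHER_RW_NOR_CFDS = "neither_rw_nor_cfds"
    AFTER_FIRST_CORRECT = "after_first_correct"


#: Mutually exclusive labels; every error carries exactly one of these.
PRIMARY_CATEGORIES = (
    ErrorCategory.OPTIMAL,
    ErrorCategory.SUBOPTIMAL,
    ErrorCategory.REPEATEDLY_WRONG,
    ErrorCategory.CORRECT_FOR_DIFFERENT_STIMULUS,
    ErrorCategory.BOTH_RW_AND_CFDS,
    ErrorCategory.NEITHER_RW_NOR_CFDS,
)


def classify_error(
    trial: TrialRecord,
    history: Sequence[TrialRecord],
    cset: Optional[ConsistencySet] = None,
) -> frozenset[ErrorCategory]:
    """Categories for one negative-feedback trial given its history prefix.

    ``cset`` may supply the consistency set already conditioned on
    ``history`` (to avoid recomputation during replays); it must match.
    """
    if trial.feedback:
        raise ValueError("classify_error applies to negative-feedback trials only")
    if cset is None:
        cset = ConsistencySet.full(4)
        for tr in history:
            cset = cset.condition(tr.stimulus, tr.response, tr.feedback)
    row = cset.counts[trial.stimulus]
    c = int(row[trial.response])
    cats: set[ErrorCategory] = set()
    if c == row.max():
        cats.add(ErrorCategory.OPTIMAL)
    elif c > 0:
        cats.add(ErrorCategory.SUBOPTIMAL)
    else:
        rw = any(
            (not tr.feedback) and tr.stimulus == trial.stimulus and tr.response == trial.response
            for tr in history
        )
        cfds = any(
            tr.feedback and tr.response == trial.response and tr.stimulus != trial.stimulus
            for tr in history
        )
        if rw and cfds:
            cats.add(ErrorCategory.BOTH_RW_AND_CFDS)
        elif rw:
            cats.add(ErrorCategory.REPEATEDLY_WRONG)
        elif cfds:
            cats.add(ErrorCategory.CORRECT_FOR_DIFFERENT_STIMULUS)
        else:
            cats.add(ErrorCategory.NEITHER_RW_NOR_CFDS)
    if any(tr.feedback and tr.stimulus == trial.stimulus for tr in history):
        cats.add(ErrorCategory.AFTER_FIRST_CORRECT)
    return frozenset(cats)


def block_error_counts(block: Block, initial_phase_only: bool = True) -> dict[ErrorCategory, int]:
    """Per-category error counts for one block (default: initial-phase
    trials only), via an incremental consistency-set replay."""
    trials = likelihood_window(block) if initial_phase_only else list(block.trials)
    counts = {cat: 0 for cat in ErrorCategory}
    cset = ConsistencySet.full(len(block.mapping))
    for i, tr in enumerate(trials):
        if not tr.feedback:
            for cat in classify_error(tr, trials[:i], cset):
                counts[cat] += 1
        cset = cset.condition(tr.stimulus, tr.response, tr.feedback)
    return counts


def count_optimal_errors(block: Block, initial_phase_only: bool = True) -> int:
    return block_error_counts(block, initial_phase_only)[ErrorCategory.OPTIMAL]


def error_profile(
    dataset: SubjectDataset,
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    initial_phase_only: bool = True,
) -> pd.Series:
    """Mean error count per category per block for one subject."""
    block_ids = tuple(block_ids)
    totals = {cat: 0 for cat in ErrorCategory}
    for b in block_ids:
        for cat, k in block_error_counts(dataset.block(b), initial_phase_only).items():
            totals[cat] += k
    return pd.Series({cat.value: totals[cat] / len(block_ids) for cat in ErrorCategory})


def cohort_error_profile(
    datasets: Sequence[SubjectDataset],
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    initial_phase_only: bool = True,
) -> pd.DataFrame:
    """Subjects x categories table of mean per-block error counts."""
    rows = {ds.subject_id: error_profile(ds, block_ids, initial_phase_only) for ds in datasets}
    return pd.DataFrame(rows).T.rename_axis("subject_id")


def learning_curves(
    datasets: Sequence[SubjectDataset],
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    alignment: str = "initial_phase",
    truncate_at: Optional[int] = 17,
) -> pd.DataFrame:
    """Probability-correct per within-block trial index, pooled over blocks.

    ``alignment="initial_phase"`` restricts each block to its initial
    learning phase (so the number of contributing blocks shrinks with the
    trial index); ``"full_block"`` uses all trials.  ``truncate_at`` caps
    the trial index (default 17; pass None or a larger value for the
    longer views).

    Returns a DataFrame with columns trial, mean, sem, n.
    """
    if alignment not in ("initial_phase", "full_block"):
        raise ValueError("alignment must be 'initial_phase' or 'full_block'")
    block_ids = tuple(block_ids)
    hits: dict[int, list[int]] = {}
    for ds in datasets:
        for b in block_ids:
            block = ds.block(b)
            end = len(block.trials)
            if alignment == "initial_phase":
                phase = initial_phase_end(block)
                end = phase if phase is not None else end
            for t, tr in enumerate(block.trials[:end], start=1):
                if truncate_at is not None and t > truncate_at:
                    break
                hits.setdefault(t, []).append(int(tr.feedback))
    rows = []
    for t in sorted(hits):
        v = np.asarray(hits[t], dtype=float)
        sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
        rows.append({"trial": t, "mean": v.mean(), "sem": sem, "n": len(v)})
    return pd.DataFrame(rows)


def generative_replay(
    spec: ModelSpec,
    dataset: SubjectDataset,
    n_reps: int = 1000,
    rng: Optional[np.random.Generator] = None,
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    config: TaskConfig = DEFAULT_CONFIG,
) -> list[SubjectDataset]:
    """Regenerate a subject's blocks from a fitted model.

    For each selected real block, simulates ``n_reps`` blocks with the same
    true mapping (stimulus sequences redrawn from the sequencing policy);
    each repetition becomes one pseudo-subject, ready for
    :func:`error_profile` and :func:`learning_curves`.
    """
    rng = np.random.default_rng() if rng is None else rng
    block_ids = tuple(block_ids)
    reps = []
    for rep in range(n_reps):
        blocks = [
            generate_block(spec, dataset.block(b).mapping, config, rng, block_id=b)
            for b in block_ids
        ]
        reps.append(SubjectDataset(subject_id=f"{dataset.subject_id}-rep{rep + 1}", blocks=blocks))
    return reps


def optimal_error_invariance_check(
    n_sequences: int = 20,
    n_fop_reps: int = 10_000,
    seed: int = 0,
    config: TaskConfig = DEFAULT_CONFIG,
) -> dict:
    """Sequence-invariance of the noise-free optimal-error distribution.

    For each of ``n_sequences`` random stimulus-sequencing streams (each
    with a random true mapping), runs all 24 noise-free DRP response orders
    and collects the multiset of per-block optimal-error counts.  The
    multiset is invariant across sequences; noise-free free optimal play,
    replayed ``n_fop_reps`` times, converges to the same distribution.

    Returns a report dict with the per-sequence multisets, an
    ``identical`` flag, both distributions, and their total-variation
    distance.
    """
    from .consistency import enumerate_mappings
    from .models import order_string

    root = np.random.SeedSequence(seed)
    seq_seeds = root.spawn(n_sequences + 1)
    orders = enumerate_mappings(config.n_responses)

    multisets = []
    for i in range(n_sequences):
        rng_map = np.random.default_rng(seq_seeds[i])
        mapping = tuple(int(x) for x in rng_map.permutation(config.n_stimuli))
        counts = []
        for order in orders:
            spec = ModelSpec("DRP", 0.0, order=order_string(order, config.response_labels))
            rng = np.random.default_rng(seq_seeds[i])  # same stream for every order
            rng.permutation(config.n_stimuli)  # skip the mapping draw
            block = generate_block(spec, mapping, config, rng)
            counts.append(count_optimal_errors(block))
        multisets.append(tuple(sorted(counts)))

    drp_values, drp_freq = np.unique(multisets[0], return_counts=True)
    drp_pmf = dict(zip(drp_values.tolist(), (drp_freq / drp_freq.sum()).tolist()))

    rng = np.random.default_rng(seq_seeds[n_sequences])
    fop_counts = np.empty(n_fop_reps, dtype=int)
    fop_spec = ModelSpec("FOP", 0.0)
    for r in range(n_fop_reps):
        mapping = tuple(int(x) for x in rng.permutation(config.n_stimuli))
        block = generate_block(fop_spec, mapping, config, rng)
        # noise-free FOP only ever selects maximal-probability responses,
        # so every error is an optimal error
        fop_counts[r] = sum(1 for tr in likelihood_window(block) if not tr.feedback)
    fv, ff = np.unique(fop_counts, return_counts=True)
    fop_pmf = dict(zip(fv.tolist(), (ff / ff.sum()).tolist()))

    support = set(drp_pmf) | set(fop_pmf)
    tv = 0.5 * sum(abs(drp_pmf.get(k, 0.0) - fop_pmf.get(k, 0.0)) for k in support)
    return {
        "multisets": multisets,
        "identical": len(set(multisets)) == 1,
        "drp_pmf": drp_pmf,
        "fop_pmf": fop_pmf,
        "tv_distance": tv,
    }
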