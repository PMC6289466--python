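"""Synthetic-subject generator.

Produces complete datasets (20 blocks per subject, fresh random mapping per
block) whose responses are sampled from a chosen model family with known
parameters, so that fitting, model comparison and error analyses can be
validated against ground truth.  Stimuli are presented in randomized order:
each trial draws uniformly among the stimuli that have not yet reached the
required number of correct repetitions (immediate repeats allowed).

All randomness flows from a master seed through per-subject
``numpy.random.SeedSequence`` children, so cohorts are bit-reproducible and
subjects are independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .models import ModelSpec, make_policy
from .task import (
    DEFAULT_CONFIG,
    Block,
    Mapping,
    SubjectDataset,
    TaskConfig,
    TrialRecord,
    block_finished,
    correct_counts,
    feedback_for,
)


@dataclass(frozen=True)
class CohortGroup:
    """``n_subjects`` generated from one model specification."""

    spec: ModelSpec
    n_subjects: int


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort; output is a pure function of
    this object (bit-reproducible)."""

    groups: tuple[CohortGroup, ...]
    seed: int
    n_blocks: int = 20
    config: TaskConfig = field(default=DEFAULT_CONFIG)

    @property
    def n_subjects(self) -> int:
        return sum(g.n_subjects for g in self.groups)


def generate_stimulus(trials, config: TaskConfig, rng: np.random.Generator) -> int:
    """Uniform draw among stimuli with fewer than the required correct
    repetitions so far."""
    counts = correct_counts(trials, config.n_stimuli)
    eligible = np.flatnonzero(counts < config.correct_reps_to_finish)
    return int(eligible[rng.integers(len(eligible))])


def generate_block(
    spec: ModelSpec,
    mapping: Mapping,
    config: TaskConfig = DEFAULT_CONFIG,
    rng: Optional[np.random.Generator] = None,
    block_id: int = 1,
) -> Block:
    """Simulate one block: model selects, deterministic feedback, model
    updates, until the termination rule fires."""
    rng = np.random.default_rng() if rng is None else rng
    policy = make_policy(spec, config)
    trials: list[TrialRecord] = []
    while not block_finished(trials, config):
        s = generate_stimulus(trials, config, rng)
        p = policy.response_probabilities(s, spec.tau)
        r = int(rng.choice(config.n_responses, p=p))
        fb = feedback_for(mapping, s, r)
        trials.append(
            TrialRecord(block_id=block_id, trial_index=len(trials) + 1, stimulus=s, response=r, feedback=fb)
        )
        policy.update(s, r, fb)
    return Block(block_id=block_id, mapping=mapping, trials=trials)


def random_mapping(rng: np.random.Generator, n: int = 4) -> Mapping:
    return tuple(int(x) for x in rng.permutation(n))


def generate_subject(
    subject_id: str,
    spec: ModelSpec,
    rng: np.random.Generator,
    n_blocks: int = 20,
    config: TaskConfig = DEFAULT_CONFIG,
) -> SubjectDataset:
    """One subject: ``n_blocks`` blocks, each with a fresh uniform-random
    mapping and a fresh policy state."""
    blocks = []
    for b in range(1, n_blocks + 1):
        mapping = random_mapping(rng, config.n_stimuli)
        blocks.append(generate_block(spec, mapping, config, rng, block_id=b))
    return SubjectDataset(subject_id=subject_id, blocks=blocks)


def generate_cohort(cohort: CohortSpec) -> tuple[list[SubjectDataset], dict]:
    """Generate all subjects plus a ground-truth manifest.

    The manifest records, per subject, the generating family/parameters and
    the derived seed, keyed by subject_id.
    """
    ss = np.random.SeedSequence(cohort.seed)
    children = ss.spawn(cohort.n_subjects)
    datasets: list[SubjectDataset] = []
    manifest: dict = {"seed": cohort.seed, "n_blocks": cohort.n_blocks, "subjects": {}}
    i = 0
    for group in cohort.groups:
        for _ in range(group.n_subjects):
            sid = f"sub-{i + 1:03d}"
            child = children[i]
            rng = np.random.default_rng(child)
            datasets.append(
                generate_subject(sid, group.spec, rng, cohort.n_blocks, cohort.config)
            )
            manifest["subjects"][sid] = {
                **group.spec.to_dict(),
                "label": group.spec.label,
                "seed_entropy": int(child.entropy),
                "spawn_key": [int(k) for k in child.spawn_key],
            }
            i += 1
    return datasets, manifest


def human_mix_spec(seed: int, tau: float = 0.25, alpha: float = 0.5) -> CohortSpec:
    """Cohort mirroring the reported human subsample composition
    (36 DRP-dfkl, 7 DRP-lkfd, 18 FOP, 19 BP, 5 Q = 85 subjects).

    The human study estimates no generative noise level; ``tau`` defaults to
    0.25, the middle of the low-noise fit range.
    """
    return CohortSpec(
        groups=(
            CohortGroup(ModelSpec("DRP", tau, order="dfkl"), 36),
            CohortGroup(ModelSpec("DRP", tau, order="lkfd"), 7),
            CohortGroup(ModelSpec("FOP", tau), 18),
            CohortGroup(ModelSpec("BP", tau), 19),
            CohortGroup(ModelSpec("Q", tau, alpha=alpha), 5),
        ),
        seed=seed,
    )


def recovery_cohort_spec(
    seed: int,
    n_per_family: int = 20,
    tau: float = 1.0 / 6.0,
    alpha: float = 0.5,
    families: Iterable[str] = ("DRP_dfkl", "FOP", "BP", "Q"),
) -> CohortSpec:
    """Model-recovery cohort: ``n_per_family`` subjects per generating
    family at a common noise level."""
    groups = []
    for label in families:
        if label.startswith("DRP_"):
            spec = ModelSpec("DRP", tau, order=label.split("_", 1)[1])
        elif label == "Q":
            spec = ModelSpec("Q", tau, alpha=alpha)
        else:
            spec = ModelSpec(label, tau)
        groups.append(CohortGroup(spec, n_per_family))
    return CohortSpec(groups=tuple(groups), seed=seed)
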