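"""Per-subject maximum-likelihood estimation by exhaustive grid search.

Models are fitted on the *initial learning phase* of blocks 6-20: the
trials from block start up to and including the trial on which the fourth
(last) stimulus is answered correctly for the first time.  Blocks 1-5 are
excluded so that fits reflect stabilized strategies.  One parameter vector
(tau, plus alpha for Q-learning) is fitted jointly across the 15 blocks;
per-block log-likelihoods at the optimum feed the paired signed-rank model
comparisons.

The likelihood evolves each model's state along the subject's *observed*
responses and feedback (not the model's preferred responses); the per-trial
contribution is the log softmax probability of the observed response.
Natural log throughout.  At tau = 0 a mispredicted trial has probability 0
and the block log-likelihood is -inf, which is a valid ordering value and
simply loses the argmax unless prediction is perfect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .consistency import enumerate_mappings
from .models import _ARGMAX_ATOL, ModelSpec, make_policy, order_string
from .task import DEFAULT_CONFIG, Block, SubjectDataset, TaskConfig, TrialRecord

#: The five-model space used for the hierarchical comparison.
MODEL_LABELS = ("DRP_dfkl", "DRP_lkfd", "FOP", "BP", "Q")

#: Default fitting window: learning blocks 6-20.
DEFAULT_BLOCK_IDS = tuple(range(6, 21))


def tau_grid() -> np.ndarray:
    """Noise grid: 0 plus reciprocals of 6.0, 5.8, ..., 0.2 (31 values)."""
    denoms = np.round(np.arange(6.0, 0.19, -0.2), 1)
    return np.concatenate(([0.0], 1.0 / denoms))


def alpha_grid() -> np.ndarray:
    """Learning-rate grid: 0.05, 0.10, ..., 1.00 (20 values, Q only)."""
    return np.round(np.arange(1, 21) * 0.05, 2)


def spec_from_label(label: str, tau: float = 0.0, alpha: Optional[float] = None) -> ModelSpec:
    """Build a ModelSpec from a model-space label like ``"DRP_dfkl"``."""
    if label.startswith("DRP_"):
        return ModelSpec("DRP", tau, order=label.split("_", 1)[1])
    if label == "Q":
        return ModelSpec("Q", tau, alpha=alpha if alpha is not None else 0.5)
    return ModelSpec(label, tau)


def all_model_labels(config: TaskConfig = DEFAULT_CONFIG) -> list[str]:
    """The 27-model space: all 24 DRP response orders plus FOP, BP, Q,
    in a fixed enumeration order (DRP orders lexicographic by index)."""
    labels = [
        "DRP_" + order_string(order, config.response_labels)
        for order in enumerate_mappings(config.n_responses)
    ]
    return labels + ["FOP", "BP", "Q"]


def initial_phase_end(block: Block) -> Optional[int]:
    """1-based index of the trial on which the last of the four stimuli is
    first answered correctly; None if some stimulus is never correct
    (70-trial cap hit with an unsolved stimulus)."""
    solved: set[int] = set()
    n = len(block.mapping)
    for i, t in enumerate(block.trials, start=1):
        if t.feedback:
            solved.add(t.stimulus)
            if len(solved) == n:
                return i
    return None


def likelihood_window(block: Block) -> list[TrialRecord]:
    """Trials entering the likelihood: the initial learning phase including
    its final trial; the whole block if the phase never completed."""
    end = initial_phase_end(block)
    return list(block.trials) if end is None else list(block.trials[:end])


def preference_trace(
    family: str,
    trials: Sequence[TrialRecord],
    alpha: Optional[float] = None,
    order: Optional[str] = None,
    config: TaskConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Preference rows along observed trials, with the state evolved by the
    observed responses/feedback.  tau plays no role here (it only scales
    selection), so one trace serves the whole tau grid.

    Returns (prefs: T x n, responses: T).
    """
    if family == "DRP" and order is None:
        raise ValueError("DRP trace requires an order")
    spec = spec_from_label(family if family in ("FOP", "BP", "Q") else f"DRP_{order}", 0.0, alpha)
    policy = make_policy(spec, config)
    prefs = np.empty((len(trials), config.n_responses))
    resp = np.empty(len(trials), dtype=int)
    for t, tr in enumerate(trials):
        prefs[t] = policy.preferences(tr.stimulus)
        resp[t] = tr.response
        policy.update(tr.stimulus, tr.response, tr.feedback)
    return prefs, resp


def ll_curve(prefs: np.ndarray, responses: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Log-likelihood of the observed responses for every tau in ``taus``.

    Vectorized log-softmax over (tau, trial, response); the tau = 0 entry
    uses the uniform-over-argmax rule and may be -inf.
    """
    taus = np.asarray(taus, dtype=float)
    out = np.empty(len(taus))
    T = len(responses)
    pos = taus > 0
    if pos.any():
        z = prefs[None, :, :] / taus[pos, None, None]
        z -= z.max(axis=2, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=2, keepdims=True))
        out[pos] = logp[:, np.arange(T), responses].sum(axis=1)
    if (~pos).any():
        mx = prefs.max(axis=1, keepdims=True)
        mask = prefs >= mx - _ARGMAX_ATOL
        chosen = mask[np.arange(T), responses]
        with np.errstate(divide="ignore"):
            ll0 = np.where(chosen, -np.log(mask.sum(axis=1)), -np.inf).sum()
        out[~pos] = ll0
    return out


def block_log_likelihood(
    spec: ModelSpec,
    block: Block,
    end_trial: Optional[int] = None,
    config: TaskConfig = DEFAULT_CONFIG,
) -> float:
    """Log-likelihood of one block's first ``end_trial`` trials under a
    fully parameterized model (default: the initial-phase window)."""
    trials = likelihood_window(block) if end_trial is None else list(block.trials[:end_trial])
    prefs, resp = preference_trace(spec.family, trials, spec.alpha, spec.order, config)
    return float(ll_curve(prefs, resp, np.array([spec.tau]))[0])


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one model to one subject."""

    subject_id: str
    label: str
    spec: ModelSpec
    block_ids: tuple[int, ...]
    block_ll: np.ndarray  # per-block LL at the best parameters
    total_ll: float

    def __post_init__(self) -> None:
        if not np.isneginf(self.total_ll):
            assert abs(self.total_ll - self.block_ll.sum()) < 1e-9


def fit_subject(
    label: str,
    dataset: SubjectDataset,
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    taus: Optional[np.ndarray] = None,
    alphas: Optional[np.ndarray] = None,
    config: TaskConfig = DEFAULT_CONFIG,
) -> FitResult:
    """Exhaustive grid search for one model on one subject.

    Parameters are shared across blocks; ties break to the first grid point
    in enumeration order (taus ascending; for Q, tau-major over alphas).
    """
    taus = tau_grid() if taus is None else np.asarray(taus, dtype=float)
    block_ids = tuple(block_ids)
    windows = [likelihood_window(dataset.block(b)) for b in block_ids]

    if label == "Q":
        alphas = alpha_grid() if alphas is None else np.asarray(alphas, dtype=float)
        # per alpha: (n_blocks, n_tau) LL table
        tables = np.empty((len(alphas), len(block_ids), len(taus)))
        for a_i, a in enumerate(alphas):
            for b_i, trials in enumerate(windows):
                prefs, resp = preference_trace("Q", trials, alpha=float(a), config=config)
                tables[a_i, b_i] = ll_curve(prefs, resp, taus)
        totals = tables.sum(axis=1)  # (n_alpha, n_tau)
        flat = np.argmax(totals.T)  # tau-major enumeration
        t_i, a_i = int(flat // len(alphas)), int(flat % len(alphas))
        best = ModelSpec("Q", float(taus[t_i]), alpha=float(alphas[a_i]))
        block_ll = tables[a_i, :, t_i]
        total = float(totals[a_i, t_i])
    else:
        family = "DRP" if label.startswith("DRP_") else label
        order = label.split("_", 1)[1] if family == "DRP" else None
        table = np.empty((len(block_ids), len(taus)))
        for b_i, trials in enumerate(windows):
            prefs, resp = preference_trace(family, trials, order=order, config=config)
            table[b_i] = ll_curve(prefs, resp, taus)
        totals = table.sum(axis=0)
        t_i = int(np.argmax(totals))
        best = spec_from_label(label, float(taus[t_i]))
        block_ll = table[:, t_i]
        total = float(totals[t_i])

    return FitResult(
        subject_id=dataset.subject_id,
        label=label,
        spec=best,
        block_ids=block_ids,
        block_ll=np.asarray(block_ll, dtype=float),
        total_ll=total,
    )


def fit_all_models(
    dataset: SubjectDataset,
    labels: Sequence[str] = MODEL_LABELS,
    block_ids: Iterable[int] = DEFAULT_BLOCK_IDS,
    config: TaskConfig = DEFAULT_CONFIG,
) -> dict[str, FitResult]:
    """Fit every model in ``labels`` to one subject."""
    block_ids = tuple(block_ids)
    return {lab: fit_subject(lab, dataset, block_ids, config=config) for lab in labels}
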