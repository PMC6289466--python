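"""The four trial-by-trial policy families: Q-learning, free optimal play
(FOP), binarized play (BP) and deterministic response patterns (DRP).

Each family exposes a per-stimulus *preference row* and a state update; the
shared softmax rule turns a preference row into response-selection
probabilities:

    p_j = exp(pref_j / tau) / sum_k exp(pref_k / tau),   tau > 0,

with the noise-free limit tau = 0 selecting uniformly among the maximizers
of the preference row.

* Q-learning keeps one associative weight q_ij per stimulus-response pair
  (initialized at 0, driven toward +1/-1 by positive/negative feedback with
  learning rate alpha); each pair is updated independently, so Q-learning
  cannot exploit the one-to-one structure of the mappings.
* FOP is the ideal observer: its preference row is the exact per-response
  probability of being correct given the consistency set over mappings.
* BP coarsens FOP by flattening each row to uniform over its nonzero
  entries (it excludes impossible responses but ignores graded evidence).
* DRP tests responses in a fixed order (e.g. ``dfkl``), skipping responses
  already assigned to other stimuli and exploiting forced inferences; its
  preference row is degenerate (probability 1 on the designated response).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .consistency import ConsistencySet
from .task import DEFAULT_CONFIG, TaskConfig

FAMILIES = ("Q", "FOP", "BP", "DRP")

_ARGMAX_ATOL = 1e-12


def softmax_select(prefs: Sequence[float], tau: float) -> np.ndarray:
    """Softmax response selection with noise parameter tau >= 0.

    For tau > 0, p_j is proportional to exp(prefs_j / tau).  For tau = 0
    (noise-free selection) the distribution is uniform over the preference
    maximizers; ties within ``1e-12`` of the maximum count as maximal.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    prefs = np.asarray(prefs, dtype=float)
    if tau == 0:
        mask = prefs >= prefs.max() - _ARGMAX_ATOL
        return mask / mask.sum()
    z = prefs / tau
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def q_update(q: np.ndarray, stimulus: int, response: int, feedback: bool, alpha: float) -> np.ndarray:
    """One Q-learning update; returns a new matrix.

    q_ij <- (1 - alpha) q_ij + alpha on positive feedback, and
    q_ij <- (1 - alpha) q_ij - alpha on negative feedback; only the tried
    pair changes.  Fixed points are +1 and -1, so values stay in [-1, 1].
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    out = q.copy()
    target = alpha if feedback else -alpha
    out[stimulus, response] = (1.0 - alpha) * out[stimulus, response] + target
    return out


def bp_transform(row: Sequence[float]) -> np.ndarray:
    """Binarize a probability row: nonzero entries become uniform
    (1 / #nonzero), zeros stay zero."""
    row = np.asarray(row, dtype=float)
    nz = row > 0
    k = int(nz.sum())
    if k == 0:
        raise ValueError("bp_transform requires at least one nonzero entry")
    return nz / k


class Policy(abc.ABC):
    """Common interface: preference row per stimulus + a state update."""

    n: int

    @abc.abstractmethod
    def preferences(self, stimulus: int) -> np.ndarray:
        """Family-specific preference row for ``stimulus`` (length n)."""

    @abc.abstractmethod
    def update(self, stimulus: int, response: int, feedback: bool) -> None:
        """Advance the internal state given one observed trial."""

    def response_probabilities(self, stimulus: int, tau: float) -> np.ndarray:
        return softmax_select(self.preferences(stimulus), tau)


class QPolicy(Policy):
    """Independent per-pair associative weights, all initialized at zero."""

    def __init__(self, alpha: float, n: int = 4):
        if not (0 < alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        self.alpha = alpha
        self.n = n
        self.q = np.zeros((n, n))

    def preferences(self, stimulus: int) -> np.ndarray:
        return self.q[stimulus]

    def update(self, stimulus: int, response: int, feedback: bool) -> None:
        self.q = q_update(self.q, stimulus, response, feedback, self.alpha)


class FopPolicy(Policy):
    """Ideal observer: tracks the consistency set, prefers exact marginals.

    Conditions on every observed trial (deterministic feedback is always
    valid evidence, including trials produced by selection noise).
    """

    def __init__(self, n: int = 4):
        self.n = n
        self.cset = ConsistencySet.full(n)

    def preferences(self, stimulus: int) -> np.ndarray:
        return self.cset.marginals()[stimulus]

    def update(self, stimulus: int, response: int, feedback: bool) -> None:
        self.cset = self.cset.condition(stimulus, response, feedback)


class BpPolicy(FopPolicy):
    """FOP with each preference row flattened to uniform over its support."""

    def preferences(self, stimulus: int) -> np.ndarray:
        return bp_transform(self.cset.marginals()[stimulus])


class DrpPolicy(Policy):
    """Fixed response-order strategy with forced-inference skipping.

    The designated response for a stimulus is the first response in the
    order that is still possible for that stimulus, i.e. has nonzero
    marginal probability under an internal consistency set.  This single
    mechanism yields both behaviors of the strategy: skipping responses
    confirmed for other stimuli, and jumping straight to a response that
    can be inferred indirectly (when all alternatives are ruled out).

    Update rule under selection noise: if the selected response is the
    designated one, the internal set is conditioned on the outcome for both
    feedback signs; if the selection deviated from the designated response,
    only positive feedback updates the internal state and negative feedback
    leaves it unchanged.
    """

    def __init__(self, order: Sequence[int], n: int = 4):
        order = tuple(int(x) for x in order)
        if sorted(order) != list(range(n)):
            raise ValueError(f"order {order!r} is not a permutation of range({n})")
        self.order = order
        self.n = n
        self.cset = ConsistencySet.full(n)

    def designated(self, stimulus: int) -> int:
        counts = self.cset.counts[stimulus]
        for r in self.order:
            if counts[r] > 0:
                return r
        raise RuntimeError("consistency set has an all-zero row")  # pragma: no cover

    def preferences(self, stimulus: int) -> np.ndarray:
        prefs = np.zeros(self.n)
        prefs[self.designated(stimulus)] = 1.0
        return prefs

    def update(self, stimulus: int, response: int, feedback: bool) -> None:
        if response == self.designated(stimulus) or feedback:
            self.cset = self.cset.condition(stimulus, response, feedback)


@dataclass(frozen=True)
class ModelSpec:
    """A fully parameterized model: family, noise tau, and family-specific
    parameters (alpha for Q, response-order string for DRP)."""

    family: str
    tau: float
    alpha: Optional[float] = None
    order: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.family == "Q":
            if self.alpha is None or not (0 < self.alpha <= 1):
                raise ValueError("Q-learning requires alpha in (0, 1]")
        if self.family == "DRP" and self.order is None:
            raise ValueError("DRP requires a response-order string")

    @property
    def label(self) -> str:
        return f"DRP_{self.order}" if self.family == "DRP" else self.family

    def to_dict(self) -> dict:
        return {"family": self.family, "tau": self.tau, "alpha": self.alpha, "order": self.order}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(family=d["family"], tau=d["tau"], alpha=d.get("alpha"), order=d.get("order"))


def parse_order(order: str, labels: Sequence[str] = DEFAULT_CONFIG.response_labels) -> tuple[int, ...]:
    """Parse a response-order string like ``"dfkl"`` against the canonical
    response alphabet into a tuple of response indices."""
    try:
        idx = tuple(labels.index(c) for c in order)
    except ValueError as e:
        raise ValueError(f"order {order!r} contains a label outside {labels}") from e
    if sorted(idx) != list(range(len(labels))):
        raise ValueError(f"order {order!r} is not a permutation of {labels}")
    return idx


def order_string(order: Sequence[int], labels: Sequence[str] = DEFAULT_CONFIG.response_labels) -> str:
    return "".join(labels[i] for i in order)


def make_policy(spec: ModelSpec, config: TaskConfig = DEFAULT_CONFIG) -> Policy:
    """Instantiate the stateful policy for ``spec`` (tau is applied at
    selection time, not stored in the state)."""
    n = config.n_stimuli
    if spec.family == "Q":
        return QPolicy(alpha=spec.alpha, n=n)
    if spec.family == "FOP":
        return FopPolicy(n=n)
    if spec.family == "BP":
        return BpPolicy(n=n)
    return DrpPolicy(order=parse_order(spec.order, config.response_labels), n=n)


def model_step(policy: Policy, spec: ModelSpec, stimulus: int) -> np.ndarray:
    """Response-selection distribution for the current trial: the family's
    preference row passed through the shared softmax at ``spec.tau``."""
    return policy.response_probabilities(stimulus, spec.tau)
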