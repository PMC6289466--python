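"""Hierarchical subject assignment via paired one-sided Wilcoxon
signed-rank tests over per-block log-likelihoods.

Models are compared in order of the specificity of their predictions:
DRP (dfkl, then lkfd) -> FOP -> BP -> Q.  A subject is assigned to the
first model that fits significantly better (p < 0.05) than all of its
competitors at that stage; subjects surviving every stage are labelled
``none``.

The signed-rank test drops zero differences, uses midranks for tied
absolute differences, and computes the exact null distribution of the
positive-rank sum by enumeration (dynamic programming over doubled ranks)
for n <= 25 remaining pairs, falling back to a tie-corrected normal
approximation with continuity correction for larger n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping as TMapping
from typing import Sequence

import numpy as np
from scipy import stats

from .fitting import MODEL_LABELS, FitResult

DEFAULT_ALPHA = 0.05


def _exact_sf(doubled_ranks: np.ndarray, doubled_w: int) -> float:
    """P(W+ >= w) under the signed-rank null, by DP enumeration.

    Ranks are doubled so midranks become integers; counts fit exactly in
    floats for n <= 25 (2^25 < 2^53).
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    doubled_w = max(0, min(doubled_w, total + 1))
    return float(counts[doubled_w:].sum() / counts.sum())


def signed_rank_p(
    x: Sequence[float], y: Sequence[float], alternative: str = "greater"
) -> float:
    """One-sided Wilcoxon signed-rank p-value for paired samples.

    ``alternative="greater"`` tests whether x tends to exceed y.  Zero
    differences are dropped; if all differences are zero the test carries
    no evidence and p = 1.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    d = x - y
    if alternative == "less":
        d = -d
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        r2 = np.round(2 * ranks).astype(int)
        return _exact_sf(r2, int(round(2 * w)))
    # normal approximation with tie correction and continuity correction
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    z = (w - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))


@dataclass
class AssignmentResult:
    """Outcome of the hierarchical procedure for one subject: the assigned
    label and the p-value of every test performed (keyed ``"A>B"``)."""

    subject_id: str
    label: str  # one of MODEL_LABELS or "none"
    p_values: dict[str, float] = field(default_factory=dict)


def assign_subject(
    fits: TMapping[str, FitResult],
    alpha: float = DEFAULT_ALPHA,
    subject_id: str | None = None,
) -> AssignmentResult:
    """Run the four comparison stages on one subject's five fits.

    Stage 1: DRP_dfkl (then DRP_lkfd) must beat all four competitors.
    Stage 2: FOP must beat BP and Q.  Stage 3: BP must beat Q.  Stage 4:
    Q must beat FOP *or* BP (either test suffices).  Otherwise ``none``.
    """
    missing = [lab for lab in MODEL_LABELS if lab not in fits]
    if missing:
        raise ValueError(f"missing fits for {missing}")
    sid = subject_id if subject_id is not None else next(iter(fits.values())).subject_id
    pvals: dict[str, float] = {}

    def p(a: str, b: str) -> float:
        key = f"{a}>{b}"
        if key not in pvals:
            pvals[key] = signed_rank_p(fits[a].block_ll, fits[b].block_ll)
        return pvals[key]

    for cand in ("DRP_dfkl", "DRP_lkfd"):
        others = [lab for lab in MODEL_LABELS if lab != cand]
        if all(p(cand, o) < alpha for o in others):
            return AssignmentResult(sid, cand, pvals)
    if p("FOP", "BP") < alpha and p("FOP", "Q") < alpha:
        return AssignmentResult(sid, "FOP", pvals)
    if p("BP", "Q") < alpha:
        return AssignmentResult(sid, "BP", pvals)
    if p("Q", "FOP") < alpha or p("Q", "BP") < alpha:
        return AssignmentResult(sid, "Q", pvals)
    return AssignmentResult(sid, "none", pvals)


def assign_cohort(
    cohort_fits: TMapping[str, TMapping[str, FitResult]], alpha: float = DEFAULT_ALPHA
) -> list[AssignmentResult]:
    """Assign every subject (keys of ``cohort_fits``) in order."""
    return [assign_subject(fits, alpha, subject_id=sid) for sid, fits in cohort_fits.items()]


def preliminary_ranking(fits: TMapping[str, FitResult], label_order: Sequence[str] | None = None) -> str:
    """Best-ranked model by total log-likelihood (the 27-model preliminary
    comparison); ties break to the first label in ``label_order`` (default:
    iteration order of ``fits``)."""
    labels = list(label_order) if label_order is not None else list(fits)
    best = labels[0]
    for lab in labels[1:]:
        if fits[lab].total_ll > fits[best].total_ll:
            best = lab
    return best
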