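# Methods

`drplearn` analyses trial-by-trial choice behavior in a deterministic-feedback
stimulus-response learning task, using four competing policy families, grid
maximum-likelihood fitting, and a hierarchical nonparametric model-comparison
procedure. This note documents the models, the synthetic-subject generator,
the numerical choices, and the known limitations.

## The task

Each learning block introduces 4 novel stimuli that map one-to-one onto 4
fixed response keys (`d`, `f`, `k`, `l` in keyboard order). Feedback is
deterministic: the response is rewarded iff it is the stimulus's unique
correct response. A block ends when every stimulus has been answered
correctly 8 times, or after 70 trials; a session has 20 blocks, each with a
fresh uniformly random mapping. The minimal block length is therefore 32
trials, and under noise-free structured play block length equals 32 plus the
number of errors. The *initial learning phase* of a block runs from trial 1
up to and including the trial on which the last of the four stimuli is first
answered correctly; the remainder is the *practice phase*.

Because the mapping is a bijection, the 4! = 24 candidate mappings form the
hypothesis space of an ideal observer. A negative outcome for pair (S, R)
falsifies the 6 mappings containing that pair; a positive outcome retains
only those 6 (thereby also blocking R for every other stimulus).

## Policy families

All families share one response-selection rule, a softmax over a
family-specific preference row with noise parameter τ ≥ 0:

    p_j = exp(pref_j / τ) / Σ_k exp(pref_k / τ)

with the τ = 0 limit defined as uniform over the preference maximizers.
The exponent is preference/τ (not preference·τ): only the divided form has
the stated τ = 0 noise-free limit. τ is a temperature: larger values flatten
selection toward uniform.

* **Q-learning** (parameters τ and learning rate α ∈ (0, 1]): one weight
  q_ij per pair, initialized at 0, updated only for the tried pair:
  q ← (1−α)q + α after positive and q ← (1−α)q − α after negative feedback.
  Fixed points are ±1, so implied reward magnitudes are not free
  parameters. Because pairs are updated independently, Q-learning cannot
  exploit the one-to-one structure — it keeps trying responses already
  assigned to other stimuli.
* **Free optimal play (FOP)** (τ only): the ideal observer. The preference
  row for stimulus i is the exact per-response probability of being correct,
  computed by counting over the consistency set (probabilities are rational
  fractions of the member count; no sampling). FOP conditions on every
  observed trial, including noise-driven deviations — under deterministic
  feedback every outcome is valid evidence.
* **Binarized play (BP)** (τ only): FOP with each preference row flattened
  to uniform over its nonzero entries, e.g. (0.6, 0, 0.3, 0.1) → (1/3, 0,
  1/3, 1/3). BP excludes impossible responses but ignores graded evidence.
* **Deterministic response patterns (DRP)** (τ plus a response order, e.g.
  `dfkl`): responses are tested in a fixed order. The designated response
  for a stimulus is the first response in the order that is still possible
  for that stimulus, judged against an internal consistency set. This
  single mechanism produces both behaviors of the strategy — skipping
  responses confirmed for other stimuli, and jumping directly to a response
  whose correctness is only inferable indirectly (three alternatives ruled
  out). The preference row is degenerate (1 on the designated response).
  Update rule under noise: if the selected response was the designated one,
  the internal set is conditioned on the outcome regardless of sign; if the
  selection deviated, only positive feedback updates the state. A deviation
  landing on a falsified response advances nothing (a backward deviation
  needs no update; updating on a forward deviation could skip over possibly
  correct responses and corrupt the pattern).

Noise-free DRP is deterministic given the stimulus sequence and mapping,
makes at most 6 errors per block (3+2+1 in the worst case), and all its
errors are optimal errors in the sense defined below. Note that noise-free
DRP is *not* error-free even when the mapping happens to agree with the
response order: any stimulus presented before its order-predecessors are
assigned still receives the first unassigned response of the order.

## Synthetic cohorts

Since the analyses operate on simulated subjects, the generator is part of
the tested surface. Stimuli are presented in randomized order, implemented
as a uniform draw among the stimuli that still need correct repetitions,
with immediate repeats allowed — the minimal reading of "randomized order",
recorded in the manifest so it can be revisited. Each subject gets an
independent RNG stream spawned from the master seed; cohorts are
bit-reproducible from their `CohortSpec`.

Default conditions: 20 blocks per subject and the task constants above.
The `human_mix_spec` helper reproduces the reported human subsample
composition (36 + 7 DRP, 18 FOP, 19 BP, 5 Q = 85 subjects) with a default
generative noise of τ = 1/4, the middle of the low-noise fitting range (the
human study estimates per-subject noise; a single representative value is
needed for simulation). Recovery cohorts default to τ = 1/6, the smallest
positive grid value, where family signatures are clearest.

What the generator does *not* emulate: response times and deadlines,
omitted responses, within-session fatigue, and the strategy-adaptation
period of the first few blocks (early blocks are drawn from the same
stationary policy). Passing recovery tests therefore shows that the
pipeline identifies stationary generating processes of these four families;
it does not show that human data are stationary.

## Fitting

Each model is fitted per subject by exhaustive grid search maximizing the
summed log-likelihood (natural log) over the initial learning phases of
blocks 6–20, with the model state evolved along the subject's observed
responses and feedback. Grids: τ ∈ {0} ∪ {1/6.0, 1/5.8, …, 1/0.2} (31
values); α ∈ {0.05, 0.10, …, 1.00} (20 values, Q only). One parameter
vector is fitted jointly across the 15 blocks, and per-block log-likelihoods
at the optimum feed the paired tests — the pairing requires a single
parameter estimate per subject and model.

Numerical choices:

* The phase-ending trial is included in the likelihood window (the phase
  "ends at" that trial; the closed reading). Blocks whose 70-trial cap was
  hit with an unsolved stimulus use all 70 trials.
* τ = 0 stays in the grid; a mispredicted trial there contributes −∞, a
  valid ordering value that loses the argmax unless prediction is perfect
  (noise-free DRP data fitted by its own model attains exactly 0).
* Ties in the grid search break to the first point in enumeration order
  (τ ascending; for Q, τ-major over α). Argmax ties at τ = 0 are resolved
  uniformly over all maximizers, for every family, with a 1e-12 tolerance
  for floating-point ties.
* Likelihood evaluation is vectorized: the preference trace along a block
  is computed once per (family, α, order) — τ only scales selection — and
  the log-softmax is evaluated for the whole τ grid at once.

Recovery behavior (measured by the test suite): the grid estimator is
unbiased at cohort level — for 20 synthetic Q-learners (α = 0.5, τ = 1/4)
the median recovered α is 0.50 and the median recovered τ is within 1–2
grid steps of the truth — but individual estimates scatter (α and τ trade
off in the softmax likelihood on ~280 initial-phase trials per subject).
Recovery is therefore quantified by the median estimate across subjects.

## Model comparison

Subjects are assigned by pairwise one-sided Wilcoxon signed-rank tests over
the 15 per-block log-likelihoods, at p < 0.05, in an order matching the
specificity of the models' predictions:

1. DRP `dfkl` (then `lkfd`) must beat all four competitors;
2. FOP must beat BP and Q;
3. BP must beat Q;
4. Q must beat FOP *or* BP (either suffices);
5. otherwise the subject is labelled `none`.

The model space is restricted to these five models; the 27-model ranking
(all 24 orders + FOP + BP + Q, argmax of total log-likelihood with a fixed
tie-break order) is available as a preliminary report, and illustrates the
selection bias of pure argmax ranking over many similar models.

Signed-rank details (the variant is not uniquely determined by convention,
so it is frozen here): zero differences are dropped; tied absolute
differences get midranks; the null distribution of the positive-rank sum is
enumerated exactly (dynamic programming over doubled ranks) for n ≤ 25
remaining pairs, beyond which a tie-corrected normal approximation with
continuity correction is used. No multiple-testing correction is applied
within a subject; the threshold is per test.

A known property of the procedure, reproduced by the recovery analyses:
FOP-generated subjects are recovered only about half the time (the rest
fall through to BP), because FOP and BP differ on just a few
graded-probability trials per initial phase, so the FOP-vs-BP signed-rank
test across 15 blocks has limited power even at τ = 1/6. DRP and BP
subjects are recovered essentially always; Q subjects are labelled Q (the
Q stage can fire on Q-generated data even though it never fired on the
human sample).

## Error analysis

Every negative-feedback trial is classified against noise-free FOP
probabilities recomputed from the observed history prefix — not against the
behaving model's internal state — so the same classifier applies to any
data source. Six mutually exclusive labels partition the errors: `optimal`
(chosen response had maximal probability), `suboptimal` (nonzero but not
maximal), and four zero-probability categories distinguished by how the
impossibility was knowable: `repeatedly_wrong`, `correct_for_different_
stimulus`, `both_rw_and_cfds`, and `neither_rw_nor_cfds` (only an indirect
inference revealed the correct response). The overlapping seventh label
`after_first_correct` marks errors on a stimulus already answered
correctly. Probability comparisons use integer member counts of the
consistency set, so "maximal" and "zero" are exact.

Learning curves report the per-trial-index probability of a correct
response with SEM across contributing blocks, pooled over subjects; the
initial-phase alignment drops each block at the end of its phase (so n
shrinks with the trial index) and truncates at trial 17 by default, with
flags for 32-trial and full-block views. Generative checks replay each real
block from a fitted model (same mapping, resampled stimulus sequences;
default 1000 repetitions).

Two structural facts, verified empirically by the test suite rather than
proved: the multiset of per-block optimal-error counts produced by the 24
noise-free DRP orders is invariant across stimulus sequences (a symmetric
distribution 1,3,5,6,5,3,1 over 0–6 errors), and noise-free FOP's
optimal-error distribution converges to the same law; and the across-subject
variance of optimal-error counts is strictly larger for DRP cohorts than
FOP cohorts, because DRP's error count depends on the stimulus sequence
while FOP's does not. "Same stimulus sequence" across the 24 orders is
realized by reusing one sequencing RNG seed, since the adaptive sequencing
rule makes a literal shared sequence ill-defined once responses diverge.

## Problem sizes

The test suite uses 100 random histories × ≥10^5 Monte-Carlo samples for
the rejection-sampling oracle, 20 sequences × 24 orders plus 10^4 replays
for the sequence-invariance check, and 20 synthetic subjects per family for
parameter and model recovery — sizes at which every stochastic assertion is
far from its tolerance except where noted above.

## Limitations

* Group-level (random-effects) model selection is out of scope; assignment
  is per subject.
* The optimality of FOP and of the DRP schemes is exercised empirically
  (error signatures, likelihood dominance), not proved formally.
* Omissions, response times, and non-stationary strategy mixtures are not
  modelled; fits on data containing them will load on the noise parameter.
* The signed-rank variant and the inclusion of the phase-ending trial in
  the likelihood window are defensible choices among near-neighbours;
  both are isolated behind single functions (`signed_rank_p`,
  `likelihood_window`) for sensitivity analyses.
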