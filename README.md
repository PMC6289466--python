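# drplearn

Trial-by-trial computational modelling of a deterministic-feedback
stimulus-response learning task: four competing policy families, synthetic
cohorts, maximum-likelihood fitting, hierarchical model comparison, and
error/learning-curve analyses.

## The problem

In each block of the task, a learner faces 4 novel stimuli that map
one-to-one onto 4 fixed response keys (`d f k l`). Feedback is
deterministic, and a block ends when every stimulus has been answered
correctly 8 times (or after 70 trials). Because the mapping is a bijection,
outcomes carry information *across* stimulus-response pairs: once `d` is
confirmed for one stimulus it is impossible for the others, and ruling out
three responses for a stimulus reveals the fourth. How much of that hidden
structure a learner exploits — and by what algorithm — is the question this
package is built to answer.

Four model families, sharing one softmax selection rule
p_ij = exp(pref_ij/τ) / Σ_k exp(pref_ik/τ) (τ = 0: uniform over the
maximizers), formalize competing hypotheses:

* **Q-learning** — independent associative weights per pair,
  q ← (1−α)q ± α; blind to the one-to-one structure.
* **FOP** (free optimal play) — the ideal observer: tracks the 24 candidate
  mappings consistent with the history and prefers the responses most
  likely to be correct.
* **BP** (binarized play) — FOP with each probability row flattened to
  uniform over its nonzero entries: excludes impossible responses, ignores
  graded evidence.
* **DRP** (deterministic response patterns) — tests responses in a fixed
  order (e.g. `dfkl`), skipping responses assigned to other stimuli and
  exploiting forced inferences; theoretically optimal at a fraction of the
  memory cost of FOP.

Subjects (here: synthetic subjects with known ground truth) are fitted per
model by exhaustive grid search over τ (31 values) and α (20 values, Q
only) on the initial learning phases of blocks 6–20, and assigned to a
model family by one-sided Wilcoxon signed-rank tests over the 15 per-block
log-likelihoods, in the order DRP → FOP → BP → Q at p < 0.05.

See `docs/methods.md` for the full model definitions, numerical choices
and limitations.

## Worked example

Run the whole pipeline on a small ground-truth cohort (3 subjects per
generating family at τ = 1/6):

```sh
drplearn run --seed 11 --out out/ --families "DRP_dfkl:3,FOP:3,BP:3,Q:3" --tau 0.1667
```

or equivalently from Python:

```python
import drplearn as dl

cohort = dl.recovery_cohort_spec(seed=11, n_per_family=3, tau=1/6)
summary = dl.run_pipeline(dl.PipelineConfig(cohort=cohort, out_dir="out"))
```

which prints (and writes to `out/summary.json`):

```json
{
  "alpha": 0.05,
  "label_counts": {"BP": 5, "DRP_dfkl": 3, "FOP": 1, "Q": 3},
  "n_subjects": 12,
  "recovery_matrix": {
    "BP": {"BP": 3},
    "DRP_dfkl": {"DRP_dfkl": 3},
    "FOP": {"BP": 2, "FOP": 1},
    "Q": {"Q": 3}
  },
  "seed": 11
}
```

Reading the output: all three DRP subjects, all three BP subjects and all
three Q-learners are assigned to their generating family. Two of the three
FOP subjects fall through to BP — the characteristic weakness of the
procedure, since FOP and BP differ only on a handful of graded-probability
trials per block and the FOP stage demands significance against both BP and
Q. `out/` also contains the trial log (`trials.csv`), the ground-truth
mappings and manifest, per-model fits (`fits.csv`), per-test p-values
(`assignments.csv`), the learning curve (`curves.csv`) and the per-subject
error taxonomy (`errors.csv`).

Stages are independently scriptable: `drplearn simulate`, `fit`, `compare`,
`analyze` consume and produce the same files.

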