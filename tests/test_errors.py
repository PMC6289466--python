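"""Error taxonomy, learning curves, generative checks."""

import numpy as np
import pytest

import drplearn as dl
from drplearn.errors import ErrorCategory, PRIMARY_CATEGORIES, block_error_counts
from drplearn.task import Block

from conftest import make_trials


class TestClassifyError:
    def test_first_trial_error_is_optimal(self):
        # every response is maximal (p = 0.25) on a fresh block
        trials = make_trials([(0, 0, 0)])
        cats = dl.classify_error(trials[0], [])
        assert cats == {ErrorCategory.OPTIMAL}

    def test_second_trial_nonmaximal_response_is_suboptimal(self):
        # after S1->d fails, d is the most likely response for S2; choosing
        # l instead is an error with nonzero but not maximal probability
        trials = make_trials([(0, 0, 0), (1, 3, 0)])
        cats = dl.classify_error(trials[1], trials[:1])
        assert cats == {ErrorCategory.SUBOPTIMAL}

    def test_reusing_confirmed_response_is_cfds(self):
        trials = make_trials([(1, 0, 1), (2, 0, 0)])
        cats = dl.classify_error(trials[1], trials[:1])
        assert cats == {ErrorCategory.CORRECT_FOR_DIFFERENT_STIMULUS}

    def test_repeatedly_wrong(self):
        trials = make_trials([(0, 1, 0), (0, 1, 0)])
        cats = dl.classify_error(trials[1], trials[:1])
        assert cats == {ErrorCategory.REPEATEDLY_WRONG}

    def test_both_rw_and_cfds(self):
        trials = make_trials([(1, 0, 1), (2, 0, 0), (2, 0, 0)])
        cats = dl.classify_error(trials[2], trials[:2])
        assert cats == {ErrorCategory.BOTH_RW_AND_CFDS}

    def test_neither_category_requires_indirect_inference(self):
        # d, f confirmed for S1, S2 and k falsified for S3 force S3 -> l,
        # hence S4 -> k; choosing l for S4 is a zero-probability error that
        # is neither repeatedly wrong nor a reused confirmed response --
        # only the indirect inference reveals it
        trials = make_trials([(0, 0, 1), (1, 1, 1), (2, 2, 0)])
        err = make_trials([(3, 3, 0)])[0]
        cats = dl.classify_error(err, trials)
        assert cats == {ErrorCategory.NEITHER_RW_NOR_CFDS}

    def test_after_first_correct_overlays_primary_label(self):
        trials = make_trials([(0, 0, 1), (0, 1, 0)])
        cats = dl.classify_error(trials[1], trials[:1])
        assert ErrorCategory.AFTER_FIRST_CORRECT in cats
        assert len(cats & set(PRIMARY_CATEGORIES)) == 1

    def test_positive_trial_rejected(self):
        trials = make_trials([(0, 0, 1)])
        with pytest.raises(ValueError):
            dl.classify_error(trials[0], [])


class TestErrorProfiles:
    def test_primary_categories_partition_errors(self, rng):
        # each error carries exactly one primary label: per-block counts
        # over primary categories sum to the total error count
        for fam, kwargs in [("Q", {"alpha": 0.5}), ("BP", {}), ("DRP", {"order": "dfkl"})]:
            spec = dl.ModelSpec(fam, 0.4, **kwargs)
            mapping = tuple(int(x) for x in rng.permutation(4))
            block = dl.generate_block(spec, mapping, rng=rng)
            counts = block_error_counts(block, initial_phase_only=False)
            total = sum(1 for t in block.trials if not t.feedback)
            assert sum(counts[c] for c in PRIMARY_CATEGORIES) == total

    def test_noise_free_fop_makes_only_optimal_errors(self, rng):
        spec = dl.ModelSpec("FOP", 0.0)
        for _ in range(10):
            mapping = tuple(int(x) for x in rng.permutation(4))
            block = dl.generate_block(spec, mapping, rng=rng)
            counts = block_error_counts(block, initial_phase_only=False)
            total = sum(1 for t in block.trials if not t.feedback)
            assert counts[ErrorCategory.OPTIMAL] == total
            for cat in PRIMARY_CATEGORIES[1:]:
                assert counts[cat] == 0

    def test_drp_optimal_error_variance_exceeds_fop(self):
        # the number of optimal errors under DRP depends on the stimulus
        # sequence; under ideal-observer play it does not
        n = 12
        drp_spec = dl.CohortSpec(
            groups=(dl.CohortGroup(dl.ModelSpec("DRP", 0.0, order="dfkl"), n),), seed=21
        )
        fop_spec = dl.CohortSpec(
            groups=(dl.CohortGroup(dl.ModelSpec("FOP", 0.0), n),), seed=21
        )
        var = {}
        for name, spec in [("DRP", drp_spec), ("FOP", fop_spec)]:
            datasets, _ = dl.generate_cohort(spec)
            profile = dl.cohort_error_profile(datasets)
            var[name] = profile["optimal"].var()
        assert var["DRP"] > var["FOP"]


class TestLearningCurves:
    def test_first_trial_accuracy_is_chance(self):
        # exact argument: whatever response a policy picks first, it is
        # correct for 6 of the 24 equally likely mappings
        spec = dl.CohortSpec(
            groups=(dl.CohortGroup(dl.ModelSpec("DRP", 0.0, order="dfkl"), 10),), seed=2
        )
        datasets, _ = dl.generate_cohort(spec)
        curves = dl.learning_curves(datasets, block_ids=range(1, 21))
        first = curves[curves.trial == 1].iloc[0]
        assert first["n"] == 200
        assert abs(first["mean"] - 0.25) < 3 * first["sem"] + 0.02

    def test_high_noise_curve_is_flat_at_chance(self):
        spec = dl.CohortSpec(
            groups=(dl.CohortGroup(dl.ModelSpec("FOP", 50.0), 8),), seed=8
        )
        datasets, _ = dl.generate_cohort(spec)
        curves = dl.learning_curves(datasets, alignment="full_block", truncate_at=32)
        # pooled accuracy at chance, and no trial deviates beyond noise
        pooled = np.average(curves["mean"], weights=curves["n"])
        assert abs(pooled - 0.25) < 0.02
        assert np.all(np.abs(curves["mean"] - 0.25) < 5 * curves["sem"])

    def test_contributing_blocks_shrink_with_trial_index(self, tiny_cohort):
        datasets, _ = tiny_cohort
        curves = dl.learning_curves(datasets)
        assert np.all(np.diff(curves["n"]) <= 0)

    def test_q_learning_asymptote_below_one(self):
        # with tau=1/4 the softmax of saturated weights caps accuracy at
        # exp(4)/(exp(4)+exp(-4)+2) ~ 0.964
        spec = dl.CohortSpec(
            groups=(dl.CohortGroup(dl.ModelSpec("Q", 0.25, alpha=0.5), 6),), seed=13
        )
        datasets, _ = dl.generate_cohort(spec)
        curves = dl.learning_curves(datasets, alignment="full_block", truncate_at=None)
        late = curves[curves.trial > 30]["mean"]
        cap = np.exp(4) / (np.exp(4) + np.exp(-4) + 2)
        assert 0.7 < late.mean() < cap + 0.02


class TestGenerativeReplay:
    def test_reproducible_with_fixed_seed(self, tiny_cohort):
        datasets, _ = tiny_cohort
        spec = dl.ModelSpec("FOP", 0.3)
        r1 = dl.generative_replay(spec, datasets[0], n_reps=2, rng=np.random.default_rng(4))
        r2 = dl.generative_replay(spec, datasets[0], n_reps=2, rng=np.random.default_rng(4))
        for a, b in zip(r1, r2):
            for ba, bb in zip(a.blocks, b.blocks):
                assert ba.trials == bb.trials

    def test_replay_preserves_mappings(self, tiny_cohort):
        datasets, _ = tiny_cohort
        reps = dl.generative_replay(
            dl.ModelSpec("BP", 0.2), datasets[0], n_reps=1, rng=np.random.default_rng(0)
        )
        for rep_block, b in zip(reps[0].blocks, range(6, 21)):
            assert rep_block.mapping == datasets[0].block(b).mapping

    def test_noise_free_drp_replay_reproduces_its_own_curve(self, rng):
        spec = dl.ModelSpec("DRP", 0.0, order="dfkl")
        ds = dl.generate_subject("d0", spec, np.random.default_rng(6))
        reps = dl.generative_replay(spec, ds, n_reps=3, rng=rng)
        # responses are a deterministic function of stimulus sequence and
        # mapping, so per-trial-1 accuracy matches exactly across reps
        for rep in reps:
            for b in range(6, 21):
                real, sim = ds.block(b), rep.block(b)
                # first trial response is the fixed first-order response
                assert sim.trials[0].response == real.trials[0].response == 0


class TestOptimalErrorInvariance:
    def test_report_is_deterministic(self):
        r1 = dl.optimal_error_invariance_check(n_sequences=3, n_fop_reps=300, seed=5)
        r2 = dl.optimal_error_invariance_check(n_sequences=3, n_fop_reps=300, seed=5)
        assert r1 == r2

    def test_multiset_invariant_on_small_run(self):
        rep = dl.optimal_error_invariance_check(n_sequences=4, n_fop_reps=500, seed=9)
        assert rep["identical"]
        # the 24-order distribution is symmetric around 3 errors
        pmf = rep["drp_pmf"]
        assert set(pmf) == set(range(7))
        for k in range(7):
            assert pmf[k] == pytest.approx(pmf[6 - k])
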