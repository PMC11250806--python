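"""CV protocol, ROC AUC oracle, leakage audit, hold-out mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methbench import (EvalProtocol, ModelSpec, SelectorSpec,
                       SimulationConfig, evaluate_biased, evaluate_holdout,
                       evaluate_unbiased, generate_study, make_cv_splits,
                       merge_batches, roc_auc, select_dm_top)
from .conftest import make_dataset


def _auc_bruteforce(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_inverted_ordering(self):
        assert roc_auc([0.9, 0.8, 0.1], [0, 0, 1]) == 0.0

    @settings(deadline=None, max_examples=200)
    @given(st.integers(2, 50), st.integers(0, 10_000))
    def test_matches_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)  # force ties
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.2, 0.4], [1, 1])


class TestCvSplits:
    def _ds(self, rng, n=300):
        return make_dataset(rng.normal(size=(n, 10)),
                            status=["case", "control"] * (n // 2))

    def test_partition_sizes(self, rng):
        ds = self._ds(rng)
        protocol = EvalProtocol(n_repeats=10, n_folds=3, seed=0)
        splits = make_cv_splits(ds, protocol)
        assert len(splits) == 30
        for rep in range(10):
            vals = [set(splits[rep * 3 + f][1]) for f in range(3)]
            assert sorted(len(v) for v in vals) == [100, 100, 100]
            assert set().union(*vals) == set(ds.sample_ids)

    def test_stratification_keeps_both_classes(self, rng):
        ds = self._ds(rng, n=60)
        for train_ids, val_ids in make_cv_splits(ds, EvalProtocol(seed=3)):
            for ids in (train_ids, val_ids):
                status = ds.samples.loc[ids, "status"]
                assert {"case", "control"} <= set(status)

    def test_seeded_determinism(self, rng):
        ds = self._ds(rng, n=90)
        a = make_cv_splits(ds, EvalProtocol(seed=5))
        b = make_cv_splits(ds, EvalProtocol(seed=5))
        assert a == b

    def test_disjoint_protocol_sets_enforced(self):
        with pytest.raises(ValueError):
            EvalProtocol(cv_batches=frozenset({"a"}),
                         holdout_batches=frozenset({"a"}))


@pytest.fixture(scope="module")
def small_signal_study():
    cfg = SimulationConfig(
        n_batches=2, samples_per_batch=[80, 80],
        case_fraction_per_batch=[0.5, 0.5], n_probes=200,
        n_signal_probes=20, effect_size_m=2.0, noise_sd=0.3,
        batch_mean_shift_sd=0.0, batch_var_scale_range=(1, 1), seed=31)
    datasets, truth = generate_study(cfg)
    return merge_batches(datasets), datasets, truth


class TestEvaluateUnbiased:
    def test_strong_signal_high_auc(self, small_signal_study):
        ds, _, _ = small_signal_study
        res = evaluate_unbiased(ds, ModelSpec("logreg_l2"),
                                SelectorSpec("dm_top", k=20),
                                EvalProtocol(n_repeats=2, n_folds=3, seed=1))
        assert len(res.folds) == 6
        assert res.mean_auc > 0.9

    def test_fold_bookkeeping(self, small_signal_study):
        ds, _, _ = small_signal_study
        res = evaluate_unbiased(ds, ModelSpec("decision_tree"),
                                SelectorSpec("anova_f", k=10),
                                EvalProtocol(n_repeats=1, n_folds=3, seed=2))
        assert set(res.folds.columns) == {"auc", "accuracy", "sensitivity",
                                          "specificity"}
        assert len(res.folds) == 3
        assert not res.biased

    def test_leakage_audit_catches_full_data_selector(self, small_signal_study):
        ds, _, _ = small_signal_study

        class LeakySelector(SelectorSpec):
            def apply(self, train_ds):
                return select_dm_top(ds, k=10)  # fitted on ALL samples

        with pytest.raises(RuntimeError, match="leakage"):
            evaluate_unbiased(ds, ModelSpec("logreg_l2"),
                              LeakySelector("dm_top"),
                              EvalProtocol(n_repeats=1, n_folds=3, seed=0))


class TestEvaluateBiased:
    def test_biased_tag_and_equivalence_structure(self, small_signal_study):
        ds, _, _ = small_signal_study
        panel = select_dm_top(ds, k=20)
        res = evaluate_biased(ds, ModelSpec("logreg_l2"), panel,
                              EvalProtocol(n_repeats=1, n_folds=3, seed=4))
        assert res.biased
        assert len(res.folds) == 3

    def test_panel_probes_must_exist(self, small_signal_study):
        ds, _, _ = small_signal_study
        panel = select_dm_top(ds, k=5)
        panel.probe_ids[0] = "cg_not_there"
        with pytest.raises(ValueError, match="absent"):
            evaluate_biased(ds, ModelSpec("logreg_l2"), panel,
                            EvalProtocol(seed=0))


class TestEvaluateHoldout:
    def test_batch_disjointness_enforced(self, small_signal_study):
        _, datasets, _ = small_signal_study
        with pytest.raises(ValueError, match="overlap"):
            evaluate_holdout(datasets[0], datasets[0],
                             ModelSpec("logreg_l2"),
                             SelectorSpec("dm_top", k=10))

    def test_holdout_consistent_with_cv_on_same_distribution(self, small_signal_study):
        ds, datasets, _ = small_signal_study
        cv = evaluate_unbiased(ds, ModelSpec("logreg_l2"),
                               SelectorSpec("dm_top", k=20),
                               EvalProtocol(n_repeats=2, n_folds=3, seed=1))
        hold = evaluate_holdout(datasets[0], datasets[1],
                                ModelSpec("logreg_l2"),
                                SelectorSpec("dm_top", k=20),
                                n_training_repeats=1)
        assert abs(hold.mean_auc - cv.mean_auc) < 0.05

    def test_reports_one_row_per_training_repeat(self, small_signal_study):
        _, datasets, _ = small_signal_study
        res = evaluate_holdout(datasets[0], datasets[1],
                               ModelSpec("random_forest"),
                               SelectorSpec("anova_f", k=10),
                               n_training_repeats=3)
        assert len(res.folds) == 3
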