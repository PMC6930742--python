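"""Fold plans, grid search, SFFS wrapper and the nested procedure."""

from dataclasses import replace

import numpy as np
import pytest
from sklearn.svm import SVC

from tinnisel.cohort import generate_cohort
from tinnisel.fscore import compute_fscore
from tinnisel.selection import (
    ClassifierConfig,
    grid_search_svm,
    make_fold_plan,
    pooled_scored_subjects,
    run_nested_selection,
    sffs_select,
    train_final_classifier,
)
from tinnisel.svm_backend import HAVE_FAST_BACKEND, fit_decision


def two_class_data(rng, n_pos, n_neg, n_features, separation=0.0):
    """Gaussian classes shifted along feature 0 by ``separation`` SDs."""
    x = rng.normal(size=(n_pos + n_neg, n_features))
    y = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    x[: n_pos, 0] += separation
    return x, y


class TestFoldPlan:
    @pytest.mark.parametrize("seed", range(10))
    def test_reference_cohort_sizes_for_every_seed(self, seed):
        plan = make_fold_plan(46, 56, 5, seed)
        assert [len(f) for f in plan.patient_folds] == [10, 9, 9, 9, 9]
        assert [len(f) for f in plan.control_folds] == [12, 11, 11, 11, 11]
        assert plan.fold_sizes == [22, 20, 20, 20, 20]

    def test_even_split(self):
        plan = make_fold_plan(10, 10, 5, seed=3)
        assert plan.fold_sizes == [4, 4, 4, 4, 4]

    def test_deterministic_in_seed(self):
        assert make_fold_plan(20, 25, 5, 9) == make_fold_plan(20, 25, 5, 9)
        assert make_fold_plan(20, 25, 5, 9) != make_fold_plan(20, 25, 5, 10)

    def test_test_rows_partition_all_subjects(self):
        plan = make_fold_plan(9, 13, 4, seed=0)
        labels = np.r_[np.ones(9, int), np.zeros(13, int)]
        rows = np.concatenate(plan.test_rows(labels))
        assert sorted(rows.tolist()) == list(range(22))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match=">= k"):
            make_fold_plan(3, 56, 5, 0)


class TestFastBackend:
    def test_fast_path_available(self):
        assert HAVE_FAST_BACKEND

    def test_matches_public_svc_decisions_and_predictions(self, rng):
        for _ in range(30):
            n_tr = int(rng.integers(12, 60))
            n_te = int(rng.integers(3, 15))
            d = int(rng.integers(1, 5))
            x = rng.normal(size=(n_tr + n_te, d))
            y = (rng.random(n_tr + n_te) < 0.5).astype(float)
            if len(np.unique(y[:n_tr])) < 2:
                continue
            gamma = float(2.0 ** rng.integers(-5, 6))
            c = float(2.0 ** rng.integers(-5, 6))
            dist = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
            kernel = np.exp(-gamma * dist)
            k_tr = np.ascontiguousarray(kernel[:n_tr, :n_tr])
            k_te = np.ascontiguousarray(kernel[n_tr:, :n_tr])
            y_tr = np.ascontiguousarray(y[:n_tr])
            dec = fit_decision(k_tr, y_tr, k_te, c, fast=True)
            svc = SVC(kernel="precomputed", C=c).fit(k_tr, y_tr)
            np.testing.assert_allclose(
                dec, svc.decision_function(k_te), atol=1e-9
            )
            np.testing.assert_array_equal(
                (dec > 0).astype(float), svc.predict(k_te)
            )


class TestGridSearch:
    def test_evaluates_all_121_pairs(self, rng):
        x, y = two_class_data(rng, 15, 15, 3, separation=1.0)
        plan = make_fold_plan(15, 15, 5, 0)
        res = grid_search_svm(x, y, [0, 1], ClassifierConfig(), plan)
        assert res.n_pairs_evaluated == 121
        assert res.accuracy_grid.shape == (11, 11)

    def test_separable_classes_reach_perfect_inner_accuracy(self, rng):
        x, y = two_class_data(rng, 15, 15, 1, separation=6.0)
        plan = make_fold_plan(15, 15, 5, 0)
        res = grid_search_svm(x, y, [0], ClassifierConfig(), plan)
        assert res.accuracy == 1.0

    def test_grid_point_from_published_model_is_reachable(self):
        config = ClassifierConfig()
        assert 2.0 in config.c_grid and 8.0 in config.gamma_grid

    def test_permuted_labels_stay_near_majority_rate(self, rng):
        accs = []
        for _ in range(20):
            x = rng.normal(size=(30, 2))
            y = rng.permutation(np.r_[np.ones(13, int), np.zeros(17, int)])
            plan = make_fold_plan(13, 17, 5, 1)
            res = grid_search_svm(x, y, [0, 1], ClassifierConfig(), plan)
            accs.append(res.accuracy)
        # max-over-grid is upward biased; mean should stay within a few
        # points of the 17/30 majority rate
        assert abs(np.mean(accs) - 17 / 30) < 0.1

    def test_empty_feature_set_rejected(self, rng):
        x, y = two_class_data(rng, 10, 10, 2)
        plan = make_fold_plan(10, 10, 5, 0)
        with pytest.raises(ValueError, match="non-empty"):
            grid_search_svm(x, y, [], ClassifierConfig(), plan)


class TestSffs:
    def test_perfect_feature_accepted_noise_rejected(self, rng):
        x, y = two_class_data(rng, 15, 15, 6, separation=8.0)
        ranking = compute_fscore(x, y).ranking
        assert ranking[0] == 0
        plan = make_fold_plan(15, 15, 5, 2)
        state = sffs_select(x, y, ranking, ClassifierConfig(), plan)
        assert state.features == [0]
        assert state.accuracy == 1.0
        # every later candidate was rejected: accuracy cannot exceed 1
        assert all(
            not t.accepted for t in state.trace if t.feature != 0
        )

    def test_trace_covers_every_feature_once(self, rng):
        x, y = two_class_data(rng, 12, 12, 5, separation=1.0)
        plan = make_fold_plan(12, 12, 5, 0)
        state = sffs_select(
            x, y, compute_fscore(x, y).ranking, ClassifierConfig(), plan
        )
        added = [t.feature for t in state.trace if t.action == "add"]
        assert sorted(added) == list(range(5))

    def test_accepted_accuracies_strictly_increase(self, rng):
        x, y = two_class_data(rng, 14, 14, 8, separation=1.5)
        plan = make_fold_plan(14, 14, 5, 1)
        state = sffs_select(
            x, y, compute_fscore(x, y).ranking, ClassifierConfig(), plan
        )
        accepted = [
            t.accuracy_after for t in state.trace if t.accepted
        ]
        assert all(b > a for a, b in zip(accepted, accepted[1:]))
        assert (not accepted) or accepted[0] > state.baseline_accuracy

    def test_rejected_candidates_leave_set_unchanged(self, rng):
        x, y = two_class_data(rng, 12, 12, 6, separation=2.0)
        plan = make_fold_plan(12, 12, 5, 3)
        state = sffs_select(
            x, y, compute_fscore(x, y).ranking, ClassifierConfig(), plan
        )
        running = []
        for t in state.trace:
            if t.accepted and t.action == "add":
                running.append(t.feature)
        assert running == state.features

    def test_pure_noise_selects_small_sets(self, rng):
        sizes, finals = [], []
        for i in range(10):
            x = rng.normal(size=(24, 8))
            y = rng.permutation(np.r_[np.ones(11, int), np.zeros(13, int)])
            plan = make_fold_plan(11, 13, 5, i)
            state = sffs_select(
                x, y, compute_fscore(x, y).ranking, ClassifierConfig(), plan
            )
            sizes.append(len(state.features))
            finals.append(state.accuracy)
        # no real structure: few features survive the strict-improvement
        # rule, and the (upward-biased) inner-CV maximum stays well short
        # of separability
        assert np.mean(sizes) <= 4
        assert np.mean(finals) < 0.9

    def test_deterministic(self, rng):
        x, y = two_class_data(rng, 12, 12, 5, separation=1.0)
        plan = make_fold_plan(12, 12, 5, 4)
        ranking = compute_fscore(x, y).ranking
        s1 = sffs_select(x, y, ranking, ClassifierConfig(), plan)
        s2 = sffs_select(x, y, ranking, ClassifierConfig(), plan)
        assert s1.features == s2.features
        assert s1.trace == s2.trace

    def test_floating_mode_can_remove_earlier_features(self, rng):
        x, y = two_class_data(rng, 14, 14, 6, separation=1.2)
        plan = make_fold_plan(14, 14, 5, 5)
        ranking = compute_fscore(x, y).ranking
        state = sffs_select(
            x, y, ranking, ClassifierConfig(), plan, floating=True
        )
        # removals recorded in the trace; selected set stays unique/valid
        assert len(set(state.features)) == len(state.features)
        assert all(t.action in ("add", "remove") for t in state.trace)


class TestFinalClassifier:
    def test_separable_training_data_fits_perfectly(self, rng):
        x, y = two_class_data(rng, 10, 10, 2, separation=8.0)
        clf = train_final_classifier(x, y, [0, 1], c=2.0, gamma=8.0)
        assert (clf.predict(x) == y).all()

    def test_scores_sign_consistent_with_predictions(self, rng):
        x, y = two_class_data(rng, 12, 12, 3, separation=1.0)
        clf = train_final_classifier(x, y, [0, 1, 2], c=1.0, gamma=0.5)
        scores = clf.decision_scores(x)
        np.testing.assert_array_equal(
            clf.predict(x), (scores > 0).astype(int)
        )

    def test_accepts_feature_table_with_region_names(self):
        from conftest import small_signal_regions
        from tinnisel.cohort import CohortConfig

        table = generate_cohort(
            CohortConfig(
                n_patients=8,
                n_controls=8,
                signal_regions=small_signal_regions(2, delta=80.0),
                n_null_regions=1,
                effect_scale=2.0,
                thi_model=None,
                seed=0,
            )
        )
        clf = train_final_classifier(
            table, feature_idx=["sig_0", "sig_1"], c=2.0, gamma=1.0
        )
        assert len(clf.decision_scores(table.volumes)) == 16

    def test_degenerate_constant_feature_rejected(self, rng):
        x, y = two_class_data(rng, 8, 8, 2)
        x[:, 1] = 42.0
        with pytest.raises(ValueError, match="constant feature"):
            train_final_classifier(x, y, [0, 1], c=1.0, gamma=1.0)


class TestNestedSelection:
    def small_table(self, seed=11, effect=2.5):
        from conftest import small_signal_regions
        from tinnisel.cohort import CohortConfig

        config = CohortConfig(
            n_patients=15,
            n_controls=15,
            signal_regions=small_signal_regions(2, delta=50.0),
            n_null_regions=4,
            effect_scale=effect,
            thi_model=None,
            seed=seed,
        )
        return generate_cohort(config)

    def test_deterministic_given_plan(self):
        table = self.small_table()
        plan = make_fold_plan(15, 15, 5, 21)
        r1 = run_nested_selection(table, ClassifierConfig(), plan)
        r2 = run_nested_selection(table, ClassifierConfig(), plan)
        assert r1.to_dict() == r2.to_dict()

    def test_every_subject_scored_once_out_of_fold(self):
        table = self.small_table()
        plan = make_fold_plan(15, 15, 5, 8)
        res = run_nested_selection(table, ClassifierConfig(), plan)
        scored = pooled_scored_subjects(table, res)
        assert len(scored.subject_ids) == 30
        assert len(np.unique(scored.subject_ids)) == 30

    def test_no_leakage_from_outer_test_rows(self):
        """Perturbing a fold's held-out subjects must not change its
        ranking, SFFS trace, or selected set."""
        table = self.small_table()
        plan = make_fold_plan(15, 15, 5, 13)
        base = run_nested_selection(table, ClassifierConfig(), plan)
        fold0_rows = base.folds[0].test_rows
        df = table.data.copy()
        cols = table.region_names
        df.loc[df.index[fold0_rows], cols] = (
            df.loc[df.index[fold0_rows], cols].to_numpy() * 3.0 + 17.0
        )
        from tinnisel.tables import FeatureTable

        perturbed = FeatureTable(df, list(cols), table.provenance)
        mod = run_nested_selection(perturbed, ClassifierConfig(), plan)
        assert mod.folds[0].trace == base.folds[0].trace
        assert mod.folds[0].selected_features == base.folds[0].selected_features
        np.testing.assert_array_equal(
            mod.folds[0].ranking, base.folds[0].ranking
        )

    def test_strong_signal_recovers_planted_features(self):
        table = self.small_table(seed=5, effect=3.0)
        plan = make_fold_plan(15, 15, 5, 2)
        res = run_nested_selection(table, ClassifierConfig(), plan)
        assert res.mean_test_accuracy > 0.8
        selected = [n for f in res.folds for n in f.selected_names]
        signal = [n for n in selected if n.startswith("sig_")]
        assert len(signal) / len(selected) > 0.6

    def test_inconsistent_plan_rejected(self):
        table = self.small_table()
        plan = make_fold_plan(10, 20, 5, 0)
        with pytest.raises(ValueError, match="inconsistent"):
            run_nested_selection(table, ClassifierConfig(), plan)

    def test_age_control_residualizes_on_training_age_only(self):
        table = self.small_table()
        plan = make_fold_plan(15, 15, 5, 4)
        res = run_nested_selection(
            table, ClassifierConfig(), plan, age_control=True
        )
        assert np.isfinite(res.mean_test_accuracy)
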