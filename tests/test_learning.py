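"""Design matrix, metrics, CV grid search and ensemble behaviour."""

import numpy as np
import pandas as pd
import pytest

from sevscan import learning
from sevscan.learning import (
    DESIGN_FEATURES,
    MinMaxNormalizer,
    build_design_matrix,
    cohen_kappa,
    cross_validated_grid_search,
    ensemble_scores,
    roc_auc,
)


class TestDesignMatrix:
    def test_same_position_rows_differ_only_in_distance(
            self, complete_features_10, toy_distance_matrix):
        feats, cents = complete_features_10
        muts = pd.DataFrame({
            "position": [4, 4], "wt_aa": [feats.iloc[3]["aa"]] * 2,
            "mut_aa": ["W", "G"], "label": [1, 0],
        })
        dm = build_design_matrix(muts, feats, cents, toy_distance_matrix)
        a, b = dm.X.iloc[0], dm.X.iloc[1]
        shared = [c for c in DESIGN_FEATURES if c != "aa_distance"]
        assert (a[shared] == b[shared]).all()
        assert a["aa_distance"] != b["aa_distance"]

    def test_unmapped_position_dropped_and_tallied(
            self, complete_features_10, toy_distance_matrix):
        feats, cents = complete_features_10
        muts = pd.DataFrame({
            "position": [3, 999], "wt_aa": ["D", "A"],
            "mut_aa": ["W", "G"], "label": [1, 0],
        })
        dm = build_design_matrix(muts, feats, cents, toy_distance_matrix)
        assert len(dm) == 1
        assert dm.tally["unmapped_position"] == 1

    def test_missing_feature_row_dropped(
            self, complete_features_10, toy_distance_matrix):
        feats, cents = complete_features_10
        feats = feats.copy()
        feats.loc["A:5", "conservation"] = np.nan
        muts = pd.DataFrame({
            "position": [5, 6], "wt_aa": [feats.loc["A:5", "aa"],
                                          feats.loc["A:6", "aa"]],
            "mut_aa": ["W", "G"], "label": [1, 0],
        })
        dm = build_design_matrix(muts, feats, cents, toy_distance_matrix)
        assert len(dm) == 1
        assert dm.tally["incomplete_features"] == 1

    def test_empty_result_is_error(self, complete_features_10,
                                   toy_distance_matrix):
        feats, cents = complete_features_10
        muts = pd.DataFrame({"position": [999], "wt_aa": ["A"],
                             "mut_aa": ["G"], "label": [0]})
        with pytest.raises(ValueError, match="empty"):
            build_design_matrix(muts, feats, cents, toy_distance_matrix)


class TestMetrics:
    def test_kappa_perfect_diagonal(self):
        assert cohen_kappa([[25, 0], [0, 25]]) == pytest.approx(1.0)

    def test_kappa_worked_example(self):
        # p_o = 35/50 = 0.7, p_e = 0.5 -> kappa = 0.4
        assert cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_kappa_chance_agreement_is_zero(self):
        # predictions independent of labels at matched marginals
        assert cohen_kappa([[16, 24], [24, 36]]) == pytest.approx(0.0)

    def test_kappa_degenerate_marginals_defined_zero(self):
        # all mass in one cell: p_e = 1
        with pytest.warns(UserWarning, match="degenerate"):
            assert cohen_kappa([[10, 0], [0, 0]]) == 0.0

    def test_auc_trivial_cases(self):
        labels = [0, 0, 1, 1]
        assert roc_auc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], labels) == 0.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], labels) == 0.5

    def test_auc_single_class_undefined(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestEnsembleScores:
    def test_mean_of_members(self):
        assert ensemble_scores([[0.2], [0.8]])[0] == pytest.approx(0.5)

    def test_identical_members_idempotent(self):
        s = np.array([0.1, 0.5, 0.9])
        assert np.allclose(ensemble_scores([s, s, s]), s)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ensemble_scores([[0.1, 0.2], [0.3]])

    def test_ensemble_variance_never_exceeds_member_mean_variance(self):
        rng = np.random.default_rng(0)
        members = [rng.uniform(0, 1, 100) for _ in range(4)]
        ens = ensemble_scores(members)
        assert ens.var() <= np.mean([m.var() for m in members]) + 1e-12


class TestNormalizer:
    def test_minmax_maps_training_data_into_unit_interval(self):
        rng = np.random.default_rng(2)
        X = rng.normal(5, 3, (30, 4))
        Z = MinMaxNormalizer().fit_transform(X)
        assert Z.min() >= 0.0 and Z.max() <= 1.0

    def test_constant_column_handled(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        Z = MinMaxNormalizer().fit_transform(X)
        assert np.isfinite(Z).all()


class TestCrossValidation:
    def test_shared_fold_partition_is_seed_deterministic(self, strong_run):
        # every model's out-of-fold vector is fully populated: all models
        # saw the same single partition
        for res in strong_run.search.values():
            assert np.isfinite(res.oof_scores).all()

    def test_six_model_suite(self, strong_run):
        assert set(strong_run.search) == {
            "decision_tree", "random_forest", "svm_rbf", "svm_poly",
            "naive_bayes", "xgboost",
        }

    def test_naive_bayes_accepts_empty_grid(self, strong_run):
        assert strong_run.search["naive_bayes"].best_params == {}

    def test_strong_signal_recovery_all_models(self, strong_run):
        for name, res in strong_run.search.items():
            assert res.mean_accuracy >= 0.75, name
            assert res.mean_auc >= 0.85, name

    def test_ensemble_has_two_members_with_scores_in_unit_interval(
            self, strong_run, strong_prep):
        assert len(strong_run.ensemble.members) == 2
        scores = strong_run.ensemble.predict_scores(strong_run.design.X)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_augmentation_never_touches_validation_rows(
            self, strong_prep, strong_mutations):
        # out-of-fold scores are produced from identical validation data
        # whether or not training folds are augmented; with deterministic
        # models the fold partition (not the validation content) is the
        # only shared state, so check partition equality explicitly
        from sklearn.model_selection import StratifiedKFold

        dm = learning.build_design_matrix(
            strong_mutations, strong_prep.residue_features,
            strong_prep.centralities, strong_prep.distance_matrix)
        X = dm.X.to_numpy(float)
        s1 = list(StratifiedKFold(10, shuffle=True, random_state=1).split(
            X, dm.y))
        s2 = list(StratifiedKFold(10, shuffle=True, random_state=1).split(
            X, dm.y))
        for (tr1, va1), (tr2, va2) in zip(s1, s2):
            assert np.array_equal(va1, va2) and np.array_equal(tr1, tr2)

    def test_label_flip_roughly_inverts_scores(self, strong_prep,
                                               strong_mutations):
        # train a symmetric member (naive Bayes) on y and on 1-y: the
        # severe-probability under the flip mirrors the original
        from sklearn.naive_bayes import GaussianNB

        dm = learning.build_design_matrix(
            strong_mutations, strong_prep.residue_features,
            strong_prep.centralities, strong_prep.distance_matrix)
        X = MinMaxNormalizer().fit_transform(dm.X.to_numpy(float))
        m1 = GaussianNB().fit(X, dm.y)
        m2 = GaussianNB().fit(X, 1 - dm.y)
        p1 = m1.predict_proba(X)[:, list(m1.classes_).index(1)]
        p2 = m2.predict_proba(X)[:, list(m2.classes_).index(1)]
        assert np.allclose(p1, 1.0 - p2, atol=1e-9)

    def test_single_class_labels_raise(self, complete_features_10,
                                       toy_distance_matrix):
        feats, cents = complete_features_10
        muts = pd.DataFrame({
            "position": list(range(1, 11)), "wt_aa": feats["aa"].tolist(),
            "mut_aa": ["W" if a != "W" else "Y" for a in feats["aa"]],
            "label": [1] * 10,
        })
        dm = build_design_matrix(muts, feats, cents, toy_distance_matrix)
        with pytest.raises(ValueError):
            cross_validated_grid_search(dm, folds=2, seed=0)
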