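"""Schemes, leakage-free splits, the four families and cross-validation."""

from __future__ import annotations

import numpy as np
import pytest

import tonguemi as tm
from tonguemi.classify import ClassifierSpec, make_scheme
from conftest import gaussian_feature_matrix


class TestSchemes:
    @pytest.mark.parametrize("name,n", [
        ("LL-LR", 2), ("CL-CR", 2), ("LU-LD", 2),
        ("LL-LR-LU-LD", 4), ("CL-CR-LU-LD", 4),
        ("LL-LR-CL-CR-LU-LD", 6),
    ])
    def test_builtin_sizes(self, name, n):
        assert make_scheme(name).n_classes == n

    def test_scheme_filters_rows(self, tiny_study_features):
        fm = tiny_study_features
        pair = fm.filter_commands(make_scheme("LL-LR").commands)
        # tiny study: 12 trials/command x 2 commands x ... per subject
        assert pair.n_trials == fm.n_trials // 3
        assert set(pair.y) == {"LL", "LR"}
        full = fm.filter_commands(
            make_scheme("LL-LR-CL-CR-LU-LD").commands)
        assert full.n_trials == fm.n_trials

    def test_custom_scheme_from_commands(self):
        sch = make_scheme(["CL", "LD"])
        assert sch.commands == ("CL", "LD")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_scheme("left-vs-right")


class TestParticipantSplit:
    def test_15_subjects_split_10_5(self):
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=15,
                                     trials_per_class=4)
        train, test = tm.split_by_participant(fm, 0.7, seed=0)
        assert len(set(train.subjects)) == 10
        assert len(set(test.subjects)) == 5

    def test_subject_disjointness(self):
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=9)
        for seed in range(5):
            train, test = tm.split_by_participant(fm, 0.7, seed=seed)
            assert not set(train.subjects) & set(test.subjects)
            assert set(train.subjects) | set(test.subjects) \
                == set(fm.subjects)

    def test_seeded_reproducibility(self):
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=12)
        a = tm.split_by_participant(fm, 0.7, seed=3)
        b = tm.split_by_participant(fm, 0.7, seed=3)
        assert list(a[0].subjects) == list(b[0].subjects)

    def test_bad_ratio_rejected(self):
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=4)
        with pytest.raises(ValueError):
            tm.split_by_participant(fm, 1.2, seed=0)


class TestTraining:
    @pytest.mark.parametrize("family", tm.FAMILIES)
    def test_separable_blobs_are_learned(self, family, toy_separable_fm):
        train, test = tm.split_by_participant(toy_separable_fm, 0.7,
                                              seed=1)
        model = tm.train_classifier(train, ClassifierSpec(family),
                                    seed=0)
        pred = model.predict(test)
        assert np.mean(pred == test.y) == 1.0

    @pytest.mark.parametrize("family", tm.FAMILIES)
    def test_refit_same_seed_identical_predictions(self, family,
                                                   toy_separable_fm):
        train, test = tm.split_by_participant(toy_separable_fm, 0.7,
                                              seed=1)
        m1 = tm.train_classifier(train, ClassifierSpec(family), seed=5)
        m2 = tm.train_classifier(train, ClassifierSpec(family), seed=5)
        np.testing.assert_array_equal(m1.predict(test), m2.predict(test))

    def test_single_class_rejected(self, toy_separable_fm):
        only = toy_separable_fm.filter_commands(["LL"])
        with pytest.raises(ValueError, match="single class"):
            tm.train_classifier(only, ClassifierSpec("lda"))

    def test_lda_matches_bayes_rule_oracle(self):
        # brute-force Bayes rule under shared-covariance Gaussians,
        # fitted by direct formula on a small toy problem
        rng = np.random.default_rng(6)
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=2,
                                     trials_per_class=10,
                                     separation=2.0, seed=6)
        model = tm.train_classifier(fm, ClassifierSpec("lda"))
        X, y = fm.X, fm.y
        mu = {c: X[y == c].mean(axis=0) for c in ("LL", "LR")}
        centered = np.vstack([X[y == c] - mu[c] for c in ("LL", "LR")])
        cov = centered.T @ centered / (len(X) - 2)
        prec = np.linalg.pinv(cov)

        def bayes(x):
            scores = {c: x @ prec @ mu[c] - 0.5 * mu[c] @ prec @ mu[c]
                      for c in ("LL", "LR")}
            return max(scores, key=scores.get)

        Xq = rng.normal(0, 2, (40, 14))
        frame = fm.frame.iloc[:40].copy()
        frame.loc[:, [c for c in frame.columns if c.startswith("ERD_")]] \
            = Xq
        query = tm.FeatureMatrix(frame, fm.channels)
        oracle = np.array([bayes(x) for x in Xq])
        np.testing.assert_array_equal(model.predict(query), oracle)

    def test_singular_covariance_triggers_shrinkage(self, caplog):
        fm = gaussian_feature_matrix(("LL", "LR"), n_subjects=2,
                                     trials_per_class=6, seed=8)
        frame = fm.frame.copy()
        frame["ERD_O2"] = frame["ERD_O1"]  # perfectly collinear pair
        degenerate = tm.FeatureMatrix(frame, fm.channels)
        with caplog.at_level("WARNING"):
            model = tm.train_classifier(degenerate, ClassifierSpec("lda"))
        assert any("shrinkage" in r.message for r in caplog.records)
        assert len(model.predict(degenerate)) == degenerate.n_trials

    def test_wrong_feature_width_rejected(self, toy_separable_fm):
        model = tm.train_classifier(toy_separable_fm,
                                    ClassifierSpec("lda"))
        narrow = gaussian_feature_matrix(("LL", "LR"), n_channels=14)
        bad_X = narrow.frame.drop(columns=["ERD_O2"])
        with pytest.raises(ValueError):
            tm.predict(model, tm.FeatureMatrix(
                bad_X, tm.ChannelSet(tuple(
                    c for c in narrow.channels.labels if c != "O2"))))

    def test_ann_probabilities_sum_to_one(self, toy_separable_fm):
        model = tm.train_classifier(toy_separable_fm,
                                    ClassifierSpec("ann"), seed=2)
        proba = tm.classify.predict_proba(model, toy_separable_fm)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_prediction_length_matches_rows(self, toy_separable_fm):
        model = tm.train_classifier(toy_separable_fm,
                                    ClassifierSpec("nb"))
        assert len(model.predict(toy_separable_fm)) \
            == toy_separable_fm.n_trials


class TestCrossValidation:
    def test_perfectly_separable_scores_100(self, toy_separable_fm):
        cv = tm.crossvalidate(toy_separable_fm, ClassifierSpec("lda"),
                              k=5, seed=0)
        assert cv.mean == pytest.approx(100.0)
        assert cv.sd == pytest.approx(0.0)

    def test_folds_partition_trials(self, toy_null_fm):
        from sklearn.model_selection import StratifiedKFold
        X, y = toy_null_fm.X, toy_null_fm.y
        seen = np.zeros(len(y), dtype=int)
        for _, va in StratifiedKFold(10, shuffle=True,
                                     random_state=0).split(X, y):
            seen[va] += 1
        assert np.all(seen == 1)

    def test_null_data_scores_near_chance(self, toy_null_fm):
        cv = tm.crossvalidate(toy_null_fm, ClassifierSpec("lda"),
                              k=10, seed=0)
        # 240 trials, chance 50%: exact binomial 95% band
        from scipy.stats import binom
        n = toy_null_fm.n_trials
        lo, hi = binom.ppf([0.025, 0.975], n, 0.5) / n * 100
        assert lo <= cv.mean <= hi

    def test_class_smaller_than_k_rejected(self, toy_separable_fm):
        with pytest.raises(ValueError, match="smaller k"):
            tm.crossvalidate(toy_separable_fm, ClassifierSpec("lda"),
                             k=100)
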