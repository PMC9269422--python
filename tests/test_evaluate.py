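"""Cross-validation machinery, metrics, ROC/AUC, Welch's t-test, group
spectra, LV selection and the reference-classifier harness."""

import numpy as np
import pytest
from scipy import stats

import skinraman as sr
from skinraman.dataset import SpectralDataset
from skinraman.evaluate import (
    ConfusionMatrix,
    GaussianNaiveBayes,
    KNearestNeighbors,
    mean_roc,
)
from skinraman.exceptions import ConfigError


def make_dataset(X, labels):
    X = np.asarray(X, float)
    return SpectralDataset(
        X,
        np.linspace(400, 1800, X.shape[1]),
        np.asarray(labels),
        np.array([f"s{i}" for i in range(X.shape[0])]),
    )


def cohort_labels():
    return np.array(["eczema"] * 52 + ["healthy"] * 20)


class TestStratifiedKfold:
    def test_study_fold_composition(self):
        """52 eczema / 20 healthy at K = 10: every fold holds exactly 2
        healthy and 5 or 6 eczema subjects (fold sizes 7 or 8)."""
        labels = cohort_labels()
        folds = sr.stratified_kfold(labels, 10, seed=0)
        for k in range(10):
            test = labels[folds.fold_ids == k]
            assert np.sum(test == "healthy") == 2
            assert np.sum(test == "eczema") in (5, 6)
            assert test.size in (7, 8)

    def test_partition_property(self):
        labels = cohort_labels()
        folds = sr.stratified_kfold(labels, 7, seed=3)
        seen = np.zeros(labels.size, dtype=int)
        for _, test in folds.split():
            seen[test] += 1
        assert np.all(seen == 1)

    def test_deterministic_given_seed(self):
        labels = cohort_labels()
        a = sr.stratified_kfold(labels, 10, seed=5)
        b = sr.stratified_kfold(labels, 10, seed=5)
        assert np.array_equal(a.fold_ids, b.fold_ids)
        c = sr.stratified_kfold(labels, 10, seed=6)
        assert not np.array_equal(a.fold_ids, c.fold_ids)

    def test_small_class_warns(self):
        labels = np.array(["eczema"] * 10 + ["healthy"] * 2)
        with pytest.warns(UserWarning, match="some folds lack"):
            sr.stratified_kfold(labels, 5, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigError):
            sr.stratified_kfold(cohort_labels(), 1, seed=0)


class TestCmMetrics:
    def test_study_confusion_matrix(self):
        """The aggregated 10-fold matrix (tn 17, fp 3, fn 3, tp 49) gives
        sensitivity 0.94, specificity 0.85, accuracy 0.92 at 2 decimals."""
        acc, sens, spec = sr.cm_metrics(ConfusionMatrix(tn=17, fp=3, fn=3, tp=49))
        assert round(sens, 2) == 0.94
        assert round(spec, 2) == 0.85
        assert round(acc, 2) == 0.92

    def test_perfect_and_degenerate_rates(self):
        acc, sens, spec = sr.cm_metrics(ConfusionMatrix(1, 0, 0, 1))
        assert acc == sens == spec == 1.0
        acc, sens, spec = sr.cm_metrics(ConfusionMatrix(0, 10, 0, 10))
        assert sens == 1.0 and spec == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ConfigError):
            sr.cm_metrics(ConfusionMatrix())

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigError):
            ConfusionMatrix(tn=-1, fp=0, fn=0, tp=1)


class TestRocAuc:
    def test_perfect_separation(self):
        y = [True, True, False, False]
        pts = sr.roc_curve(y, [0.9, 0.8, 0.2, 0.1])
        assert sr.auc(pts) == pytest.approx(1.0)

    def test_constant_scores(self):
        y = [True, False, True, False]
        pts = sr.roc_curve(y, [0.5] * 4)
        assert sr.auc(pts) == pytest.approx(0.5)

    def test_anchored_at_corners(self, rng):
        y = rng.uniform(size=20) > 0.5
        y[0], y[1] = True, False
        pts = sr.roc_curve(y, rng.normal(size=20))
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)

    def test_trapezoid_equals_pairwise_statistic(self):
        """AUC equals P(score+ > score-) + 0.5 P(equal) by exhaustive
        pair enumeration."""
        y = np.array([True, False, True, False, True, False, False, True])
        s = np.array([0.7, 0.7, 0.9, 0.2, 0.4, 0.4, 0.1, 0.3])
        pos, neg = s[y], s[~y]
        pairwise = np.mean(
            [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
        )
        assert sr.auc(sr.roc_curve(y, s)) == pytest.approx(pairwise, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            sr.roc_curve([True, True], [0.1, 0.2])

    def test_mean_roc_grid_and_averaging(self):
        c1 = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 1.0]])  # perfect
        c2 = np.array([[0.0, 0.0], [1.0, 1.0]])  # chance
        avg = mean_roc([c1, c2])
        assert avg.shape == (101, 2)
        i = 50  # fpr = 0.5
        assert avg[i, 1] == pytest.approx((1.0 + 0.5) / 2)


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = sr.welch_ttest(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        """Direct evaluation of the Welch statistic and Satterthwaite
        degrees of freedom on fixed vectors."""
        a = np.array([12.1, 14.3, 11.8, 13.5, 12.9])
        b = np.array([10.2, 9.8, 10.9, 10.4])
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t_exp = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_exp = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p_exp = 2 * stats.t.sf(abs(t_exp), df_exp)
        t, df, p = sr.welch_ttest(a, b)
        assert t == pytest.approx(t_exp, abs=1e-10)
        assert df == pytest.approx(df_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-10)

    def test_study_group_parameters_give_small_p(self):
        """At the study's group sizes and TEWL moments the test is highly
        significant."""
        rng = np.random.default_rng(0)
        cfg = sr.CohortConfig()
        a = rng.normal(*cfg.tewl_eczema, size=52)
        b = rng.normal(*cfg.tewl_healthy, size=20)
        _, _, p = sr.welch_ttest(a, b)
        assert p < 0.001

    def test_too_small_group_rejected(self):
        with pytest.raises(ConfigError):
            sr.welch_ttest([1.0], [1.0, 2.0])


class TestGroupSpectra:
    def test_identical_classes_zero_difference(self, rng):
        X = np.vstack([rng.normal(size=5)] * 6)
        ds = make_dataset(X, ["eczema"] * 3 + ["healthy"] * 3)
        out = sr.group_spectra(ds)
        assert np.allclose(out["difference"], 0.0)

    def test_two_subject_hand_computation(self):
        X = np.array([[1.0, 3.0], [3.0, 5.0], [0.0, 1.0], [2.0, 3.0]])
        ds = make_dataset(X, ["eczema", "eczema", "healthy", "healthy"])
        out = sr.group_spectra(ds)
        assert np.allclose(out["eczema_mean"], [2.0, 4.0])
        assert np.allclose(out["healthy_mean"], [1.0, 2.0])
        assert np.allclose(out["eczema_sd"], [np.sqrt(2.0), np.sqrt(2.0)])
        assert np.allclose(out["difference"], [1.0, 2.0])

    def test_noiseless_cohort_difference_confined(self, noiseless_cohort):
        """Surface spectra of the noiseless cohort differ between classes
        only inside the discriminative bands (up to Lorentzian tails)."""
        grid = noiseless_cohort[0].stack.grid
        X = np.vstack(
            [r.stack.intensities[r.surface_depth_index_true] for r in noiseless_cohort]
        )
        ds = make_dataset(X, [r.group for r in noiseless_cohort])
        diff = np.abs(sr.group_spectra(ds)["difference"])
        from skinraman.simulate import DISCRIMINATIVE_BANDS

        near_band = np.zeros(grid.size, dtype=bool)
        for lo, hi in DISCRIMINATIVE_BANDS:
            near_band |= (grid > lo - 80) & (grid < hi + 80)
        assert diff[near_band].max() > 50 * diff[~near_band].max()

    def test_single_subject_class_warns(self, rng):
        X = rng.normal(size=(3, 4))
        ds = make_dataset(X, ["eczema", "eczema", "healthy"])
        with pytest.warns(UserWarning, match="SD reported as 0"):
            out = sr.group_spectra(ds)
        assert np.allclose(out["healthy_sd"], 0.0)


class TestSelectNumLvs:
    def test_single_factor_separable_chooses_one(self, rng):
        t = np.r_[rng.normal(4.0, 0.3, 26), rng.normal(-4.0, 0.3, 10)]
        X = np.outer(t, rng.normal(size=40)) + 0.01 * rng.normal(size=(36, 40))
        ds = make_dataset(X, ["eczema"] * 26 + ["healthy"] * 10)
        curve = sr.select_num_lvs(ds, A_max=5, K=6, seed=0)
        assert curve.chosen_A == 1
        assert curve.cv_error[0] == 0.0

    def test_calibration_error_non_increasing(self, processed_default):
        curve = sr.select_num_lvs(processed_default, A_max=8, K=10, seed=1)
        assert np.all(np.diff(curve.calibration_error) <= 1e-12)

    def test_first_minimum_rule(self, rng):
        # engineered tie: curve minimum appears at two A values; the
        # smaller one must be chosen
        t = np.r_[rng.normal(3.0, 1.5, 26), rng.normal(-3.0, 1.5, 10)]
        X = np.outer(t, rng.normal(size=30)) + rng.normal(size=(36, 30))
        ds = make_dataset(X, ["eczema"] * 26 + ["healthy"] * 10)
        curve = sr.select_num_lvs(ds, A_max=6, K=6, seed=0)
        mins = np.flatnonzero(curve.cv_error <= curve.cv_error.min() + 1e-12)
        assert curve.chosen_A == mins[0] + 1


class TestCrossValidate:
    def test_separable_data_perfect_aggregate(self, rng):
        t = np.r_[rng.normal(5.0, 0.2, 26), rng.normal(-5.0, 0.2, 10)]
        X = np.outer(t, rng.normal(size=25)) + 0.01 * rng.normal(size=(36, 25))
        ds = make_dataset(X, ["eczema"] * 26 + ["healthy"] * 10)
        rep = sr.cross_validate_plsda(ds, A=1, K=6, seed=0)
        assert rep.aggregated.fp == 0 and rep.aggregated.fn == 0
        assert rep.accuracy_mean == pytest.approx(1.0)
        assert rep.auc_mean == pytest.approx(1.0)

    def test_aggregate_is_sum_of_folds(self, processed_default):
        rep = sr.cross_validate_plsda(processed_default, A=2, K=10, seed=0)
        assert rep.aggregated.total == 72
        total = sum(rep.per_fold, ConfusionMatrix())
        assert vars(total) == vars(rep.aggregated)
        assert rep.mean_roc.shape == (101, 2)

    def test_null_data_near_majority_rate(self, rng):
        """Labels shuffled against pure-noise spectra: CV accuracy stays
        within 3 SD of the 52/72 majority-class rate."""
        X = rng.normal(size=(72, 120))
        labels = cohort_labels()
        rng.shuffle(labels)
        ds = make_dataset(X, labels)
        rep = sr.cross_validate_plsda(ds, A=2, K=10, seed=0)
        p0 = 52 / 72
        sd = np.sqrt(p0 * (1 - p0) / 72)
        assert abs(rep.accuracy_mean - p0) < 3 * sd

    def test_null_calibration_over_permutations(self, rng):
        """Mean CV accuracy over 200 label permutations of null data is
        within 2% of the majority-class rate.

        Low feature count and a single component keep the held-out score
        spread small; with many noise features PLS-DA's spurious fitted
        directions widen the score distribution around the class-mean
        coding and drag null accuracy below the majority rate.
        """
        X = rng.normal(size=(72, 3))
        labels = cohort_labels()
        accs = []
        for i in range(200):
            perm = rng.permutation(72)
            ds = make_dataset(X, labels[perm])
            rep = sr.cross_validate_plsda(ds, A=1, K=10, seed=i)
            accs.append(rep.accuracy_mean)
        assert abs(np.mean(accs) - 52 / 72) < 0.02


class TestReferenceClassifiers:
    def test_native_naive_bayes_matches_manual_posterior(self):
        """Two-feature toy: prediction agrees with a hand-evaluated
        Gaussian Bayes rule."""
        X = np.array([[0.0, 0.0], [0.2, -0.1], [-0.1, 0.1], [3.0, 2.9], [2.8, 3.2], [3.1, 3.0]])
        y_pos = np.array([False, False, False, True, True, True])
        nb = GaussianNaiveBayes().fit(X, y_pos)
        queries = np.array([[0.1, 0.0], [2.9, 3.1], [1.5, 1.4]])
        scores = nb.score_samples(queries)
        for q, s in zip(queries, scores):
            manual = 0.0
            for cls, sign in ((True, 1.0), (False, -1.0)):
                mu, var, logprior = nb.stats_[cls]
                ll = logprior - 0.5 * np.sum(np.log(2 * np.pi * var) + (q - mu) ** 2 / var)
                manual += sign * ll
            assert s == pytest.approx(manual, abs=1e-12)
        assert scores[0] < 0 < scores[1]

    def test_native_knn_scores(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1], [5.2]])
        y_pos = np.array([False, False, True, True, True])
        knn = KNearestNeighbors(k=3).fit(X, y_pos)
        s = knn.score_samples(np.array([[5.05], [0.05]]))
        assert s[0] == 1.0 and s[1] == pytest.approx(1 / 3)

    def test_harness_table_shape_and_separable_accuracy(self, rng):
        t = np.r_[rng.normal(4.0, 0.3, 26), rng.normal(-4.0, 0.3, 10)]
        X = np.outer(t, rng.normal(size=30)) + 0.05 * rng.normal(size=(36, 30))
        ds = make_dataset(X, ["eczema"] * 26 + ["healthy"] * 10)
        spec = [("lda", 3), ("naive_bayes", 3), ("knn", 3)]
        table = sr.reference_classifiers(ds, spec, K=6, seed=0)
        assert len(table) == 3
        assert set(table["classifier"]) == {"lda", "naive_bayes", "knn"}
        assert (table["accuracy_mean"] > 0.9).all()

    def test_unknown_classifier_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(10, 5)), ["eczema"] * 5 + ["healthy"] * 5)
        with pytest.raises(ConfigError):
            sr.reference_classifiers(ds, [("forest", 3)], K=2, seed=0)
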