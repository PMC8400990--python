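import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexcad import diagnosis as dg
from cortexcad.surface_recon import TriMesh
from cortexcad.synthetic_phantoms import CohortSpec, make_cohort


class TestComputeMetrics:
    def test_study_split_confusion_matrix(self):
        """The unique 86 MCI / 60 NC confusion matrix with these counts."""
        m = dg.compute_metrics(tp=73, fp=7, tn=53, fn=13)
        assert round(m["accuracy"], 2) == 86.3
        assert round(m["sensitivity"], 2) == 84.88
        assert round(m["specificity"], 2) == 88.33

    def test_uniform_counts(self):
        m = dg.compute_metrics(1, 1, 1, 1)
        assert m == {"accuracy": 50.0, "sensitivity": 50.0, "specificity": 50.0}

    def test_perfect_classifier(self):
        m = dg.compute_metrics(10, 0, 10, 0)
        assert m == {"accuracy": 100.0, "sensitivity": 100.0, "specificity": 100.0}

    def test_zero_denominator_flagged_undefined(self):
        m = dg.compute_metrics(0, 5, 5, 0)
        assert np.isnan(m["sensitivity"])
        assert not np.isnan(m["specificity"])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(*(st.integers(0, 500) for _ in range(4)))
    def test_metric_identities(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        m = dg.compute_metrics(tp, fp, tn, fn)
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / (tp + fp + tn + fn))
        if tp + fn:
            assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        if tn + fp:
            assert m["specificity"] == pytest.approx(100 * tn / (tn + fp))


class TestTrainPredict:
    def test_separable_cohort_training_accuracy(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        model = dg.train(table, labels, seed=0)
        _, pred, _ = dg.predict(model, table)
        assert (pred == labels).mean() == 1.0

    def test_prediction_deterministic(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        m1 = dg.train(table, labels, seed=3)
        m2 = dg.train(table, labels, seed=3)
        P1, _, s1 = dg.predict(m1, table)
        P2, _, s2 = dg.predict(m2, table)
        np.testing.assert_array_equal(P1, P2)
        np.testing.assert_array_equal(s1, s2)

    def test_margin_classifier_duplication_equivalence(self, small_separable_cohort):
        """Duplicating every sample while halving the per-sample penalty C
        (the weighting-equivalence of the unnormalized hinge loss) leaves
        the margin classifier's decision values unchanged."""
        table, labels, _ = small_separable_cohort
        y = dg._binarize(labels)
        rng = np.random.default_rng(0)
        Z = np.column_stack([y + 0.1 * rng.normal(size=len(y)),
                             rng.normal(size=len(y))])
        from sklearn.svm import SVC

        a = SVC(kernel="linear", C=1.0, tol=1e-10).fit(Z, y)
        b = SVC(kernel="linear", C=0.5, tol=1e-10).fit(
            np.vstack([Z, Z]), np.concatenate([y, y]))
        np.testing.assert_allclose(
            a.decision_function(Z), b.decision_function(Z), atol=1e-6)

    def test_mean_subject_null_regions_calibrated(self, small_separable_cohort):
        table, labels, truth = small_separable_cohort
        model = dg.train(table, labels, seed=0)
        mean_tab = table.subset([0])
        mean_tab.features[0] = np.nanmean(table.features, axis=0)
        P = dg.regional_probabilities(model, mean_tab)
        null = [i for i, r in enumerate(model.regions)
                if r not in truth["affected_regions"]]
        assert np.all((P[0, null] > 0.2) & (P[0, null] < 0.8))

    def test_planted_regions_rank_above_null(self, small_separable_cohort):
        table, labels, truth = small_separable_cohort
        model = dg.train(table, labels, seed=0)
        P = dg.regional_probabilities(model, table)
        mci = labels == "MCI"
        aff = [i for i, r in enumerate(model.regions)
               if r in truth["affected_regions"]]
        null = [i for i, r in enumerate(model.regions)
                if r not in truth["affected_regions"]]
        assert np.median(P[mci][:, aff]) > np.median(P[mci][:, null])

    def test_single_class_rejected(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        with pytest.raises(ValueError, match="per class"):
            dg.train(table, np.array(["MCI"] * len(labels)), seed=0)

    def test_mostly_missing_region_dropped(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        crippled = table.copy()
        crippled.features[: int(0.8 * len(labels)), 0, :] = np.nan
        crippled.missing[: int(0.8 * len(labels)), 0] = True
        model = dg.train(crippled, labels, seed=0)
        assert crippled.regions[0] in model.dropped_regions
        assert crippled.regions[0] not in model.regions


class TestKFold:
    def test_folds_partition_and_determinism(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        r1 = dg.kfold_evaluate(table, labels, k=4, seed=5)
        r2 = dg.kfold_evaluate(table, labels, k=4, seed=5)
        assert r1.to_dict() == r2.to_dict()
        # pooled counts partition the cohort exactly once
        assert r1.tp + r1.fp + r1.tn + r1.fn == len(labels)
        assert r1.tp + r1.fn == int((labels == "MCI").sum())
        assert r1.tn + r1.fp == int((labels == "NC").sum())

    def test_separable_cohort_high_cv_accuracy(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        rep = dg.kfold_evaluate(table, labels, k=4, seed=1)
        assert rep.accuracy >= 90.0

    def test_permuted_labels_near_chance(self):
        spec = CohortSpec(n_per_group=(15, 15), n_regions=6,
                          affected_regions=(1, 2), effect_size=3.0, seed=21)
        table, labels, _ = make_cohort(spec)
        accs = []
        for rep_i in range(20):
            rng = np.random.default_rng(100 + rep_i)
            perm = rng.permutation(labels)
            accs.append(dg.kfold_evaluate(table, perm, k=3, seed=rep_i).accuracy)
        assert 35.0 <= np.mean(accs) <= 65.0

    def test_k_larger_than_class_rejected(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        with pytest.raises(ValueError):
            dg.kfold_evaluate(table, labels, k=21, seed=0)


class TestCompareClassifiers:
    def test_all_methods_on_separable_cohort(self, small_separable_cohort):
        table, labels, _ = small_separable_cohort
        reports = dg.compare_classifiers(table, labels, k=4, seed=2)
        assert set(reports) == {"linear_svm", "polynomial_svm", "rbf_svm",
                                "decision_tree", "ensemble", "knn"}
        hashes = {r.fold_hash for r in reports.values()}
        assert len(hashes) == 1
        for name, rep in reports.items():
            assert rep.accuracy >= 80.0, name

    def test_tiny_bandwidth_rbf_overfits(self):
        """An RBF with tiny bandwidth memorizes training data but fails CV."""
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = (rng.random(30) > 0.5).astype(int)
        clf = SVC(kernel="rbf", gamma=1000.0, C=100.0).fit(X, y)
        train_acc = clf.score(X, y)
        from sklearn.model_selection import cross_val_score

        cv_acc = cross_val_score(SVC(kernel="rbf", gamma=1000.0, C=100.0),
                                 X, y, cv=5).mean()
        assert train_acc > 0.95
        assert cv_acc < train_acc - 0.2


class TestBehavioralCorrelation:
    def _probs(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"r1": rng.uniform(size=n), "r2": rng.uniform(size=n)})

    def test_identical_scores_perfect_correlation(self):
        probs = self._probs()
        scores = pd.DataFrame({"task": probs["r1"]})
        out = dg.behavioral_correlation(probs, scores)
        row = out[(out.region == "r1") & (out.task == "task")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p < 1e-10

    def test_negated_scores(self):
        probs = self._probs(seed=1)
        scores = pd.DataFrame({"task": -probs["r2"]})
        out = dg.behavioral_correlation(probs, scores)
        row = out[(out.region == "r2") & (out.task == "task")].iloc[0]
        assert row.r == pytest.approx(-1.0)

    def test_independent_null_small_r(self):
        rng = np.random.default_rng(2)
        probs = pd.DataFrame({"r1": rng.normal(size=80)})
        scores = pd.DataFrame({"t1": rng.normal(size=80)})
        out = dg.behavioral_correlation(probs, scores)
        assert abs(out.iloc[0].r) < 0.3

    def test_constant_column_flagged(self):
        probs = pd.DataFrame({"r1": np.ones(10)})
        scores = pd.DataFrame({"t1": np.arange(10.0)})
        out = dg.behavioral_correlation(probs, scores)
        assert out.iloc[0].undefined
        assert np.isnan(out.iloc[0].r)

    def test_q_values_present(self):
        probs = self._probs(seed=3)
        rng = np.random.default_rng(4)
        scores = pd.DataFrame({"t1": rng.normal(size=40), "t2": rng.normal(size=40)})
        out = dg.behavioral_correlation(probs, scores)
        assert (out.q >= out.p - 1e-12).all()


class TestSeverityExport:
    def _mesh(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.5]], float)
        f = np.array([[0, 1, 2], [1, 3, 2]])
        return TriMesh(v, f)

    def test_zero_probabilities_uniform(self, tmp_path):
        sev = dg.export_severity({1: 0.0, 2: 0.0}, self._mesh(),
                                 np.array([1, 1, 2, 2]))
        assert not sev.any()

    def test_single_hot_region(self):
        sev = dg.export_severity({1: 0.0, 2: 1.0}, self._mesh(),
                                 np.array([1, 1, 2, 0]))
        np.testing.assert_allclose(sev, [0, 0, 1, 0])

    def test_csv_round_trip(self, tmp_path):
        probs = {1: 0.25, 2: 0.75}
        dg.export_severity(probs, self._mesh(), np.array([1, 1, 2, 2]),
                           ply_path=tmp_path / "sev.ply",
                           csv_path=tmp_path / "sev.csv")
        back = pd.read_csv(tmp_path / "sev.csv")
        assert dict(zip(back.region, back.probability)) == probs
        assert (tmp_path / "sev.ply").exists()


class TestLeakage:
    def test_fold_fit_invariant_to_test_subject_removal(self, small_separable_cohort):
        from sklearn.model_selection import StratifiedKFold

        table, labels, _ = small_separable_cohort
        y = dg._binarize(labels)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=9)
        tr, te = next(iter(skf.split(np.zeros(len(y)), y)))
        model_full = dg.train(table.subset(tr), y[tr], seed=9)
        # deleting a test-fold subject cannot change the training portion
        keep = np.setdiff1d(np.arange(len(y)), te[:1])
        remap = {old: new for new, old in enumerate(keep)}
        tr2 = np.array([remap[i] for i in tr])
        reduced = table.subset(keep)
        model_red = dg.train(reduced.subset(tr2), y[keep][tr2], seed=9)
        assert dg.model_fingerprint(model_full) == dg.model_fingerprint(model_red)
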