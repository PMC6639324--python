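import numpy as np
import pytest

from oracles import auc_brute_force
from perfradiomics.io import ClassLabel, FeatureTable
from perfradiomics.modeling import (
    ClassifierSpec,
    Protocol,
    SelectionMode,
    binomial_test,
    operating_metrics,
    predict_new,
    roc_auc,
    run_cv,
    train_classifier,
)


def _table(X, y, names=None):
    n, p = np.asarray(X).shape
    return FeatureTable(
        subject_ids=[f"s{i}" for i in range(n)],
        feature_names=names or [f"f{j}" for j in range(p)],
        values=np.asarray(X, dtype=float),
        labels=[ClassLabel.PD if v else ClassLabel.PSP for v in y],
    )


class TestRocAuc:
    def test_perfectly_separated(self):
        auc, *_ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_worked_three_of_four_concordant(self):
        auc, *_ = roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_negation_symmetry(self, rng):
        s = rng.normal(size=30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a1, *_ = roc_auc(s, y)
        a2, *_ = roc_auc(-s, y)
        assert a1 + a2 == pytest.approx(1.0)

    def test_equals_concordant_pair_fraction_with_ties(self):
        """100 random score/label sets incl. tied scores vs the pair-counting oracle."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(6, 25)
            s = rng.choice([0.1, 0.25, 0.5, 0.5, 0.8, 0.9], size=n)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            auc, *_ = roc_auc(s, y)
            assert auc == pytest.approx(auc_brute_force(s, y), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


class TestOperatingMetrics:
    def test_worked_confusion_matrix(self):
        # TP=70 FN=6 TN=19 FP=3 at threshold 0.5
        y = np.array([1] * 76 + [0] * 22)
        s = np.array([1.0] * 70 + [0.0] * 6 + [1.0] * 3 + [0.0] * 19)
        m = operating_metrics(s, y, threshold_rule=0.5)
        assert (m.tp, m.fn, m.tn, m.fp) == (70, 6, 19, 3)
        assert m.sensitivity == pytest.approx(70 / 76)
        assert m.specificity == pytest.approx(19 / 22)
        assert m.accuracy == pytest.approx(89 / 98)
        assert m.ppv == pytest.approx(70 / 73)
        assert m.npv == pytest.approx(19 / 25)

    def test_perfect_scores_all_ones(self):
        y = np.array([1, 1, 1, 0, 0])
        m = operating_metrics([0.9, 0.8, 0.7, 0.2, 0.1], y)
        assert (m.accuracy, m.sensitivity, m.specificity, m.ppv, m.npv) == (1, 1, 1, 1, 1)

    def test_class_swap_exchanges_sens_spec_and_ppv_npv(self, rng):
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        m1 = operating_metrics(s, y, threshold_rule=0.0)
        m2 = operating_metrics(-s + 1e-9, 1 - y, threshold_rule=0.0)
        assert m2.sensitivity == pytest.approx(m1.specificity)
        assert m2.specificity == pytest.approx(m1.sensitivity)
        assert m2.ppv == pytest.approx(m1.npv)
        assert m2.npv == pytest.approx(m1.ppv)


class TestBinomial:
    def test_nine_of_ten_exact_tail(self):
        assert binomial_test(9, 10, 0.5) == pytest.approx(11 / 1024, abs=1e-15)

    def test_all_correct_closed_form(self):
        assert binomial_test(20, 20, 0.5) == pytest.approx(2.0**-20, rel=1e-12)

    def test_null_consistent_accuracy_not_significant(self):
        assert binomial_test(round(40 * 0.6), 40, 0.6) > 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_test(5, 10, 1.0)


class TestTraining:
    @pytest.mark.parametrize("family", ["svm", "tree"])
    def test_separable_single_feature_resubstitution_perfect(self, family, rng):
        x = np.concatenate([rng.uniform(0, 1, 15), rng.uniform(2, 3, 15)])
        y = np.array([0] * 15 + [1] * 15)
        table = _table(x[:, None], y)
        model = train_classifier(ClassifierSpec(family=family), table)
        assert (model.predict(table.values) == y).all()

    def test_single_class_rejected(self, rng):
        table = _table(rng.normal(size=(8, 2)), np.ones(8))
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ClassifierSpec(), table)

    def test_zero_variance_feature_dropped_with_warning(self, rng, caplog):
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        y = (X[:, 0] > 0).astype(int)
        with caplog.at_level("WARNING"):
            model = train_classifier(ClassifierSpec(), _table(X, y))
        assert "zero-variance" in caplog.text
        assert model.keep_.sum() == 2

    def test_permuted_labels_yield_chance_level_auc(self, rng):
        """Null property: mean LOOCV AUC over 20 label permutations is ~0.5."""
        X = rng.normal(size=(98, 15))
        y = np.array([1] * 76 + [0] * 22)
        aucs = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(98)
            rep = run_cv(ClassifierSpec("svm"), _table(X, y[perm]), protocol=Protocol.LOOCV)
            aucs.append(rep.auc)
        assert 0.35 <= np.mean(aucs) <= 0.65


class TestRunCV:
    def _separable(self, rng, n=40):
        y = np.array([1] * (n // 2) + [0] * (n // 2))
        X = rng.normal(size=(n, 5))
        X[:, 2] += 3.0 * y
        return _table(X, y), y

    def test_loocv_emits_one_prediction_per_subject(self, rng):
        table, y = self._separable(rng)
        rep = run_cv(ClassifierSpec("svm"), table, protocol=Protocol.LOOCV)
        assert len(rep.scores) == len(rep.predicted) == table.n_subjects
        assert rep.auc > 0.9

    def test_seed_reproducibility_kfold(self, rng):
        table, y = self._separable(rng, n=60)
        r1 = run_cv(ClassifierSpec("tree"), table, protocol=Protocol.KFOLD10, seed=5)
        r2 = run_cv(ClassifierSpec("tree"), table, protocol=Protocol.KFOLD10, seed=5)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.auc == r2.auc

    def test_pooled_selection_carries_caveat(self, rng):
        table, y = self._separable(rng)
        rep = run_cv(
            ClassifierSpec("svm"), table, protocol=Protocol.LOOCV,
            selector=("mrmr", 3), selection_mode=SelectionMode.POOLED,
        )
        assert rep.caveat is not None and "outside CV" in rep.caveat
        assert len(rep.selected_features) == 3
        nested = run_cv(
            ClassifierSpec("svm"), table, protocol=Protocol.LOOCV,
            selector=("mrmr", 3), selection_mode=SelectionMode.NESTED,
        )
        assert nested.caveat is None

    def test_binomial_p_uses_no_information_rate(self, rng):
        table, y = self._separable(rng)
        rep = run_cv(ClassifierSpec("svm"), table, protocol=Protocol.LOOCV)
        correct = rep.tp_total if hasattr(rep, "tp_total") else int(
            (rep.predicted == rep.labels).sum()
        )
        assert rep.binomial_p == pytest.approx(
            binomial_test(correct, table.n_subjects, rep.no_information_rate)
        )

    def test_report_serializes_to_json(self, rng, tmp_path):
        table, _ = self._separable(rng)
        rep = run_cv(ClassifierSpec("svm"), table, protocol=Protocol.RESUBSTITUTION)
        rep.to_json(tmp_path / "r.json")
        import json

        data = json.loads((tmp_path / "r.json").read_text())
        assert data["protocol"] == "resubstitution"
        assert len(data["scores"]) == table.n_subjects


class TestPredictNew:
    def _fitted(self, rng):
        y = np.array([1] * 20 + [0] * 20)
        X = rng.normal(size=(40, 4))
        X[:, 0] += 2.5 * y
        table = _table(X, y)
        model = train_classifier(ClassifierSpec("svm"), table)
        return model, table, y

    def test_training_subjects_reproduce_resubstitution(self, rng):
        model, table, y = self._fitted(rng)
        labels, proba = predict_new(model, table.feature_names, table)
        resub = model.predict(table.values)
        assert [l is ClassLabel.PD for l in labels] == [p == 1 for p in resub]
        assert np.all((proba >= 0) & (proba <= 1))

    def test_copy_of_training_pd_subject_classified_pd(self, rng):
        model, table, y = self._fitted(rng)
        # a confidently-PD training subject duplicated as a "new" arrival
        scores = model.decision_scores(table.values)
        idx = int(np.argmax(np.where(y == 1, scores, -np.inf)))
        new = FeatureTable(
            subject_ids=["new"],
            feature_names=table.feature_names,
            values=table.values[idx : idx + 1].copy(),
        )
        labels, proba = predict_new(model, table.feature_names, new)
        assert labels[0] is ClassLabel.PD
        assert proba[0] > 0.5

    def test_column_mismatch_reported(self, rng):
        model, table, y = self._fitted(rng)
        bad = FeatureTable(
            subject_ids=["n"], feature_names=["f0", "f1", "f2", "weird"],
            values=np.zeros((1, 4)),
        )
        with pytest.raises(ValueError, match="feature mismatch"):
            predict_new(model, table.feature_names, bad)

    def test_held_out_generator_pd_subjects_classified_pd(self):
        """New phantoms from the PD-like setting are called PD >= 90% of the time."""
        from perfradiomics.modeling import ClassifierSpec
        from perfradiomics.pipeline import simulate_feature_table
        from perfradiomics.synthetic import SyntheticCohortConfig, generate_lesion
        from perfradiomics.texture import extract_subject_features
        from perfradiomics.io import MapKind

        cfg = SyntheticCohortConfig(n_pd=20, n_psp=10, seed=42)
        train = simulate_feature_table(cfg)
        model = train_classifier(ClassifierSpec("svm"), train)
        rows = []
        for s in range(10):  # subject seeds beyond the training cohort
            lesion = generate_lesion(cfg, ClassLabel.PD, 1000 + s)
            feats = extract_subject_features(lesion[MapKind.KTRANS], lesion[MapKind.RCBV])
            rows.append([feats[n] for n in train.feature_names])
        new = FeatureTable(
            subject_ids=[f"new{s}" for s in range(10)],
            feature_names=train.feature_names,
            values=np.asarray(rows),
        )
        labels, proba = predict_new(model, train.feature_names, new)
        assert sum(l is ClassLabel.PD for l in labels) >= 9
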