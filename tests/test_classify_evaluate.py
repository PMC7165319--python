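"""Classifier training, LOOCV, independent evaluation and ROC analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.dummy import DummyClassifier

import uridx
from uridx.classify_evaluate import (ClassificationMetrics, confusion_from_rates,
                                     decision_scores, evaluate, loocv, roc_auc,
                                     train_classifier)
from uridx.io_preprocess import AbundanceMatrix

from conftest import make_matrix, make_metadata


def auc_pairwise_oracle(scores, labels):
    """AUC = P(pos > neg) + 0.5 P(pos == neg) over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == "AA"]
    neg = [s for s, l in zip(scores, labels) if l == "CON"]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def separable_toy(n_per=6):
    """Two features, linearly separable classes."""
    rng = np.random.default_rng(0)
    aa = rng.normal([5, 5], 0.3, (n_per, 2))
    con = rng.normal([-5, -5], 0.3, (n_per, 2))
    values = np.vstack([aa, con]).T  # 2 proteins x samples
    samples = [f"s{i}" for i in range(2 * n_per)]
    meta = make_metadata(samples, ["AA"] * n_per + ["CON"] * n_per)
    df = pd.DataFrame(values, index=["PROT0", "PROT1"], columns=samples)
    matrix = AbundanceMatrix(df, "log2_imputed", imputation_value=float(values.min()))
    return matrix, meta


class TestMetrics:
    def test_perfect_predictions(self):
        m = ClassificationMetrics.from_predictions(["AA", "CON"], ["AA", "CON"])
        assert m.as_percentages() == {"accuracy": 100.0, "sensitivity": 100.0,
                                      "specificity": 100.0}

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_accuracy_identity(self, tp, fp, tn, fn):
        """accuracy == (sens*P + spec*N)/(P+N) holds exactly."""
        if tp + fn == 0 or tn + fp == 0:
            return
        m = ClassificationMetrics(tp=tp, fp=fp, tn=tn, fn=fn)
        lhs = m.accuracy
        rhs = (m.sensitivity * (tp + fn) + m.specificity * (tn + fp)) / m.n
        assert lhs == pytest.approx(rhs, abs=1e-12)
        assert 0 <= m.sensitivity <= 1 and 0 <= m.specificity <= 1


class TestTrainAndEvaluate:
    @pytest.mark.parametrize("algo", ["rf", "svm", "nb"])
    def test_separable_toy_perfect_training_accuracy(self, algo):
        matrix, meta = separable_toy()
        model = train_classifier(matrix, meta, ["PROT0", "PROT1"], algo=algo, seed=1)
        pred = uridx.classify_evaluate.predict(model, matrix, meta)
        truth = meta.set_index("sample_id").loc[pred.index, "group"]
        assert (pred == truth).all()

    def test_same_seed_identical_predictions(self):
        matrix, meta = separable_toy()
        m1 = train_classifier(matrix, meta, ["PROT0", "PROT1"], algo="rf", seed=5)
        m2 = train_classifier(matrix, meta, ["PROT0", "PROT1"], algo="rf", seed=5)
        p1 = uridx.classify_evaluate.predict(m1, matrix, meta)
        p2 = uridx.classify_evaluate.predict(m2, matrix, meta)
        assert (p1 == p2).all()

    def test_single_class_training_errors(self):
        matrix, meta = separable_toy()
        aa_only = meta[meta["group"] == "AA"]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(matrix.select_samples(aa_only["sample_id"].tolist()),
                             aa_only, ["PROT0", "PROT1"], algo="rf", seed=1)

    def test_missing_panel_protein_errors_by_name(self):
        matrix, meta = separable_toy()
        with pytest.raises(KeyError, match="GHOST"):
            train_classifier(matrix, meta, ["GHOST"], algo="rf", seed=1)

    def test_validation_overlap_rejected(self):
        matrix, meta = separable_toy()
        model = train_classifier(matrix, meta, ["PROT0", "PROT1"], algo="rf", seed=1)
        with pytest.raises(ValueError, match="overlap"):
            evaluate(model, matrix, meta)

    def test_strong_effect_validation_accuracy(self, strong_cohort, strong_discovery):
        """A cohort with 2.5-log2 markers is classified nearly perfectly on an
        independent validation cohort from the same universe."""
        spec, *_ = strong_cohort
        from uridx import synthetic_data as sd
        vdis, _, vmeta, _ = sd.generate_cohort(sd.validation_spec(spec), seed=211,
                                               universe_seed=11)
        _, metrics = uridx.run_validation(strong_discovery, vdis, vmeta,
                                          algo="rf", seed=3)
        assert metrics.accuracy >= 0.90


class TestLoocv:
    def test_constant_stub_accuracy_closed_form(self):
        matrix, meta = separable_toy(n_per=5)
        stub = lambda: DummyClassifier(strategy="constant", constant="AA")
        metrics, preds = loocv(matrix, meta, panel=["PROT0"], algo=stub)
        assert (preds == "AA").all()
        assert metrics.accuracy == pytest.approx(5 / 10)

    def test_each_sample_predicted_exactly_once(self):
        matrix, meta = separable_toy(n_per=4)
        _, preds = loocv(matrix, meta, panel=["PROT0", "PROT1"], algo="nb")
        assert sorted(preds.index) == sorted(meta["sample_id"])
        assert not preds.index.has_duplicates

    def test_order_invariance(self):
        matrix, meta = separable_toy(n_per=4)
        perm = meta.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled = matrix.select_samples(perm["sample_id"].tolist())
        m1, p1 = loocv(matrix, meta, panel=["PROT0", "PROT1"], algo="rf", seed=2)
        m2, p2 = loocv(shuffled, perm, panel=["PROT0", "PROT1"], algo="rf", seed=2)
        assert (p1.sort_index() == p2.sort_index()).all()
        assert m1 == m2

    def test_minimum_size_enforced(self):
        matrix, meta = separable_toy(n_per=1)
        with pytest.raises(ValueError, match="at least 3"):
            loocv(matrix, meta, panel=["PROT0"], algo="nb")

    def test_single_class_fold_predicts_majority_with_warning(self):
        rng = np.random.default_rng(1)
        samples = ["a0", "c0", "c1", "c2"]
        meta = make_metadata(samples, ["AA", "CON", "CON", "CON"])
        m = make_matrix(rng.normal(5, 1, (2, 4)), stage="quantile", samples=samples)
        matrix = AbundanceMatrix(m.data, "log2_imputed", imputation_value=0.0)
        with pytest.warns(UserWarning, match="majority"):
            _, preds = loocv(matrix, meta, panel=["PROT0"], algo="nb")
        assert preds.loc["a0"] == "CON"


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], ["AA", "AA", "CON", "CON"])
        assert roc.auc == 1.0
        assert roc.sensitivity_at_youden == 1.0
        assert roc.specificity_at_youden == 1.0

    def test_all_equal_scores(self):
        roc = roc_auc([0.5, 0.5, 0.5, 0.5], ["AA", "AA", "CON", "CON"])
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n = int(rng.integers(6, 21))
            labels = ["AA" if rng.random() < 0.5 else "CON" for _ in range(n)]
            if len(set(labels)) < 2:
                continue
            scores = rng.choice(np.linspace(0, 1, 8), size=n)  # forces ties
            roc = roc_auc(scores, labels)
            assert roc.auc == pytest.approx(auc_pairwise_oracle(scores, labels),
                                            abs=1e-12)

    @given(st.lists(st.integers(-500, 500), min_size=4, max_size=12, unique=True))
    def test_invariant_under_monotone_transform(self, grid):
        scores = [g / 100.0 for g in grid]
        labels = ["AA", "CON"] * (len(scores) // 2) + ["AA"] * (len(scores) % 2)
        base = roc_auc(scores, labels).auc
        transformed = roc_auc(np.exp(0.5 * np.asarray(scores)) + 3, labels).auc
        assert base == pytest.approx(transformed, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], ["AA", "AA"])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        labels = ["AA"] * 6 + ["CON"] * 6
        roc = roc_auc(rng.normal(size=12), labels)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()


class TestConfusionFromRates:
    def test_validation_confusion_rf(self):
        """16/45 cohort, printed 81.2%/84.4% -> unique table (13,3,38,7)
        with accuracy 83.6%."""
        m = confusion_from_rates(16, 45, 81.2, 84.4)
        assert (m.tp, m.fn, m.tn, m.fp) == (13, 3, 38, 7)
        assert m.as_percentages()["accuracy"] == 83.6

    def test_validation_confusion_svm(self):
        m = confusion_from_rates(16, 45, 25.0, 97.8)
        assert (m.tp, m.fn, m.tn, m.fp) == (4, 12, 44, 1)
        assert m.as_percentages()["accuracy"] == 78.7

    def test_ambiguous_rates_rejected(self):
        with pytest.raises(ValueError, match="confusion tables"):
            confusion_from_rates(1000, 10, 50.0, 50.0, decimals=0)


class TestDecisionScores:
    @pytest.mark.parametrize("algo", ["rf", "svm", "nb"])
    def test_scores_separate_classes_on_toy(self, algo):
        matrix, meta = separable_toy()
        model = train_classifier(matrix, meta, ["PROT0", "PROT1"], algo=algo, seed=1)
        scores = decision_scores(model, matrix, meta)
        truth = meta.set_index("sample_id").loc[scores.index, "group"]
        assert roc_auc(scores.to_numpy(), truth.to_numpy()).auc == 1.0
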