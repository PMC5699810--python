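"""Agreement and safety statistics against brute-force tally oracles."""

import numpy as np
import pytest

from copdtriage.metrics import (
    MetricError,
    build_confusion,
    binary_metrics,
    collapse_to_attention,
    label_distributions,
    medical_attention_metrics,
    safety_summary,
    triage_metrics,
    ConfusionMatrix,
)
from copdtriage.panel import LabelMatrix


# ---------------------------------------------------------------------------
# Brute-force per-case tally oracle (independent of the matrix formulas)
# ---------------------------------------------------------------------------

def oracle_triage(pred, cons):
    n = len(pred)
    TC = sum(1 for p, c in zip(pred, cons) if p == c)
    TP = sum(1 for p, c in zip(pred, cons) if p == 4 and c == 4)
    FN = sum(1 for p, c in zip(pred, cons) if p != 4 and c == 4)
    FP = sum(1 for p, c in zip(pred, cons) if p == 4 and c != 4)
    TN = sum(1 for p, c in zip(pred, cons) if p != 4 and c != 4)
    LT = sum(1 for p, c in zip(pred, cons) if p < c)
    CG1 = sum(1 for p, c in zip(pred, cons) if abs(p - c) > 1)
    out = {
        "ACC": 100.0 * TC / n,
        "TPR": 100.0 * TP / (TP + FN) if TP + FN else None,
        "TNR": 100.0 * TN / (TN + FP) if TN + FP else None,
        "PPV": 100.0 * TP / (TP + FP) if TP + FP else None,
        "NPV": 100.0 * TN / (TN + FN) if TN + FN else None,
        "UTP": 100.0 * (1.0 - LT / n),
        "EG1": 100.0 * (CG1 / n),
    }
    return out


def oracle_attention(pred, cons):
    p2 = [1 if p >= 3 else 0 for p in pred]
    c2 = [1 if c >= 3 else 0 for c in cons]
    TP = sum(1 for p, c in zip(p2, c2) if p == 1 and c == 1)
    TN = sum(1 for p, c in zip(p2, c2) if p == 0 and c == 0)
    FP = sum(1 for p, c in zip(p2, c2) if p == 1 and c == 0)
    FN = sum(1 for p, c in zip(p2, c2) if p == 0 and c == 1)
    n = len(pred)
    return {
        "ACC": 100.0 * (TP + TN) / n,
        "TPR": 100.0 * TP / (TP + FN) if TP + FN else None,
        "TNR": 100.0 * TN / (TN + FP) if TN + FP else None,
        "PPV": 100.0 * TP / (TP + FP) if TP + FP else None,
        "NPV": 100.0 * TN / (TN + FN) if TN + FN else None,
    }


class TestBuildConfusion:
    def test_perfect_agreement_is_diagonal(self):
        cm = build_confusion([1, 2, 3, 4], [1, 2, 3, 4], K=4)
        assert np.array_equal(cm.counts, np.eye(4, dtype=int))

    def test_single_over_triage_above_diagonal(self):
        cm = build_confusion([4], [3], K=4)
        assert cm.counts[2, 3] == 1 and cm.n == 1

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(3)
        pred = rng.integers(1, 5, size=50)
        cons = rng.integers(1, 5, size=50)
        cm = build_confusion(pred, cons, K=4)
        for i in range(4):
            for j in range(4):
                tally = sum(1 for p, c in zip(pred, cons) if c == i + 1 and p == j + 1)
                assert cm.counts[i, j] == tally

    def test_length_mismatch_rejected(self):
        with pytest.raises(MetricError, match="alignment"):
            build_confusion([1, 2], [1], K=4)


class TestFormulaOracleEquivalence:
    def test_triage_and_attention_formulas_match_oracle_exactly(self):
        # >= 1000 random small label-vector pairs, exact float equality
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n = int(rng.integers(1, 51))
            pred = rng.integers(1, 5, size=n)
            cons = rng.integers(1, 5, size=n)
            m = triage_metrics(build_confusion(pred, cons, K=4))
            expected = oracle_triage(pred, cons)
            for key, val in expected.items():
                assert getattr(m, key) == val, (key, pred, cons)
            am = medical_attention_metrics(pred, cons)
            for key, val in oracle_attention(pred, cons).items():
                assert getattr(am, key) == val, (key, pred, cons)

    def test_partition_identity(self):
        # below-diagonal, above-diagonal and diagonal fractions partition 1;
        # below = 1 - UTP when both are taken as fractions
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            pred = rng.integers(1, 5, size=n)
            cons = rng.integers(1, 5, size=n)
            cm = build_confusion(pred, cons, K=4)
            m = triage_metrics(cm, percent=False)
            above = np.triu(cm.counts, k=1).sum() / cm.n
            assert (1.0 - m.UTP) + above + m.ACC == pytest.approx(1.0)

    def test_attention_collapse_preserves_n(self):
        rng = np.random.default_rng(11)
        pred = rng.integers(1, 5, size=73)
        cons = rng.integers(1, 5, size=73)
        am = medical_attention_metrics(pred, cons)
        assert am.n == 73


class TestWorkedMatrices:
    def test_strong_classifier_style_matrix(self):
        # 101 cases, 89 on the diagonal, 12 off-diagonal of which 4 below,
        # no error greater than one category
        counts = np.array([
            [6, 0, 0, 0],
            [0, 8, 7, 0],
            [0, 0, 49, 1],
            [0, 0, 4, 26],
        ])
        m = triage_metrics(ConfusionMatrix(counts, (1, 2, 3, 4)))
        assert round(m.ACC, 1) == 88.1
        assert round(m.UTP, 1) == 96.0
        assert round(m.EG1, 1) == 0.0
        s = safety_summary(ConfusionMatrix(counts, (1, 2, 3, 4)))
        assert s.under_triage_rate == pytest.approx(100 * 4 / 101)
        assert s.under_triage_share == pytest.approx(100 * 4 / 12)

    def test_er_sensitivity_with_30_percent_missed(self):
        # 30 consensus-ER cases of which 9 under-triaged to category 3
        counts = np.zeros((4, 4), dtype=int)
        counts[3, 3] = 21
        counts[3, 2] = 9
        counts[0, 0] = 10
        m = triage_metrics(ConfusionMatrix(counts, (1, 2, 3, 4)))
        assert m.TPR == pytest.approx(70.0)

    def test_attention_miss_eleven_of_eighty(self):
        # 80 consensus-attention cases, 11 predicted below category 3
        pred = [3] * 69 + [2] * 11 + [1] * 21
        cons = [3] * 80 + [1] * 21
        am = medical_attention_metrics(pred, cons)
        assert am.TPR == pytest.approx(100 * 69 / 80)  # 86.25, printed as 86.3

    def test_diagonal_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.diag([10, 10, 10, 10]), (1, 2, 3, 4))
        m = triage_metrics(cm)
        assert (m.ACC, m.UTP, m.EG1) == (100.0, 100.0, 0.0)
        assert (m.TPR, m.TNR, m.PPV, m.NPV) == (100.0, 100.0, 100.0, 100.0)
        s = safety_summary(cm)
        assert s.under_triage_rate == 0.0 and s.over_triage_rate == 0.0
        assert s.under_triage_share is None  # no misclassifications at all


class TestUndefinedMetrics:
    def test_no_positive_class_leaves_tpr_undefined(self):
        pred = [1, 2, 2, 1]
        cons = [1, 1, 2, 2]
        am = medical_attention_metrics(pred, cons)
        assert am.TPR is None
        assert am.TNR is not None

    def test_never_coerced_to_zero_or_hundred(self):
        cm = ConfusionMatrix(np.array([[5, 0], [0, 0]]), (1, 2))
        bm = binary_metrics(cm)
        assert bm.TPR is None and bm.PPV is None
        assert bm.TNR == 100.0


class TestLabelDistributions:
    def test_identical_raters_have_zero_sd_and_no_flags(self):
        records = [
            dict(rater_id=r, case_id=f"c{i}", triage=t, exacerbation=0,
                 triage_confidence=50.0, exacerbation_confidence=50.0)
            for r in "abc"
            for i, t in enumerate([1, 2, 3, 4, 4])
        ]
        d = label_distributions(LabelMatrix.from_records(records))
        assert (d.triage_sd < 1e-12).all()
        assert d.outliers == {}

    def test_constructed_er_outlier_is_flagged(self):
        rng = np.random.default_rng(0)
        records = []
        for r in range(8):
            for i in range(60):
                records.append(dict(
                    rater_id=f"r{r}", case_id=f"c{i}",
                    triage=int(rng.integers(1, 5)), exacerbation=0,
                    triage_confidence=50.0, exacerbation_confidence=50.0,
                ))
        for i in range(60):  # one rater assigns 100% ER
            records.append(dict(rater_id="extreme", case_id=f"c{i}", triage=4,
                                exacerbation=0, triage_confidence=50.0,
                                exacerbation_confidence=50.0))
        d = label_distributions(LabelMatrix.from_records(records))
        assert any(task == "triage" and cat == 4
                   for task, cat in d.outliers.get("extreme", []))

    def test_shares_sum_to_one(self, small_labels):
        d = label_distributions(small_labels)
        np.testing.assert_allclose(d.triage_shares.sum(axis=1), 1.0)
        np.testing.assert_allclose(d.exacerbation_shares.sum(axis=1), 1.0)
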