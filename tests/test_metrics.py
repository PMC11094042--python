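"""Score banding, confusion construction and metric formulas.

Cross-checks: random confusion tables against scikit-learn on reconstructed
label arrays, AUC against an O(n^2) pair-counting oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from missbench.io import ClinicalLabel, ScoreClass
from missbench.metrics import (
    AmbiguousPolicy,
    ConfusionTable,
    ThresholdScheme,
    auc_roc,
    build_confusion,
    classify_score,
    compute_metrics,
)

B, P = ClinicalLabel.BENIGN, ClinicalLabel.PATHOGENIC
LB, AM, LP = (
    ScoreClass.LIKELY_BENIGN,
    ScoreClass.AMBIGUOUS,
    ScoreClass.LIKELY_PATHOGENIC,
)


class TestClassifyScore:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, LB),
            (0.08, LB),
            (0.339, LB),
            (0.340, AM),  # lower boundary is ambiguous
            (0.35, AM),
            (0.5637, AM),  # just under the pathogenic cutoff
            (0.564, LP),  # upper boundary is pathogenic
            (0.87, LP),
            (1.0, LP),
        ],
    )
    def test_band_assignment(self, score, expected):
        assert classify_score(score) is expected

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_partition_is_total(self, score):
        assert classify_score(score) in (LB, AM, LP)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_score(1.01)

    def test_disordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ThresholdScheme(0.6, 0.3)


CFTR2_PAIRS = (
    [(P, LP)] * 98 + [(P, AM)] * 3 + [(P, LB)] * 1
    + [(B, LP)] * 3 + [(B, AM)] * 1 + [(B, LB)] * 13
)


class TestBuildConfusion:
    def test_ambiguous_as_error(self):
        ct = build_confusion(CFTR2_PAIRS, AmbiguousPolicy.AS_ERROR)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (98, 4, 4, 13)
        assert ct.n_evaluated == len(CFTR2_PAIRS)

    def test_ambiguous_excluded(self):
        ct = build_confusion(CFTR2_PAIRS, AmbiguousPolicy.EXCLUDED)
        assert (ct.tp, ct.fn, ct.fp, ct.tn) == (98, 1, 3, 13)
        assert ct.n_ambig_on_pathogenic_label == 3
        assert ct.n_ambig_on_benign_label == 1
        assert ct.n_total == len(CFTR2_PAIRS)

    def test_empty_input(self):
        ct = build_confusion([])
        assert (ct.tp, ct.fp, ct.tn, ct.fn) == (0, 0, 0, 0)

    @given(
        st.lists(
            st.tuples(st.sampled_from([B, P]), st.sampled_from([LB, AM, LP])),
            max_size=200,
        )
    )
    def test_totals_account_for_every_pair(self, pairs):
        for policy in AmbiguousPolicy:
            ct = build_confusion(pairs, policy)
            assert ct.n_total == len(pairs)


class TestComputeMetrics:
    def test_reconstructed_benchmark_row(self):
        values = compute_metrics(ConfusionTable(tp=98, fp=4, tn=13, fn=4))
        assert values.ppv == pytest.approx(0.961, abs=5e-4)
        assert values.tpr == pytest.approx(0.961, abs=5e-4)
        assert values.f1 == pytest.approx(0.961, abs=5e-4)
        assert values.mcc == pytest.approx(0.725, abs=5e-4)
        assert not values.degenerate

    def test_perfect_classifier(self):
        values = compute_metrics(ConfusionTable(tp=1, tn=1))
        assert (values.ppv, values.tpr, values.f1, values.mcc) == (1, 1, 1, 1)

    def test_all_wrong_classifier(self):
        # every marginal is 1, so the MCC formula evaluates to -1 outright
        values = compute_metrics(ConfusionTable(fp=1, fn=1))
        assert (values.ppv, values.tpr, values.f1, values.mcc) == (0, 0, 0, -1)
        assert "f1" in values.degenerate and "mcc" not in values.degenerate

    def test_single_class_input_flags_mcc(self):
        values = compute_metrics(ConfusionTable(tp=3, fn=2))
        assert values.mcc == 0.0
        assert "mcc" in values.degenerate

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200),
            st.integers(0, 200), st.integers(0, 200),
        )
    )
    def test_against_sklearn_on_reconstructed_labels(self, counts):
        tp, fp, tn, fn = counts
        ct = ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)
        values = compute_metrics(ct)
        assert -1.0 <= values.mcc <= 1.0
        if ct.n_evaluated == 0:
            return
        from sklearn.metrics import (
            f1_score,
            matthews_corrcoef,
            precision_score,
            recall_score,
        )

        y_true = [1] * (tp + fn) + [0] * (fp + tn)
        y_pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
        if tp + fp > 0:
            assert values.ppv == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0)
            )
        if tp + fn > 0:
            assert values.tpr == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0)
            )
        if values.ppv + values.tpr > 0:
            assert values.f1 == pytest.approx(f1_score(y_true, y_pred))
        if "mcc" not in values.degenerate:
            assert values.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    def test_label_permutation_mcc_near_zero(self):
        rng = np.random.default_rng(99)
        n = 40_000
        y_true = rng.integers(0, 2, n)
        y_pred = rng.integers(0, 2, n)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        values = compute_metrics(ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn))
        assert abs(values.mcc) <= 3 / math.sqrt(n)


def auc_pair_oracle(scores, labels):
    """O(n^2) pair counting: wins + half ties over pathogenic x benign pairs."""
    pos = [s for s, l in zip(scores, labels) if l is P]
    neg = [s for s, l in zip(scores, labels) if l is B]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRoc:
    def test_perfect_separation(self):
        assert auc_roc([0.9, 0.8, 0.2, 0.1], [P, P, B, B]) == 1.0

    def test_all_tied_is_half(self):
        assert auc_roc([0.5, 0.5], [P, B]) == 0.5

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="single class"):
            auc_roc([0.1, 0.9], [P, P])

    def test_matches_pair_counting_oracle_exactly(self):
        rng = np.random.default_rng(7)
        # discretized scores force ties, exercising the midrank path
        scores = np.round(rng.random(200), 1)
        labels = [P if v else B for v in rng.integers(0, 2, 200)]
        if P not in labels:
            labels[0] = P
        if B not in labels:
            labels[1] = B
        assert auc_roc(scores, labels) == pytest.approx(
            auc_pair_oracle(list(scores), labels), abs=1e-12
        )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        scores = rng.random(150)
        y = rng.integers(0, 2, 150)
        y[0], y[1] = 0, 1
        labels = [P if v else B for v in y]
        assert auc_roc(scores, labels) == pytest.approx(roc_auc_score(y, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.random(80)
        y = rng.integers(0, 2, 80)
        y[0], y[1] = 0, 1
        labels = [P if v else B for v in y]
        assert auc_roc(scores, labels) == auc_roc(scores**3, labels)

    def test_flipping_labels_complements_auc(self):
        rng = np.random.default_rng(5)
        scores = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        labels = [P if v else B for v in y]
        flipped = [B if l is P else P for l in labels]
        assert auc_roc(scores, labels) + auc_roc(scores, flipped) == pytest.approx(1.0)
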