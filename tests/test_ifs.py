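import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from scdiscrim import (
    ConfusionCounts,
    ExpressionMatrix,
    SvmClassifier,
    confusion_to_metrics,
    loocv_evaluate,
    run_ifs,
    select_peak,
)
from scdiscrim.ifs import IfsCurve, PerformanceMetrics, loocv_predict
from scdiscrim.mrmr import RankedTranscripts


def _counts_to_vectors(c: ConfusionCounts):
    y = [1] * (c.tp + c.fn) + [0] * (c.tn + c.fp)
    pred = [1] * c.tp + [0] * c.fn + [0] * c.tn + [1] * c.fp
    return y, pred


class TestMetrics:
    def test_reference_cohort_counts(self):
        """263/9/150/10 on the 272/160 cohort give ACC .956, MCC .906."""
        m = confusion_to_metrics(ConfusionCounts(tp=263, fn=9, tn=150, fp=10))
        assert round(m.sn, 3) == 0.967
        assert round(m.sp, 3) == 0.938
        assert round(m.acc, 3) == 0.956
        assert round(m.mcc, 3) == 0.906

    def test_perfect_classifier(self):
        m = confusion_to_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_completely_wrong_classifier_has_mcc_minus_one(self):
        m = confusion_to_metrics(ConfusionCounts(tp=0, tn=0, fp=5, fn=5))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_zero_denominator_mcc_convention(self):
        # every cell predicted negative with only positives present:
        # (TP+FP) = 0 makes the denominator vanish -> MCC is 0 by convention
        m = confusion_to_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=5))
        assert m.acc == 0.0
        assert m.mcc == 0.0

    def test_undefined_sn_is_nan_not_zero(self):
        m = confusion_to_metrics(ConfusionCounts(tp=0, fn=0, tn=4, fp=1))
        assert math.isnan(m.sn)
        assert m.sp == pytest.approx(0.8)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_agrees_with_independent_formulas_on_random_counts(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            m = confusion_to_metrics(c)
            y, pred = _counts_to_vectors(c)
            assert m.acc == pytest.approx(np.mean(np.array(y) == np.array(pred)))
            if len(set(y)) > 1 or len(set(pred)) > 1:
                assert m.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)

    def test_label_swap_exchanges_sn_sp_and_keeps_mcc(self):
        c = ConfusionCounts(tp=8, tn=3, fp=2, fn=1)
        swapped = ConfusionCounts(tp=c.tn, tn=c.tp, fp=c.fn, fn=c.fp)
        m, ms = confusion_to_metrics(c), confusion_to_metrics(swapped)
        assert m.sn == pytest.approx(ms.sp)
        assert m.sp == pytest.approx(ms.sn)
        assert m.mcc == pytest.approx(ms.mcc)


def _separable_matrix(n_per_class=10, n_features=4, gap=50.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(gap, 1.0, size=(n_per_class, n_features))
    neg = rng.normal(0.0, 1.0, size=(n_per_class, n_features))
    values = np.vstack([pos, neg]).T  # transcripts x cells
    values = np.abs(values)
    n = 2 * n_per_class
    return ExpressionMatrix(
        values=values,
        transcript_ids=[f"t{i}" for i in range(n_features)],
        gene_symbols=[f"g{i}" for i in range(n_features)],
        cell_ids=[f"c{j}" for j in range(n)],
        labels=np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)],
    )


class TestLoocv:
    def test_separated_clusters_classified_perfectly(self):
        m = _separable_matrix()
        c = loocv_evaluate(m)
        assert (c.tp, c.tn, c.fp, c.fn) == (10, 10, 0, 0)

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(1, 5, size=(30, 6))
        y = np.r_[np.ones(15, int), np.zeros(15, int)]
        c1 = loocv_evaluate(x, labels=y)
        c2 = loocv_evaluate(x, labels=y)
        assert c1 == c2

    def test_count_conservation(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(1, 5, size=(24, 5))
        y = np.r_[np.ones(14, int), np.zeros(10, int)]
        c = loocv_evaluate(x, labels=y)
        assert c.tp + c.fn == 14
        assert c.tn + c.fp == 10

    def test_singleton_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            loocv_predict(x, np.array([1, 0, 0, 0, 0]), SvmClassifier())


def _metrics(mcc):
    return PerformanceMetrics(sn=1, sp=1, acc=1, mcc=mcc)


def _point(k, mcc):
    return (k, _metrics(mcc), ConfusionCounts(1, 1, 0, 0))


class TestPeakSelection:
    def test_tie_goes_to_smallest_k(self):
        assert select_peak([_point(1, 0.5), _point(2, 0.9), _point(3, 0.9)]) == 2

    def test_strictly_increasing_selects_last(self):
        assert select_peak([_point(k, 0.1 * k) for k in range(1, 6)]) == 5

    def test_all_equal_selects_first(self):
        assert select_peak([_point(k, 0.7) for k in range(1, 4)]) == 1

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_peak([])


class TestRunIfs:
    def _ranked_planted(self, seed=0):
        """Transcripts 0-4 informative, 5-19 pure noise."""
        rng = np.random.default_rng(seed)
        n_pos, n_neg = 25, 20
        n = n_pos + n_neg
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        values = np.abs(rng.normal(5, 1, size=(20, n)))
        values[:5, :n_pos] += 6.0
        m = ExpressionMatrix(
            values=values,
            transcript_ids=[f"t{i}" for i in range(20)],
            gene_symbols=[f"g{i}" for i in range(20)],
            cell_ids=[f"c{j}" for j in range(n)],
            labels=labels,
        )
        ranks = RankedTranscripts(
            order=list(range(20)), scores=[0.0] * 20, relevance=[0.0] * 20
        )
        return m, ranks

    def test_curve_improves_with_informative_prefix(self):
        m, ranks = self._ranked_planted()
        curve = run_ifs(m, ranks, k_max=15)
        assert curve.metrics_at(5).mcc >= curve.metrics_at(1).mcc
        assert curve.peak_k <= 10

    def test_counts_conserved_at_every_k(self):
        m, ranks = self._ranked_planted(seed=3)
        curve = run_ifs(m, ranks, k_max=6)
        for _, _, c in curve.points:
            assert c.tp + c.fn == m.n_pos
            assert c.tn + c.fp == m.n_neg

    def test_k_max_one_gives_single_point_curve(self):
        m, ranks = self._ranked_planted()
        curve = run_ifs(m, ranks, k_max=1)
        assert curve.ks == [1]
        assert curve.peak_k == 1

    def test_k_max_beyond_ranking_rejected(self):
        m, ranks = self._ranked_planted()
        with pytest.raises(ValueError):
            run_ifs(m, ranks, k_max=21)

    def test_mcc_bounds_hold_along_curve(self):
        m, ranks = self._ranked_planted(seed=9)
        curve = run_ifs(m, ranks, k_max=8)
        for _, metrics, counts in curve.points:
            assert -1.0 - 1e-12 <= metrics.mcc <= 1.0 + 1e-12
            if metrics.mcc == 1.0:
                assert counts.fp == 0 and counts.fn == 0
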