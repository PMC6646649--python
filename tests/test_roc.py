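"""Pooled ROC, stand-alone CAD scoring, operating points and the
theoretical-reader counterfactual."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from cadreader.io import CadMark
from cadreader.metrics import UndefinedMetricError
from cadreader.roc import (aggregate_score, auc_mann_whitney, pct_change_auc,
                           pooled_roc, reader_operating_point,
                           roc_from_scores, standalone_case_score,
                           standalone_roc, theoretical_matrix,
                           theoretical_transform)
from cadreader.simulate import default_config, generate_study

from conftest import hit_mark, matrix_from_arrays, mk_cancer


def _pair_enumeration_auc(scores, truth):
    """Independent O(n^2) oracle: (concordant + 0.5 ties) / (n1 n0)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    pos, neg = s[y], s[~y]
    num = 0.0
    for a in pos:
        for b in neg:
            num += 1.0 if a > b else (0.5 if a == b else 0.0)
    return num / (pos.size * neg.size)


class TestAggregateScore:
    def test_sums_binary_recalls(self):
        pre = np.array([[1], [1], [0], [1], [0], [0], [1]])
        m = matrix_from_arrays(pre, pre, [True])
        assert aggregate_score(m, "c000", "pre") == 4

    def test_zero_when_no_reader_recalls(self):
        z = np.zeros((3, 2), dtype=int)
        m = matrix_from_arrays(z, z, [True, False])
        assert aggregate_score(m, "c000", "pre") == 0

    def test_equals_brute_force_sum(self, sim_matrix):
        rng = np.random.default_rng(0)
        ids = [c.case_id for c in sim_matrix.cases]
        for case_id in rng.choice(ids, size=15, replace=False):
            for phase in ("pre", "post"):
                want = sum(sim_matrix.decision(r, case_id, phase).recall
                           for r in sim_matrix.readers)
                assert aggregate_score(sim_matrix, case_id, phase) == want


class TestRocFromScores:
    def test_perfect_separation(self):
        curve = roc_from_scores([2, 3, 0, 1], [True, True, False, False])
        assert curve.auc == pytest.approx(1.0)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_all_tied_scores_give_diagonal_chord(self):
        curve = roc_from_scores([5, 5, 5, 5], [True, False, True, False])
        assert curve.auc == pytest.approx(0.5)
        assert len(curve.fpr) == 2  # sentinel point plus the single score

    def test_curve_monotone_and_anchored(self, sim_results):
        for curve in (sim_results.roc_pre, sim_results.roc_post,
                      sim_results.roc_standalone):
            assert (np.diff(curve.fpr) >= 0).all()
            assert (np.diff(curve.tpr) >= 0).all()
            assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
            assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
            assert curve.auc == pytest.approx(
                np.trapezoid(curve.tpr, curve.fpr))

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_from_scores([1, 2], [True, True])

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_equals_rank_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 200))
        scores = rng.integers(0, 8, size=n).astype(float)
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        curve = roc_from_scores(scores, truth)
        assert curve.auc == pytest.approx(
            _pair_enumeration_auc(scores, truth), abs=1e-12)
        assert curve.auc == pytest.approx(auc_mann_whitney(scores, truth),
                                          abs=1e-12)
        assert curve.auc == pytest.approx(roc_auc_score(truth, scores),
                                          abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 8, size=60).astype(float)
        truth = rng.random(60) < 0.6
        a = roc_from_scores(scores, truth).auc
        b = roc_from_scores(np.exp(scores / 3.0) + 5.0, truth).auc
        assert a == pytest.approx(b, abs=1e-12)


class TestStandaloneScore:
    def test_max_score_rules(self):
        case = mk_cancer("c1")
        marks = [hit_mark(case, 75.0),
                 CadMark("c1", "LMLO", (0, 0, 5, 5), 40.0)]
        assert standalone_case_score(marks) == 75.0
        assert standalone_case_score([]) == 0.0
        assert standalone_case_score(marks[1:]) == 40.0

    def test_standalone_roc_uses_max_mark_scores(self, sim_matrix):
        curve = standalone_roc(sim_matrix)
        scores = {c.case_id: standalone_case_score(
            sim_matrix.marks_for(c.case_id)) for c in sim_matrix.cases}
        truth = {c.case_id: c.truth_label for c in sim_matrix.cases}
        assert curve.auc == pytest.approx(
            roc_from_scores(scores, truth).auc)


class TestOperatingPoints:
    def test_perfect_and_recall_everything(self):
        eye = np.array([[1, 1, 0]])
        m = matrix_from_arrays(eye, eye, [True, True, False])
        op = reader_operating_point(m, "r0", "pre")
        assert (op.fpr, op.tpr) == (0.0, 1.0)
        ones = np.ones((1, 3), dtype=int)
        m1 = matrix_from_arrays(ones, ones, [True, True, False])
        op1 = reader_operating_point(m1, "r0", "pre")
        assert (op1.fpr, op1.tpr) == (1.0, 1.0)

    def test_consistent_with_metrics_module(self, sim_matrix):
        from cadreader.metrics import reader_cdr
        for r in sim_matrix.readers:
            op = reader_operating_point(sim_matrix, r, "post")
            assert op.tpr == pytest.approx(
                reader_cdr(sim_matrix, r, "post"))
            fp = sum(sim_matrix.decision(r, c.case_id, "post").recall
                     for c in sim_matrix.normal_cases())
            assert op.fpr == pytest.approx(
                fp / len(sim_matrix.normal_cases()))


class TestTheoreticalReader:
    def test_flagged_miss_converts_and_unflagged_recall_survives(
            self, tiny_matrix):
        repl = theoretical_transform(tiny_matrix, "rB")
        # rB missed c1 unaided; c1 is flagged -> converted to recall
        assert repl[("rB", "c1")].recall == 1
        # converted cancer recall claims the truth-hitting mark location
        assert repl[("rB", "c1")].claimed_laterality == "L"
        assert repl[("rB", "c1")].claimed_quadrant == "UO"
        # rB's unaided recall on c2 is never removed
        assert repl[("rB", "c2")].recall == 1
        # flagged normal converts too (rule applies to both classes)
        repl_a = theoretical_transform(tiny_matrix, "rA")
        assert repl_a[("rA", "n1")].recall == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tpr_and_fpr_never_decrease(self, seed):
        m = generate_study(default_config(), seed=seed)
        theo = theoretical_matrix(m)
        for r in m.readers:
            base = reader_operating_point(m, r, "pre", localization=False)
            after = reader_operating_point(theo, r, "post",
                                           localization=False)
            assert after.tpr >= base.tpr
            assert after.fpr >= base.fpr

    def test_adding_truth_hit_to_missed_cancer_never_lowers_tpr(self):
        pre = np.array([[1, 0, 0, 0]])
        truth = [True, True, True, False]
        m = matrix_from_arrays(pre, pre, truth,
                               hit_flags=[False, False, False, False])
        base = reader_operating_point(theoretical_matrix(m), "r0", "post",
                                      localization=False)
        flagged = matrix_from_arrays(pre, pre, truth,
                                     hit_flags=[False, True, False, False])
        after = reader_operating_point(theoretical_matrix(flagged), "r0",
                                       "post", localization=False)
        assert after.tpr >= base.tpr


class TestPctChangeAuc:
    def test_published_auc_pair_gives_7_2_percent(self):
        from cadreader._format import round_half_away
        change = pct_change_auc(0.7599, 0.8148)
        assert change == pytest.approx(7.2247, abs=1e-3)
        assert round_half_away(change, 1) == 7.2

    def test_identity_and_arithmetic(self):
        assert pct_change_auc(0.6, 0.6) == 0.0
        assert pct_change_auc(0.5, 0.55) == pytest.approx(10.0)
        with pytest.raises(UndefinedMetricError):
            pct_change_auc(0.0, 0.5)


class TestPooledVariants:
    def test_localization_aware_pooled_score_never_higher(self, sim_matrix):
        raw = pooled_roc(sim_matrix, "pre", localization=False)
        loc = pooled_roc(sim_matrix, "pre", localization=True)
        # mislocalized recalls are discounted on cancers only, so the
        # localization-aware aggregate scores on cancers can only drop
        from cadreader.roc import aggregate_score
        for c in sim_matrix.cancer_cases():
            assert aggregate_score(sim_matrix, c.case_id, "pre", True) <= \
                aggregate_score(sim_matrix, c.case_id, "pre", False)
        assert 0.0 <= loc.auc <= 1.0 and 0.0 <= raw.auc <= 1.0
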