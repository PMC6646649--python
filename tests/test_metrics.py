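"""Per-reader detection metrics, conversion accounting and group
summaries."""

import numpy as np
import pytest

from cadreader import datasets
from cadreader.metrics import (UndefinedMetricError, conversion_accounting,
                               delta_and_pct_change,
                               density_stratified_deltas, fp_recall_metrics,
                               group_summary, is_true_positive, leading_class,
                               reader_cdr)

from conftest import matrix_from_arrays, mk_cancer, mk_dec


class TestTruePositiveRule:
    def test_wrong_quadrant_is_false_negative(self):
        case = mk_cancer("c1", quad="UO")
        d = mk_dec("r", case, "pre", 1, correct=False)
        assert is_true_positive(case, d) == 0

    def test_no_recall_is_false_negative(self):
        case = mk_cancer("c1")
        assert is_true_positive(case, mk_dec("r", case, "pre", 0)) == 0

    def test_matching_location_is_true_positive(self):
        case = mk_cancer("c1")
        assert is_true_positive(case, mk_dec("r", case, "pre", 1)) == 1

    def test_location_agnostic_mode_counts_any_recall(self):
        case = mk_cancer("c1")
        d = mk_dec("r", case, "pre", 1, correct=False)
        assert is_true_positive(case, d, localization=False) == 1


class TestReaderCdr:
    def test_saturation_and_zero(self):
        ones = np.ones((1, 4), dtype=int)
        m = matrix_from_arrays(ones, ones, [True, True, True, False])
        assert reader_cdr(m, "r0", "pre") == 1.0
        zeros = np.zeros((1, 4), dtype=int)
        m0 = matrix_from_arrays(zeros, zeros, [True, True, True, False])
        assert reader_cdr(m0, "r0", "pre") == 0.0

    def test_38_of_90_correct_recalls(self):
        pre = np.zeros((1, 91), dtype=int)
        pre[0, :38] = 1
        m = matrix_from_arrays(pre, pre, [True] * 90 + [False])
        assert reader_cdr(m, "r0", "pre") == pytest.approx(38 / 90)

    def test_undefined_without_cancer_cases(self):
        ones = np.ones((1, 2), dtype=int)
        m = matrix_from_arrays(ones, ones, [False, False])
        with pytest.raises(UndefinedMetricError):
            reader_cdr(m, "r0", "pre")


class TestDeltaAndPctChange:
    @pytest.mark.parametrize("pre, post, delta, pct", [
        (0.25, 0.41, 16.0, 64.0),
        (0.42, 0.68, 26.0, 61.90476),
        (0.5, 0.5, 0.0, 0.0),
    ])
    def test_arithmetic(self, pre, post, delta, pct):
        d, p = delta_and_pct_change(pre, post)
        assert d == pytest.approx(delta, abs=1e-9)
        assert p == pytest.approx(pct, abs=1e-4)

    def test_zero_baseline_reports_absent_with_warning(self):
        with pytest.warns(UserWarning):
            d, p = delta_and_pct_change(0.0, 0.3)
        assert d == pytest.approx(30.0)
        assert p is None


class TestFpRecallMetrics:
    def test_printed_first_reader_row_conserves(self):
        # 7 unaided FP recalls, 4 conversions, 3 reversals over 32 normals
        pre = np.zeros((1, 33), dtype=int)
        post = np.zeros((1, 33), dtype=int)
        pre[0, 1:8] = 1          # case 0 is the obligatory cancer
        post[0, 1:5] = 1         # 3 of the 7 reversed
        post[0, 8:12] = 1        # 4 new conversions
        truth = [True] + [False] * 32
        m = matrix_from_arrays(pre, post, truth)
        fp_pre, inc, red, fp_post, rate = fp_recall_metrics(m, "r0")
        assert (fp_pre, inc, red, fp_post) == (7, 4, 3, 8)
        assert fp_post == fp_pre + inc - red
        assert rate == pytest.approx(100 * 1 / 32)

    def test_no_change_and_saturation(self):
        k = np.zeros((1, 6), dtype=int)
        k[0, 1:4] = 1
        truth = [True] + [False] * 5
        m = matrix_from_arrays(k, k, truth)
        assert fp_recall_metrics(m, "r0") == (3, 0, 0, 3, 0.0)
        ones = np.ones((1, 6), dtype=int)
        m1 = matrix_from_arrays(ones, ones, truth)
        assert fp_recall_metrics(m1, "r0") == (5, 0, 0, 5, 0.0)

    def test_undefined_without_normals(self):
        ones = np.ones((1, 2), dtype=int)
        m = matrix_from_arrays(ones, ones, [True, True])
        with pytest.raises(UndefinedMetricError):
            fp_recall_metrics(m, "r0")


class TestLeadingClass:
    def test_rules(self):
        assert leading_class(("microcalcifications",)) == "calc"
        assert leading_class(("mass", "microcalcifications")) == "mass"
        assert leading_class(("microcalcifications", "asymmetry")) == "calc"
        assert leading_class(("focal_asymmetry",)) == "mass"
        with pytest.raises(UndefinedMetricError):
            leading_class(())

    def test_published_lesion_mix_splits_17_calc_73_mass(self):
        calc = sum(w for comps, w in datasets.LESION_MIX
                   if leading_class(comps) == "calc")
        mass = sum(w for comps, w in datasets.LESION_MIX
                   if leading_class(comps) == "mass")
        assert (calc, mass) == (17, 73)


class TestConversionAccounting:
    def test_printed_first_reader_calc_row(self):
        # 17 calc cancers: 8 recalled unaided, 6 converted on a flag,
        # 3 flags ignored (all 17 cases carry a truth-hitting mark)
        pre = np.zeros((1, 18), dtype=int)
        post = np.zeros((1, 18), dtype=int)
        pre[0, :8] = 1
        post[0, :14] = 1
        truth = [True] * 17 + [False]
        m = matrix_from_arrays(pre, post, truth,
                               hit_flags=[True] * 17 + [False],
                               classes=["calc"] * 17 + [None])
        assert conversion_accounting(m, "r0", "calc") == (8, 6, 3)

    def test_recall_everything_leaves_no_headroom(self):
        ones = np.ones((1, 5), dtype=int)
        m = matrix_from_arrays(ones, ones, [True] * 4 + [False],
                               hit_flags=[True] * 5,
                               classes=["mass"] * 4 + [None])
        assert conversion_accounting(m, "r0", "mass") == (4, 0, 0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            C = 12
            truth = [True] * 8 + [False] * 4
            classes = [rng.choice(["calc", "mass"]) if t else None
                       for t in truth]
            hits = [bool(rng.integers(2)) for _ in truth]
            pre = rng.integers(0, 2, (2, C))
            post = rng.integers(0, 2, (2, C))
            m = matrix_from_arrays(pre, post, truth, hit_flags=hits,
                                   classes=classes)
            for i, r in enumerate(("r0", "r1")):
                for cls in ("calc", "mass"):
                    want = [0, 0, 0]
                    for j in range(C):
                        if not truth[j] or classes[j] != cls:
                            continue
                        want[0] += pre[i, j]
                        want[1] += int(pre[i, j] == 0 and post[i, j] == 1
                                       and hits[j])
                        want[2] += int(pre[i, j] == 0 and post[i, j] == 0
                                       and hits[j])
                    assert conversion_accounting(m, r, cls) == tuple(want)

    def test_accounting_partition_of_pre_misses(self, sim_matrix):
        """additional + ignored + unflagged misses = unaided misses."""
        for r in sim_matrix.readers:
            for cls in ("calc", "mass"):
                _, additional, ignored = conversion_accounting(
                    sim_matrix, r, cls)
                misses = misses_unflagged = 0
                for c in sim_matrix.cancer_cases():
                    if leading_class(c.lesion_components) != cls:
                        continue
                    if sim_matrix.decision(r, c.case_id, "pre").recall:
                        continue
                    misses += 1
                    if not sim_matrix.truth_hitting_marks(c.case_id):
                        misses_unflagged += 1
                # flagged misses split into converted vs ignored
                assert additional + ignored == misses - misses_unflagged


class TestGroupSummary:
    def test_printed_cdr_column_mean(self):
        g = group_summary(datasets.CDR_PRE_PCT)
        assert g.mean == pytest.approx(50.714285, abs=1e-4)
        assert (g.min, g.max) == (25, 71)

    def test_printed_additional_mass_column_mean(self):
        g = group_summary(datasets.MASS_ADDITIONAL)
        assert g.mean == pytest.approx(6.42857, abs=1e-4)

    def test_single_reader_collapses(self):
        g = group_summary([0.37])
        assert g.mean == g.min == g.max == 0.37

    def test_order_invariance(self):
        vals = [3.0, 1.0, 7.0, 5.0]
        assert group_summary(vals) == group_summary(vals[::-1])


class TestDensityStrata:
    def test_no_change_gives_zero_deltas(self):
        pre = np.array([[1, 0, 1, 0, 1, 0]])
        truth = [True] * 5 + [False]
        m = matrix_from_arrays(pre, pre, truth,
                               densities=[1, 2, 2, 3, 3, 2])
        strata = density_stratified_deltas(m)
        assert set(strata) == {1, 2, 3}
        assert all(v == [0.0] for v in strata.values())

    def test_stratum_deltas_equal_subset_recomputation(self, sim_matrix):
        strata = density_stratified_deltas(sim_matrix)
        for density, deltas in strata.items():
            pool = [c for c in sim_matrix.cancer_cases()
                    if c.density == density]
            for i, r in enumerate(sim_matrix.readers):
                pre = reader_cdr(sim_matrix, r, "pre", cases=pool)
                post = reader_cdr(sim_matrix, r, "post", cases=pool)
                assert deltas[i] == pytest.approx(100 * (post - pre))

    def test_stratum_tp_counts_sum_to_overall(self, sim_matrix):
        from cadreader.metrics import is_true_positive
        for r in sim_matrix.readers:
            for phase in ("pre", "post"):
                total = sum(
                    is_true_positive(c, sim_matrix.decision(r, c.case_id,
                                                            phase))
                    for c in sim_matrix.cancer_cases())
                by_density = sum(
                    is_true_positive(c, sim_matrix.decision(r, c.case_id,
                                                            phase))
                    for d in (1, 2, 3, 4)
                    for c in sim_matrix.cancer_cases() if c.density == d)
                assert total == by_density
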