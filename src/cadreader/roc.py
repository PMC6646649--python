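"""Pooled readers-as-a-group ROC, stand-alone CAD ROC, per-reader
operating points and the "theoretical reader" counterfactual.

A binary recall per reader cannot yield a per-reader ROC, but summing
the seven binary recalls per case gives an ordinal aggregate score in
[0, R] that supports a group ROC: sweep a threshold t from above the
maximum score down to the minimum, recall iff score >= t, one operating
point per threshold, AUC by the trapezoidal rule. The same sweep serves
the stand-alone CAD curve, scored per case by the maximum mark score
(0 when unmarked).

By default the aggregate score sums raw recall decisions (the 0-R score
is described as a sum of recalls); a localization-aware variant that
only credits correctly-located recalls on cancers is available.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np

from .io import CadMark, ReaderDecision, StudyMatrix, quadrant_from_box
from .metrics import UndefinedMetricError, is_true_positive, reader_cdr


@dataclass
class RocCurve:
    """Empirical ROC: aligned (fpr, tpr) points and thresholds, with the
    trapezoidal AUC. First point (0,0), last (1,1), both coordinates
    non-decreasing along the sweep."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> list:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


@dataclass(frozen=True)
class OperatingPoint:
    reader_id: str
    phase: str
    fpr: float
    tpr: float


def aggregate_score(matrix: StudyMatrix, case_id: str, phase: str,
                    localization: bool = False) -> int:
    """Sum of the binary recalls on one case in one phase (0..R)."""
    case = matrix.case(case_id)
    total = 0
    for r in matrix.readers:
        d = matrix.decision(r, case_id, phase)
        if localization and case.is_cancer:
            total += is_true_positive(case, d)
        else:
            total += d.recall
    return total


def aggregate_scores(matrix: StudyMatrix, phase: str,
                     localization: bool = False) -> Dict[str, int]:
    return {c.case_id: aggregate_score(matrix, c.case_id, phase, localization)
            for c in matrix.cases}


ScoreLike = Union[Mapping[str, float], Sequence[float], np.ndarray]


def _as_arrays(scores: ScoreLike, truth: Union[Mapping[str, str], Sequence]
               ) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(scores, Mapping):
        keys = sorted(scores)
        s = np.asarray([scores[k] for k in keys], dtype=float)
        if isinstance(truth, Mapping):
            t = np.asarray([truth[k] for k in keys])
        else:
            raise TypeError("mapping scores require mapping truth")
    else:
        s = np.asarray(scores, dtype=float)
        t = np.asarray(truth)
    if t.dtype.kind in "US":
        y = t == "cancer"
    else:
        y = t.astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and truth must align")
    return s, y


def roc_from_scores(scores: ScoreLike,
                    truth: Union[Mapping[str, str], Sequence]) -> RocCurve:
    """Threshold-sweep ROC from case scores and truth labels.

    Thresholds are the sorted unique scores in descending order,
    preceded by a sentinel above the maximum (yielding (0, 0)); recall
    iff score >= threshold. Requires both truth classes.
    """
    s, y = _as_arrays(scores, truth)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("ROC requires both truth classes")
    uniq = np.unique(s)[::-1]
    thresholds = np.concatenate(([uniq[0] + 1.0], uniq))
    tpr = np.empty(thresholds.shape)
    fpr = np.empty(thresholds.shape)
    for i, t in enumerate(thresholds):
        called = s >= t
        tpr[i] = (called & y).sum() / n1
        fpr[i] = (called & ~y).sum() / n0
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def auc_mann_whitney(scores: ScoreLike,
                     truth: Union[Mapping[str, str], Sequence]) -> float:
    """Tie-corrected rank-statistic AUC:
    (#concordant pairs + 0.5 #tied pairs) / (n1 * n0), computed through
    midranks. Identical to the trapezoidal threshold-sweep AUC."""
    s, y = _as_arrays(scores, truth)
    n1 = int(y.sum())
    n0 = s.size - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC requires both truth classes")
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(s.size)
    sorted_s = s[order]
    i = 0
    while i < s.size:
        j = i
        while j + 1 < s.size and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def pooled_roc(matrix: StudyMatrix, phase: str,
               localization: bool = False) -> RocCurve:
    """Group ROC from the per-case aggregate recall scores."""
    scores = aggregate_scores(matrix, phase, localization)
    truth = {c.case_id: c.truth_label for c in matrix.cases}
    return roc_from_scores(scores, truth)


def standalone_case_score(marks: Iterable[CadMark]) -> float:
    """Case-level CAD score: the maximum mark score, 0 if unmarked."""
    scores = [m.neuscore for m in marks]
    return max(scores) if scores else 0.0


def standalone_roc(matrix: StudyMatrix) -> RocCurve:
    """Stand-alone CAD ROC over the study cases."""
    scores = {c.case_id: standalone_case_score(matrix.marks_for(c.case_id))
              for c in matrix.cases}
    truth = {c.case_id: c.truth_label for c in matrix.cases}
    return roc_from_scores(scores, truth)


def reader_operating_point(matrix: StudyMatrix, reader_id: str, phase: str,
                           localization: bool = True) -> OperatingPoint:
    normals = matrix.normal_cases()
    if not normals or not matrix.cancer_cases():
        raise UndefinedMetricError("operating point requires both classes")
    tpr = reader_cdr(matrix, reader_id, phase, localization)
    fp = sum(matrix.decision(reader_id, c.case_id, phase).recall
             for c in normals)
    return OperatingPoint(reader_id=reader_id, phase=phase,
                          fpr=fp / len(normals), tpr=tpr)


def _mark_location(mark: CadMark) -> Tuple[str, str]:
    return mark.laterality, quadrant_from_box(mark.box)


def theoretical_transform(matrix: StudyMatrix, reader_id: str
                          ) -> Dict[Tuple[str, str], ReaderDecision]:
    """Counterfactual post decisions for a fully CAD-compliant reader.

    post recall := pre recall OR the case carries any CAD mark; a recall
    is never removed. Applied to cancers and normals alike. Converted
    recalls claim the truth-hitting mark's location when one exists,
    else the highest-scoring mark's location.
    """
    out: Dict[Tuple[str, str], ReaderDecision] = {}
    for c in matrix.cases:
        pre = matrix.decision(reader_id, c.case_id, "pre")
        marks = matrix.marks_for(c.case_id)
        if pre.recall:
            lat, quad = pre.claimed_laterality, pre.claimed_quadrant
            recall = 1
        elif marks:
            recall = 1
            hits = matrix.truth_hitting_marks(c.case_id)
            if hits:
                lat, quad = c.truth_laterality, c.truth_quadrant
            else:
                lat, quad = _mark_location(max(marks, key=lambda m: m.neuscore))
        else:
            recall, lat, quad = 0, "none", "none"
        out[(reader_id, c.case_id)] = ReaderDecision(
            reader_id=reader_id, case_id=c.case_id, phase="post",
            recall=recall, claimed_laterality=lat, claimed_quadrant=quad)
    return out


def theoretical_matrix(matrix: StudyMatrix) -> StudyMatrix:
    """Matrix whose post phase is the theoretical-reader transform of
    the pre phase, for every reader."""
    repl: Dict[Tuple[str, str], ReaderDecision] = {}
    for r in matrix.readers:
        repl.update(theoretical_transform(matrix, r))
    return matrix.with_post_decisions(repl)


def pct_change_auc(auc_pre: float, auc_post: float) -> float:
    """Relative AUC change in percent: 100 * (post - pre) / pre."""
    if auc_pre <= 0:
        raise UndefinedMetricError("pct AUC change undefined for zero baseline")
    return 100.0 * (auc_post - auc_pre) / auc_pre
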