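"""Per-reader and group-level detection metrics before/after the CAD
second look.

"Cancer detection rate" (CDR) here is the per-case sensitivity on the
enriched study set — the fraction of cancer cases a reader correctly
recalls — *not* a per-thousand-screens clinical rate. A recall on a
cancer case counts as a true positive only when the claimed laterality
and quadrant both match the truth ("localization-aware" rule); a recall
with the wrong side or quadrant is a false-negative recall. The
per-class conversion/ignore accounting defaults to plain case-level
recall (location-agnostic); both behaviours are switchable.

All internal values are unrounded proportions/counts; display rounding
happens only in report formatting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .io import CaseRecord, ReaderDecision, StudyMatrix

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator class is empty."""


def is_true_positive(case: CaseRecord, decision: ReaderDecision,
                     localization: bool = True) -> int:
    """1 iff the reader recalled the cancer case (and, under the
    localization-aware rule, claimed the correct side and quadrant)."""
    if not case.is_cancer:
        raise UndefinedMetricError(
            f"is_true_positive on non-cancer case {case.case_id}")
    if not decision.recall:
        return 0
    if not localization:
        return 1
    return int(decision.claimed_laterality == case.truth_laterality
               and decision.claimed_quadrant == case.truth_quadrant)


def reader_cdr(matrix: StudyMatrix, reader_id: str, phase: str,
               localization: bool = True,
               cases: Optional[Sequence[CaseRecord]] = None) -> float:
    """Fraction of cancer cases correctly recalled by one reader.

    ``cases`` restricts the denominator (used for density strata);
    defaults to every cancer case in the matrix.
    """
    pool = tuple(c for c in (cases if cases is not None else matrix.cases)
                 if c.is_cancer)
    if not pool:
        raise UndefinedMetricError("CDR undefined: no cancer cases")
    tp = sum(is_true_positive(c, matrix.decision(reader_id, c.case_id, phase),
                              localization) for c in pool)
    return tp / len(pool)


def delta_and_pct_change(pre: float, post: float
                         ) -> Tuple[float, Optional[float]]:
    """(percentage-point delta, relative % change) between proportions.

    The relative change is undefined for a zero baseline and reported
    as None with a warning.
    """
    delta = 100.0 * (post - pre)
    if pre == 0:
        warnings.warn("pct change undefined for zero baseline", stacklevel=2)
        return delta, None
    return delta, 100.0 * (post - pre) / pre


def fp_recall_metrics(matrix: StudyMatrix, reader_id: str
                      ) -> Tuple[int, int, int, int, float]:
    """(fp_pre, fp_increase, fp_reduction, fp_post, rate_change_%) over
    the normal cases. Conservation fp_post = fp_pre + inc - red holds
    by construction."""
    normals = matrix.normal_cases()
    if not normals:
        raise UndefinedMetricError("FP metrics undefined: no normal cases")
    fp_pre = fp_inc = fp_red = 0
    for c in normals:
        pre = matrix.decision(reader_id, c.case_id, "pre").recall
        post = matrix.decision(reader_id, c.case_id, "post").recall
        fp_pre += pre
        fp_inc += int(pre == 0 and post == 1)
        fp_red += int(pre == 1 and post == 0)
    fp_post = fp_pre + fp_inc - fp_red
    rate_change = 100.0 * (fp_post - fp_pre) / len(normals)
    return fp_pre, fp_inc, fp_red, fp_post, rate_change


def leading_class(lesion_components: Sequence[str]) -> str:
    """Dichotomize a lesion composition into ``calc`` vs ``mass``.

    ``calc`` iff the designated leading component (first element) is
    microcalcifications; every other composition — masses, distortions,
    asymmetries, and mixed lesions led by them — counts as ``mass``.
    """
    if not lesion_components:
        raise UndefinedMetricError("leading_class of an empty component set")
    return "calc" if lesion_components[0] == "microcalcifications" else "mass"


def conversion_accounting(matrix: StudyMatrix, reader_id: str, cls: str,
                          localization: bool = False
                          ) -> Tuple[int, int, int]:
    """(recalled_pre, additional_recalled, ignored_flags) for one reader
    over the cancer cases of one lesion class.

    additional_recalled: missed unaided, recalled after CAD, and the
    case carried a truth-hitting mark. ignored_flags: missed in both
    phases despite a truth-hitting mark. ``localization`` switches the
    recall notion from plain case-level recall (default) to the
    localization-aware true-positive rule.
    """
    if cls not in ("calc", "mass"):
        raise ValueError(f"class must be 'calc' or 'mass', got {cls!r}")
    recalled_pre = additional = ignored = 0
    for c in matrix.cancer_cases():
        if leading_class(c.lesion_components) != cls:
            continue
        if localization:
            pre = is_true_positive(c, matrix.decision(reader_id, c.case_id, "pre"))
            post = is_true_positive(c, matrix.decision(reader_id, c.case_id, "post"))
        else:
            pre = matrix.decision(reader_id, c.case_id, "pre").recall
            post = matrix.decision(reader_id, c.case_id, "post").recall
        hit = bool(matrix.truth_hitting_marks(c.case_id))
        recalled_pre += pre
        additional += int(pre == 0 and post == 1 and hit)
        ignored += int(pre == 0 and post == 0 and hit)
    return recalled_pre, additional, ignored


@dataclass
class ClassCounts:
    recalled_pre: int
    additional_recalled: int
    ignored_flags: int


@dataclass
class ReaderMetrics:
    """Every per-reader figure of the before/after comparison."""

    reader_id: str
    cdr_pre: float
    cdr_post: float
    delta_cdr: float                 # percentage points
    pct_change_cdr: Optional[float]  # relative %, None for zero baseline
    fp_pre: int
    fp_increase: int
    fp_reduction: int
    fp_post: int
    fp_rate_change: float            # percentage points over normals
    calc: ClassCounts = field(default=None)  # type: ignore[assignment]
    mass: ClassCounts = field(default=None)  # type: ignore[assignment]


def compute_reader_metrics(matrix: StudyMatrix, reader_id: str,
                           localization: bool = True,
                           conversion_localization: bool = False
                           ) -> ReaderMetrics:
    cdr_pre = reader_cdr(matrix, reader_id, "pre", localization)
    cdr_post = reader_cdr(matrix, reader_id, "post", localization)
    delta, pct = delta_and_pct_change(cdr_pre, cdr_post)
    fp_pre, fp_inc, fp_red, fp_post, rate = fp_recall_metrics(matrix, reader_id)
    return ReaderMetrics(
        reader_id=reader_id, cdr_pre=cdr_pre, cdr_post=cdr_post,
        delta_cdr=delta, pct_change_cdr=pct,
        fp_pre=fp_pre, fp_increase=fp_inc, fp_reduction=fp_red,
        fp_post=fp_post, fp_rate_change=rate,
        calc=ClassCounts(*conversion_accounting(
            matrix, reader_id, "calc", conversion_localization)),
        mass=ClassCounts(*conversion_accounting(
            matrix, reader_id, "mass", conversion_localization)),
    )


def all_reader_metrics(matrix: StudyMatrix, localization: bool = True,
                       conversion_localization: bool = False
                       ) -> List[ReaderMetrics]:
    return [compute_reader_metrics(matrix, r, localization,
                                   conversion_localization)
            for r in matrix.readers]


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic mean and range of one metric across readers."""

    mean: float
    min: float
    max: float


def group_summary(values: Iterable[float]) -> GroupSummary:
    vals = [float(v) for v in values]
    if not vals:
        raise UndefinedMetricError("group summary of an empty value list")
    return GroupSummary(mean=sum(vals) / len(vals), min=min(vals), max=max(vals))


def density_stratified_deltas(matrix: StudyMatrix, localization: bool = True
                              ) -> Dict[int, List[float]]:
    """Per-density-stratum vectors of per-reader CDR deltas (percentage
    points), suitable for a one-sample t test against zero. Strata with
    no cancer cases are omitted with a warning."""
    out: Dict[int, List[float]] = {}
    for density in (1, 2, 3, 4):
        pool = tuple(c for c in matrix.cancer_cases() if c.density == density)
        if not pool:
            logger.warning("density stratum %d has no cancer cases; omitted",
                           density)
            continue
        deltas = []
        for r in matrix.readers:
            pre = reader_cdr(matrix, r, "pre", localization, cases=pool)
            post = reader_cdr(matrix, r, "post", localization, cases=pool)
            deltas.append(100.0 * (post - pre))
        out[density] = deltas
    return out


def lesion_distribution(matrix: StudyMatrix) -> Dict[Tuple[str, ...], int]:
    """Composition table of the cancer cases (leading component first)."""
    out: Dict[Tuple[str, ...], int] = {}
    for c in matrix.cancer_cases():
        out[c.lesion_components] = out.get(c.lesion_components, 0) + 1
    return out
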