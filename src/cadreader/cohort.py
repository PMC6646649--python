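"""Subject-group accounting: the filtering ladder from a biopsy
population down to the Earliest-Actionable reader-study set.

A *prior* exam is one taken strictly more than 270 days (9 months)
before the tissue biopsy. Cancer patients with priors either show a
*retrospective finding* (the eventually biopsied lesion is visible in
hindsight) or had a *de novo* cancer. Retrospective patients carry a
category assigned by the validating radiologists — ``actionable`` (the
lesion was recallable in a clinical setting), ``non_actionable``
(subthreshold), or ``excluded`` (ipsilateral prior lumpectomy, or
tomosynthesis/synthesized images). Actionability is an input label;
this module never infers it.

Per-exam retrospective visibility is carried on the exam row's
``retrospective_finding`` flag; the Earliest Actionable exam for a
patient of category ``actionable`` is their oldest flagged prior exam.
Lead times are reported from that exam to the biopsy date and labelled
as such.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from ._format import round_half_away

logger = logging.getLogger(__name__)

CATEGORIES = ("actionable", "non_actionable", "excluded", "de_novo")
EXCLUDED_REASONS = ("ipsilateral_prior_lumpectomy", "tomo_or_synthesized")


class LedgerError(ValueError):
    """A cohort violates one of the partition identities."""


def is_prior(exam_date: dt.date, biopsy_date: dt.date) -> int:
    """1 iff the exam predates the biopsy by strictly more than 270 days."""
    return int((biopsy_date - exam_date).days > 270)


@dataclass(frozen=True)
class ExamEntry:
    exam_id: str
    exam_date: dt.date
    retrospective_finding: bool = False
    modality_flags: Tuple[str, ...] = ()


@dataclass(frozen=True)
class CohortRecord:
    """One patient: biopsy outcomes, exams, and the validating
    radiologists' categorization of any retrospective finding."""

    patient_id: str
    biopsy_outcomes: frozenset
    biopsy_date: Optional[dt.date]
    exams: Tuple[ExamEntry, ...] = ()
    retrospective_finding: Optional[bool] = None
    category: Optional[str] = None
    excluded_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category is not None and self.category not in CATEGORIES:
            raise LedgerError(
                f"patient {self.patient_id}: unknown category {self.category!r}")
        if self.excluded_reason is not None and \
                self.excluded_reason not in EXCLUDED_REASONS:
            raise LedgerError(
                f"patient {self.patient_id}: unknown excluded reason "
                f"{self.excluded_reason!r}")
        if self.category is not None and not self.prior_exams():
            raise LedgerError(
                f"patient {self.patient_id}: category without a prior exam")

    def prior_exams(self) -> Tuple[ExamEntry, ...]:
        if self.biopsy_date is None:
            return ()
        return tuple(e for e in self.exams
                     if is_prior(e.exam_date, self.biopsy_date))


def select_earliest_actionable(record: CohortRecord) -> Optional[str]:
    """Exam id of the oldest actionable prior, or None.

    Date ties break lexicographically on exam_id (and are logged).
    """
    if record.category != "actionable":
        return None
    candidates = [e for e in record.prior_exams() if e.retrospective_finding]
    if not candidates:
        return None
    earliest = min(candidates, key=lambda e: (e.exam_date, e.exam_id))
    if sum(1 for e in candidates if e.exam_date == earliest.exam_date) > 1:
        logger.warning(
            "patient %s: multiple actionable priors on %s; tie broken "
            "lexicographically to %s", record.patient_id,
            earliest.exam_date, earliest.exam_id)
    return earliest.exam_id


@dataclass
class LedgerReport:
    """Counts and percentages at every filter stage, plus the selected
    Earliest-Actionable exam list with lead-time statistics (years,
    measured to the biopsy date)."""

    total_patients: int
    cancer_patients: int
    benign_patients: int
    both_patients: int
    with_priors: int
    retrospective: int
    de_novo: int
    actionable: int
    non_actionable: int
    excluded: int
    pct_retrospective: Optional[float]
    pct_actionable: Optional[float]
    earliest_actionable: List[Tuple[str, str, int]]  # (patient, exam, lead days)
    lead_time_years: Dict[str, Optional[float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["earliest_actionable"] = [list(t) for t in self.earliest_actionable]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_text(self) -> str:
        lines = [
            "Cohort ledger",
            "-" * 46,
            f"total patients              {self.total_patients:>6}",
            f"  cancer biopsy             {self.cancer_patients:>6}",
            f"  benign biopsy             {self.benign_patients:>6}",
            f"  both                      {self.both_patients:>6}",
            f"cancer patients with priors {self.with_priors:>6}",
            f"  retrospective findings    {self.retrospective:>6}"
            + (f"  ({self.pct_retrospective:.0f}%)"
               if self.pct_retrospective is not None else ""),
            f"  de novo                   {self.de_novo:>6}",
            f"    actionable              {self.actionable:>6}"
            + (f"  ({self.pct_actionable:.0f}%)"
               if self.pct_actionable is not None else ""),
            f"    non-actionable          {self.non_actionable:>6}",
            f"    excluded                {self.excluded:>6}",
            f"earliest-actionable exams   {len(self.earliest_actionable):>6}",
        ]
        lt = self.lead_time_years
        if lt.get("mean") is not None:
            lines.append(
                "lead time to biopsy (y)     "
                f"mean {lt['mean']:.1f}  min {lt['min']:.2f}  max {lt['max']:.1f}")
        return "\n".join(lines)


def build_ledger(records: Sequence[CohortRecord]) -> LedgerReport:
    """Compute the filtering ladder and assert its partition identities.

    Identities enforced on every run:
    ``actionable + non_actionable + excluded == retrospective`` and
    ``retrospective + de_novo == with_priors`` and
    ``cancer + benign - both == total``.
    """
    total = len(records)
    cancer = [r for r in records if "cancer" in r.biopsy_outcomes]
    benign = [r for r in records if "benign" in r.biopsy_outcomes]
    both = [r for r in records if {"cancer", "benign"} <= set(r.biopsy_outcomes)]
    if len(cancer) + len(benign) - len(both) != total:
        raise LedgerError("biopsy-outcome counts do not partition the cohort")

    with_priors = [r for r in cancer if r.prior_exams()]
    retro = [r for r in with_priors if r.retrospective_finding]
    de_novo = [r for r in with_priors if not r.retrospective_finding]
    act = [r for r in retro if r.category == "actionable"]
    non_act = [r for r in retro if r.category == "non_actionable"]
    excl = [r for r in retro if r.category == "excluded"]

    if len(act) + len(non_act) + len(excl) != len(retro):
        raise LedgerError(
            "actionable + non_actionable + excluded != retrospective count")
    if len(retro) + len(de_novo) != len(with_priors):
        raise LedgerError("retrospective + de_novo != with-priors count")

    def _pct(num: int, den: int) -> Optional[float]:
        return None if den == 0 else round_half_away(100.0 * num / den)

    earliest: List[Tuple[str, str, int]] = []
    for r in act:
        exam_id = select_earliest_actionable(r)
        if exam_id is None:
            continue
        exam = next(e for e in r.exams if e.exam_id == exam_id)
        earliest.append(
            (r.patient_id, exam_id, (r.biopsy_date - exam.exam_date).days))

    lead_years = [d / 365.25 for _, _, d in earliest]
    lead_stats: Dict[str, Optional[float]] = {
        "mean": sum(lead_years) / len(lead_years) if lead_years else None,
        "min": min(lead_years) if lead_years else None,
        "max": max(lead_years) if lead_years else None,
    }

    return LedgerReport(
        total_patients=total,
        cancer_patients=len(cancer),
        benign_patients=len(benign),
        both_patients=len(both),
        with_priors=len(with_priors),
        retrospective=len(retro),
        de_novo=len(de_novo),
        actionable=len(act),
        non_actionable=len(non_act),
        excluded=len(excl),
        pct_retrospective=_pct(len(retro), len(with_priors)),
        pct_actionable=_pct(len(act), len(retro)),
        earliest_actionable=sorted(earliest),
        lead_time_years=lead_stats,
    )


# ---------------------------------------------------------------- CSV I/O

def load_cohort(path) -> Tuple[CohortRecord, ...]:
    """Read cohort.csv (one row per exam; exam fields may be empty for
    patients with no recorded exams)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ["patient_id", "biopsy_outcomes", "biopsy_date", "exam_id",
                "exam_date", "retrospective_finding", "category",
                "excluded_reason"]:
        if col not in df.columns:
            raise LedgerError(f"cohort file missing column {col!r}")
    by_patient: Dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        p = by_patient.setdefault(row.patient_id, {
            "outcomes": frozenset(t for t in row.biopsy_outcomes.split(";") if t),
            "biopsy_date": (dt.date.fromisoformat(row.biopsy_date)
                            if row.biopsy_date else None),
            "category": row.category or None,
            "excluded_reason": row.excluded_reason or None,
            "retro": None,
            "exams": [],
        })
        if row.exam_id:
            if not row.exam_date:
                raise LedgerError(f"cohort row {i}: exam without a date")
            flag = row.retrospective_finding == "1"
            p["exams"].append(ExamEntry(
                exam_id=row.exam_id,
                exam_date=dt.date.fromisoformat(row.exam_date),
                retrospective_finding=flag))
            if flag:
                p["retro"] = True
    out = []
    for pid, p in by_patient.items():
        retro = p["retro"]
        if retro is None:
            retro = False if p["exams"] else None
        out.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=p["outcomes"],
            biopsy_date=p["biopsy_date"], exams=tuple(p["exams"]),
            retrospective_finding=retro, category=p["category"],
            excluded_reason=p["excluded_reason"]))
    return tuple(out)


def write_cohort(records: Sequence[CohortRecord], path) -> None:
    rows = []
    for r in records:
        base = {
            "patient_id": r.patient_id,
            "biopsy_outcomes": ";".join(sorted(r.biopsy_outcomes)),
            "biopsy_date": r.biopsy_date.isoformat() if r.biopsy_date else "",
            "category": r.category or "",
            "excluded_reason": r.excluded_reason or "",
        }
        if not r.exams:
            rows.append({**base, "exam_id": "", "exam_date": "",
                         "retrospective_finding": ""})
        for e in r.exams:
            rows.append({**base, "exam_id": e.exam_id,
                         "exam_date": e.exam_date.isoformat(),
                         "retrospective_finding":
                             "1" if e.retrospective_finding else "0"})
    cols = ["patient_id", "biopsy_outcomes", "biopsy_date", "exam_id",
            "exam_date", "retrospective_finding", "category", "excluded_reason"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
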