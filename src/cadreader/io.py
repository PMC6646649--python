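"""Schemas, validation and CSV round-tripping for reader-study data.

A sequential CAD reader study is fully described by three tables:

``cases.csv``
    one row per exam with the adjudicated ground truth — cancer/normal
    label, lesion composition (semicolon-joined tokens, the *first* token
    is the leading component), BI-RADS-style density category 1–4,
    truth laterality/quadrant, truth bounding boxes per view, and dates.
``decisions.csv``
    one row per reader × case × phase (``pre`` = unaided read, ``post`` =
    after seeing the CAD marks) with the binary recall decision and the
    claimed lesion location.
``cad_marks.csv``
    zero or more CAD findings per case, each a view, a pixel bounding
    box and a 0–100 suspicion score.

Coordinates are 0-based pixels, x rightward, y downward; a box is
(x, y, w, h) = corner + extent. Two boxes overlap only if their
intersection has strictly positive area — edge-touching does not count.
Dates are ISO-8601 and day gaps are calendar-day differences.

:class:`StudyMatrix` is the validated in-memory container the rest of
the package computes from: a complete readers × cases × {pre, post}
decision cube with truth and marks attached.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

LATERALITIES = ("L", "R", "none")
QUADRANTS = ("UO", "UI", "LO", "LI", "central", "none")
VIEWS = ("LCC", "RCC", "LMLO", "RMLO")
DENSITIES = (1, 2, 3, 4)
LESION_COMPONENTS = (
    "mass",
    "microcalcifications",
    "architectural_distortion",
    "asymmetry",
    "focal_asymmetry",
)
PHASES = ("pre", "post")

Box = Tuple[float, float, float, float]
TruthBox = Tuple[str, float, float, float, float]  # (view, x, y, w, h)


class StudyDataError(ValueError):
    """Base class for every study-data validation failure."""


class SchemaError(StudyDataError):
    """A CSV row failed to parse (unknown enum token, bad number, ...)."""


class CompletenessError(StudyDataError):
    """The decision cube is missing (reader, case, phase) triples."""


class DuplicationError(StudyDataError):
    """The same (reader, case, phase) triple appears more than once."""


class ValidationError(StudyDataError):
    """A record violates a structural invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class CaseRecord:
    """One exam with its adjudicated ground truth.

    ``lesion_components`` is ordered: the first entry is the leading
    component as designated by the validating radiologists, which drives
    the calcification/mass dichotomy in the per-class tables.
    """

    case_id: str
    patient_id: str
    truth_label: str  # "cancer" | "normal"
    lesion_components: Tuple[str, ...]
    density: int
    truth_laterality: str
    truth_quadrant: str
    exam_date: dt.date
    biopsy_date: Optional[dt.date] = None
    truth_boxes: Tuple[TruthBox, ...] = ()

    def __post_init__(self) -> None:
        _require(self.truth_label in ("cancer", "normal"),
                 f"case {self.case_id}: bad truth_label {self.truth_label!r}")
        _require(self.density in DENSITIES,
                 f"case {self.case_id}: density must be 1-4, got {self.density!r}")
        _require(self.truth_laterality in LATERALITIES,
                 f"case {self.case_id}: bad laterality {self.truth_laterality!r}")
        _require(self.truth_quadrant in QUADRANTS,
                 f"case {self.case_id}: bad quadrant {self.truth_quadrant!r}")
        for c in self.lesion_components:
            _require(c in LESION_COMPONENTS,
                     f"case {self.case_id}: unknown lesion component {c!r}")
        for tb in self.truth_boxes:
            _require(tb[0] in VIEWS,
                     f"case {self.case_id}: unknown view {tb[0]!r}")
            _require(tb[3] > 0 and tb[4] > 0,
                     f"case {self.case_id}: truth box must have positive extent")
        if self.truth_label == "normal":
            _require(not self.lesion_components,
                     f"case {self.case_id}: normal case with lesion components")
            _require(self.truth_laterality == "none" and self.truth_quadrant == "none",
                     f"case {self.case_id}: normal case with a truth location")
            _require(not self.truth_boxes,
                     f"case {self.case_id}: normal case with truth boxes")
        else:
            _require(len(self.lesion_components) >= 1,
                     f"case {self.case_id}: cancer case without lesion components")
            _require(self.truth_laterality in ("L", "R"),
                     f"case {self.case_id}: cancer case needs a truth laterality")
            _require(self.truth_quadrant != "none",
                     f"case {self.case_id}: cancer case needs a truth quadrant")

    @property
    def is_cancer(self) -> bool:
        return self.truth_label == "cancer"


@dataclass(frozen=True)
class ReaderDecision:
    """One binary recall by one reader on one case in one phase."""

    reader_id: str
    case_id: str
    phase: str
    recall: int
    claimed_laterality: str = "none"
    claimed_quadrant: str = "none"

    def __post_init__(self) -> None:
        _require(self.phase in PHASES,
                 f"decision {self.reader_id}/{self.case_id}: bad phase {self.phase!r}")
        _require(self.recall in (0, 1),
                 f"decision {self.reader_id}/{self.case_id}: recall must be 0/1")
        _require(self.claimed_laterality in LATERALITIES and
                 self.claimed_quadrant in QUADRANTS,
                 f"decision {self.reader_id}/{self.case_id}: bad claimed location")
        if self.recall:
            _require(self.claimed_laterality != "none",
                     f"decision {self.reader_id}/{self.case_id}: "
                     "recall without claimed laterality")
        else:
            _require(self.claimed_laterality == "none" and
                     self.claimed_quadrant == "none",
                     f"decision {self.reader_id}/{self.case_id}: "
                     "no-recall with a claimed location")


@dataclass(frozen=True)
class CadMark:
    """One CAD finding: view, pixel bounding box, 0-100 suspicion score."""

    case_id: str
    view: str
    box: Box
    neuscore: float

    def __post_init__(self) -> None:
        _require(self.view in VIEWS,
                 f"mark on {self.case_id}: unknown view {self.view!r}")
        x, y, w, h = self.box
        _require(x >= 0 and y >= 0 and w > 0 and h > 0,
                 f"mark on {self.case_id}: invalid box {self.box!r}")
        _require(0.0 <= self.neuscore <= 100.0,
                 f"mark on {self.case_id}: score must be in [0, 100]")

    @property
    def laterality(self) -> str:
        return self.view[0]


def boxes_overlap(a: Box, b: Box) -> int:
    """1 iff the two boxes share strictly positive intersection area.

    Edge-touching boxes (zero-area intersection) do not overlap.
    """
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ox = min(ax + aw, bx + bw) - max(ax, bx)
    oy = min(ay + ah, by + bh) - max(ay, by)
    return int(ox > 0 and oy > 0)


def mark_hits_truth(case: CaseRecord, mark: CadMark) -> int:
    """1 iff the mark overlaps a truth box on the same view.

    Only meaningful on cancer cases: normals carry no truth boxes, so
    every mark on a normal is by definition a false mark.
    """
    if not case.is_cancer:
        raise ValidationError(
            f"mark_hits_truth called on normal case {case.case_id}")
    for view, x, y, w, h in case.truth_boxes:
        if view == mark.view and boxes_overlap((x, y, w, h), mark.box):
            return 1
    return 0


def quadrant_from_box(box: Box, image_size: float = 1000.0) -> str:
    """Deterministic box-centre -> quadrant mapping used study-wide.

    Centres within the middle 30% of both axes map to ``central``;
    otherwise upper/lower × outer/inner by halves, with the *outer*
    half taken as low x (lateral convention is fixed per view; the
    simulator uses the same mapping when placing truth boxes so claimed
    locations derived from marks are consistent).
    """
    x, y, w, h = box
    cx, cy = x + w / 2.0, y + h / 2.0
    lo, hi = 0.35 * image_size, 0.65 * image_size
    if lo <= cx < hi and lo <= cy < hi:
        return "central"
    vert = "U" if cy < image_size / 2.0 else "L"
    horiz = "O" if cx < image_size / 2.0 else "I"
    return vert + horiz


@dataclass
class StudyMatrix:
    """Complete readers × cases × {pre, post} decision cube.

    Exactly one decision exists per (reader, case, phase) triple, i.e.
    2·R·C decisions for R readers and C cases.
    """

    readers: Tuple[str, ...]
    cases: Tuple[CaseRecord, ...]
    decisions: Mapping[Tuple[str, str, str], ReaderDecision]
    marks: Mapping[str, Tuple[CadMark, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.readers = tuple(self.readers)
        self.cases = tuple(self.cases)
        self.decisions = dict(self.decisions)
        self.marks = {k: tuple(v) for k, v in dict(self.marks).items()}
        self._case_by_id = {c.case_id: c for c in self.cases}
        self.validate()

    # -- validation -------------------------------------------------

    def validate(self) -> None:
        if len(self._case_by_id) != len(self.cases):
            raise DuplicationError("duplicate case_id in case table")
        expected = {(r, c.case_id, p)
                    for r in self.readers for c in self.cases for p in PHASES}
        got = set(self.decisions.keys())
        missing = expected - got
        if missing:
            listing = ", ".join(map(str, sorted(missing)[:10]))
            raise CompletenessError(
                f"{len(missing)} missing (reader, case, phase) triples: {listing}")
        extra = got - expected
        if extra:
            raise ValidationError(
                f"decisions reference unknown readers/cases: {sorted(extra)[:10]}")
        for key, d in self.decisions.items():
            if (d.reader_id, d.case_id, d.phase) != key:
                raise ValidationError(f"decision stored under wrong key {key}")
        for case_id in self.marks:
            if case_id not in self._case_by_id:
                raise ValidationError(f"marks reference unknown case {case_id!r}")

    # -- accessors --------------------------------------------------

    @property
    def n_readers(self) -> int:
        return len(self.readers)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def case(self, case_id: str) -> CaseRecord:
        return self._case_by_id[case_id]

    def decision(self, reader_id: str, case_id: str, phase: str) -> ReaderDecision:
        return self.decisions[(reader_id, case_id, phase)]

    def marks_for(self, case_id: str) -> Tuple[CadMark, ...]:
        return self.marks.get(case_id, ())

    def cancer_cases(self) -> Tuple[CaseRecord, ...]:
        return tuple(c for c in self.cases if c.is_cancer)

    def normal_cases(self) -> Tuple[CaseRecord, ...]:
        return tuple(c for c in self.cases if not c.is_cancer)

    def has_any_mark(self, case_id: str, min_score: float = 0.0) -> bool:
        """Case-level "flagged": at least one mark at/above ``min_score``."""
        return any(m.neuscore >= min_score for m in self.marks_for(case_id))

    def truth_hitting_marks(self, case_id: str) -> Tuple[CadMark, ...]:
        case = self.case(case_id)
        if not case.is_cancer:
            return ()
        return tuple(m for m in self.marks_for(case_id)
                     if mark_hits_truth(case, m))

    def with_post_decisions(
        self, replacements: Mapping[Tuple[str, str], ReaderDecision]
    ) -> "StudyMatrix":
        """New matrix with post-phase decisions replaced for given
        (reader_id, case_id) keys; pre decisions are untouched."""
        decisions = dict(self.decisions)
        for (r, c), d in replacements.items():
            if d.phase != "post":
                raise ValidationError("replacement decisions must be post-phase")
            decisions[(r, c, "post")] = d
        return StudyMatrix(self.readers, self.cases, decisions, self.marks)


# ---------------------------------------------------------------- CSV I/O

_DATE_FMT = "%Y-%m-%d"


def _parse_date(tok: str, ctx: str) -> dt.date:
    try:
        return dt.datetime.strptime(tok, _DATE_FMT).date()
    except ValueError as exc:
        raise SchemaError(f"{ctx}: bad date {tok!r} (expect YYYY-MM-DD)") from exc


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df


def _parse_truth_boxes(tok: str, ctx: str) -> Tuple[TruthBox, ...]:
    if not tok:
        return ()
    out = []
    for part in tok.split(";"):
        bits = part.split(":")
        if len(bits) != 5:
            raise SchemaError(f"{ctx}: bad truth box {part!r} (expect view:x:y:w:h)")
        view = bits[0]
        try:
            x, y, w, h = (float(b) for b in bits[1:])
        except ValueError as exc:
            raise SchemaError(f"{ctx}: non-numeric truth box {part!r}") from exc
        out.append((view, x, y, w, h))
    return tuple(out)


def load_cases(path) -> Tuple[CaseRecord, ...]:
    df = _read_csv(path)
    needed = ["case_id", "patient_id", "truth_label", "lesion_components",
              "density", "truth_laterality", "truth_quadrant", "exam_date",
              "biopsy_date", "truth_boxes"]
    for col in needed:
        if col not in df.columns:
            raise SchemaError(f"cases file missing column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"cases row {i}"
        try:
            density = int(row.density)
        except ValueError as exc:
            raise SchemaError(f"{ctx}: bad density {row.density!r}") from exc
        comps = tuple(t for t in row.lesion_components.split(";") if t)
        biopsy = _parse_date(row.biopsy_date, ctx) if row.biopsy_date else None
        try:
            records.append(CaseRecord(
                case_id=row.case_id,
                patient_id=row.patient_id,
                truth_label=row.truth_label,
                lesion_components=comps,
                density=density,
                truth_laterality=row.truth_laterality,
                truth_quadrant=row.truth_quadrant,
                exam_date=_parse_date(row.exam_date, ctx),
                biopsy_date=biopsy,
                truth_boxes=_parse_truth_boxes(row.truth_boxes, ctx),
            ))
        except ValidationError as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return tuple(records)


def load_decisions(path) -> Tuple[ReaderDecision, ...]:
    df = _read_csv(path)
    for col in ["reader_id", "case_id", "phase", "recall",
                "claimed_laterality", "claimed_quadrant"]:
        if col not in df.columns:
            raise SchemaError(f"decisions file missing column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"decisions row {i}"
        if row.recall not in ("0", "1"):
            raise SchemaError(f"{ctx}: recall must be 0 or 1, got {row.recall!r}")
        try:
            records.append(ReaderDecision(
                reader_id=row.reader_id,
                case_id=row.case_id,
                phase=row.phase,
                recall=int(row.recall),
                claimed_laterality=row.claimed_laterality,
                claimed_quadrant=row.claimed_quadrant,
            ))
        except ValidationError as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return tuple(records)


def load_marks(path) -> Tuple[CadMark, ...]:
    df = _read_csv(path)
    for col in ["case_id", "view", "x", "y", "w", "h", "neuscore"]:
        if col not in df.columns:
            raise SchemaError(f"marks file missing column {col!r}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ctx = f"marks row {i}"
        try:
            box = (float(row.x), float(row.y), float(row.w), float(row.h))
            score = float(row.neuscore)
        except ValueError as exc:
            raise SchemaError(f"{ctx}: non-numeric box or score") from exc
        try:
            records.append(CadMark(case_id=row.case_id, view=row.view,
                                   box=box, neuscore=score))
        except ValidationError as exc:
            raise SchemaError(f"{ctx}: {exc}") from exc
    return tuple(records)


def assemble(cases: Sequence[CaseRecord],
             decisions: Iterable[ReaderDecision],
             marks: Iterable[CadMark] = ()) -> StudyMatrix:
    """Build a validated StudyMatrix from record streams.

    Reader order is the sorted set of reader ids so that row order in
    the input never affects any downstream result.
    """
    dec_map: dict = {}
    for d in decisions:
        key = (d.reader_id, d.case_id, d.phase)
        if key in dec_map:
            raise DuplicationError(f"duplicate decision for triple {key}")
        dec_map[key] = d
    readers = tuple(sorted({d.reader_id for d in dec_map.values()}))
    mark_map: dict = {}
    for m in marks:
        mark_map.setdefault(m.case_id, []).append(m)
    return StudyMatrix(readers=readers, cases=tuple(cases),
                       decisions=dec_map, marks=mark_map)


def load_study(cases_path, decisions_path, marks_path) -> StudyMatrix:
    """Load and validate a full study from its three CSV files."""
    return assemble(load_cases(cases_path), load_decisions(decisions_path),
                    load_marks(marks_path))


def _fmt_num(x: float) -> str:
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def write_study(matrix: StudyMatrix, cases_path, decisions_path,
                marks_path) -> None:
    """Write the three CSVs; ``load_study`` of the output round-trips."""
    case_rows = []
    for c in matrix.cases:
        case_rows.append({
            "case_id": c.case_id,
            "patient_id": c.patient_id,
            "truth_label": c.truth_label,
            "lesion_components": ";".join(c.lesion_components),
            "density": c.density,
            "truth_laterality": c.truth_laterality,
            "truth_quadrant": c.truth_quadrant,
            "exam_date": c.exam_date.isoformat(),
            "biopsy_date": c.biopsy_date.isoformat() if c.biopsy_date else "",
            "truth_boxes": ";".join(
                ":".join([v] + [_fmt_num(t) for t in rest])
                for v, *rest in c.truth_boxes),
        })
    pd.DataFrame(case_rows).to_csv(cases_path, index=False)

    dec_rows = [dataclasses.asdict(matrix.decisions[(r, c.case_id, p)])
                for r in matrix.readers for c in matrix.cases for p in PHASES]
    pd.DataFrame(dec_rows).to_csv(decisions_path, index=False)

    mark_rows = []
    for c in matrix.cases:
        for m in matrix.marks_for(c.case_id):
            x, y, w, h = m.box
            mark_rows.append({"case_id": m.case_id, "view": m.view,
                              "x": _fmt_num(x), "y": _fmt_num(y),
                              "w": _fmt_num(w), "h": _fmt_num(h),
                              "neuscore": _fmt_num(m.neuscore)})
    pd.DataFrame(mark_rows,
                 columns=["case_id", "view", "x", "y", "w", "h", "neuscore"]
                 ).to_csv(marks_path, index=False)
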