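"""Shared fixtures: hand-built miniature studies and a seeded synthetic
study at the default (published-marginals) configuration."""

from __future__ import annotations

import datetime as dt
from typing import Optional, Sequence

import numpy as np
import pytest

from cadreader.io import (CadMark, CaseRecord, ReaderDecision, StudyMatrix)
from cadreader.model import ReaderStudy
from cadreader.simulate import default_config, generate_study

TRUTH_BOX = (100.0, 100.0, 80.0, 80.0)


def mk_cancer(case_id: str, lat: str = "L", quad: str = "UO",
              comps=("mass",), density: int = 2,
              boxes=None, patient: Optional[str] = None) -> CaseRecord:
    view = f"{lat}CC"
    if boxes is None:
        boxes = ((view,) + TRUTH_BOX,)
    return CaseRecord(
        case_id=case_id, patient_id=patient or f"p_{case_id}",
        truth_label="cancer", lesion_components=tuple(comps),
        density=density, truth_laterality=lat, truth_quadrant=quad,
        exam_date=dt.date(2014, 1, 1), biopsy_date=dt.date(2016, 1, 1),
        truth_boxes=boxes)


def mk_normal(case_id: str, density: int = 2) -> CaseRecord:
    return CaseRecord(
        case_id=case_id, patient_id=f"p_{case_id}", truth_label="normal",
        lesion_components=(), density=density, truth_laterality="none",
        truth_quadrant="none", exam_date=dt.date(2014, 1, 1))


def mk_dec(reader: str, case: CaseRecord, phase: str, recall: int,
           correct: bool = True, lat: str = None, quad: str = None
           ) -> ReaderDecision:
    """Decision with the truth location when recalled (or an explicitly
    wrong/arbitrary one)."""
    if not recall:
        return ReaderDecision(reader, case.case_id, phase, 0)
    if lat is None:
        if case.is_cancer and correct:
            lat, quad = case.truth_laterality, case.truth_quadrant
        elif case.is_cancer:
            lat = case.truth_laterality
            quad = "LI" if case.truth_quadrant != "LI" else "LO"
        else:
            lat, quad = "L", "UO"
    return ReaderDecision(reader, case.case_id, phase, 1, lat, quad)


def hit_mark(case: CaseRecord, score: float = 80.0) -> CadMark:
    """A CAD mark coincident with the case's first truth box."""
    view, x, y, w, h = case.truth_boxes[0]
    return CadMark(case_id=case.case_id, view=view, box=(x, y, w, h),
                   neuscore=score)


def false_mark(case: CaseRecord, score: float = 50.0,
               view: str = "RMLO") -> CadMark:
    return CadMark(case_id=case.case_id, view=view,
                   box=(600.0, 600.0, 60.0, 60.0), neuscore=score)


def matrix_from_arrays(pre: np.ndarray, post: np.ndarray,
                       truth: Sequence[bool],
                       hit_flags: Optional[Sequence[bool]] = None,
                       classes: Optional[Sequence[str]] = None,
                       densities: Optional[Sequence[int]] = None
                       ) -> StudyMatrix:
    """Matrix from R x C binary recall arrays; recalls always claim the
    truth location on cancers. ``hit_flags`` adds a truth-hitting mark
    to flagged cancers (and a false mark to flagged normals);
    ``classes`` sets calc/mass-leading lesions on cancers."""
    pre = np.asarray(pre)
    post = np.asarray(post)
    R, C = pre.shape
    cases = []
    for j in range(C):
        if truth[j]:
            comps = (("microcalcifications",)
                     if classes is not None and classes[j] == "calc"
                     else ("mass",))
            cases.append(mk_cancer(f"c{j:03d}", comps=comps,
                                   density=densities[j] if densities else 2))
        else:
            cases.append(mk_normal(
                f"c{j:03d}", density=densities[j] if densities else 2))
    readers = [f"r{i}" for i in range(R)]
    decisions = {}
    for i, r in enumerate(readers):
        for j, case in enumerate(cases):
            for phase, arr in (("pre", pre), ("post", post)):
                d = mk_dec(r, case, phase, int(arr[i, j]))
                decisions[(r, case.case_id, phase)] = d
    marks = {}
    if hit_flags is not None:
        for j, case in enumerate(cases):
            if hit_flags[j]:
                marks[case.case_id] = ([hit_mark(case)] if case.is_cancer
                                       else [false_mark(case)])
    return StudyMatrix(readers=tuple(readers), cases=tuple(cases),
                       decisions=decisions, marks=marks)


@pytest.fixture
def tiny_matrix() -> StudyMatrix:
    """2 readers x 3 cases (2 cancer + 1 normal), 12 decisions."""
    c1 = mk_cancer("c1", lat="L", quad="UO")
    c2 = mk_cancer("c2", lat="R", quad="LI", comps=("microcalcifications",))
    n1 = mk_normal("n1")
    cases = (c1, c2, n1)
    decisions = {}
    plan = {  # (reader, case): (pre, post)
        ("rA", c1): (1, 1), ("rA", c2): (0, 1), ("rA", n1): (0, 0),
        ("rB", c1): (0, 0), ("rB", c2): (1, 1), ("rB", n1): (1, 1),
    }
    for (r, case), (pre, post) in plan.items():
        decisions[(r, case.case_id, "pre")] = mk_dec(r, case, "pre", pre)
        decisions[(r, case.case_id, "post")] = mk_dec(r, case, "post", post)
    marks = {"c1": [hit_mark(c1, 75.0)], "c2": [hit_mark(c2, 90.0)],
             "n1": [false_mark(n1, 40.0)]}
    return StudyMatrix(readers=("rA", "rB"), cases=cases,
                       decisions=decisions, marks=marks)


@pytest.fixture(scope="session")
def sim_matrix() -> StudyMatrix:
    return generate_study(default_config(), seed=0)


@pytest.fixture(scope="session")
def sim_results(sim_matrix):
    return ReaderStudy(sim_matrix).fit()
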