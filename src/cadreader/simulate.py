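"""Synthetic study and cohort generators.

The study generator emulates the decision structure of a sequential
CAD reader study: enriched case set (90 cancers + 32 normals by
default), CAD marks with ~98% case-level sensitivity on cancers plus
Poisson false marks, and a two-phase reader model —

* unaided phase: recall ~ Bernoulli(sens_pre) on cancers /
  Bernoulli(fp_prob_pre) on normals, with the claimed location correct
  with probability ``localization_accuracy``;
* CAD phase: an unaided recall survives unless the case is unmarked and
  the reader reverses (prob ``reversal_prob``); an unaided miss
  converts to recall with probability ``compliance_correct`` when a
  truth-hitting mark exists, else ``compliance_false`` when any (false)
  mark exists, else stays a miss.

Readers are conditionally independent given the case. Three RNG
streams (cases, marks, one per reader) are derived from the seed by
stable sub-seeding, so changing one reader's parameters perturbs
neither the case set nor the other readers; each reader draws a fixed
block of four uniforms per case, which makes raising a compliance
probability produce a superset of conversions under the same seed.

The default configuration is calibrated to the published per-reader
marginals (unaided sensitivities, false-positive counts, and
conversion/reversal targets) by solving the expected-count equations
with bisection.

The cohort generator emits a patient/exam table whose filter-stage
counts match the configured ladder exactly (biopsy population, priors,
retrospective findings, actionable/non-actionable/excluded split),
with prior-exam gaps sampled in the configured day range.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from . import datasets
from .cohort import CohortRecord, ExamEntry
from .io import (CadMark, CaseRecord, QUADRANTS, ReaderDecision, StudyMatrix,
                 quadrant_from_box)


class ConfigError(ValueError):
    """A simulation configuration parameter is out of range."""


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ReaderProfile:
    """Behavioural parameters of one simulated reader."""

    reader_id: str
    sens_pre: float
    fp_prob_pre: float
    compliance_correct: float = 0.5
    compliance_false: float = 0.1
    reversal_prob: float = 0.0
    localization_accuracy: float = 1.0

    def validate(self) -> None:
        for name in ("sens_pre", "fp_prob_pre", "compliance_correct",
                     "compliance_false", "reversal_prob",
                     "localization_accuracy"):
            _check_prob(getattr(self, name), f"reader {self.reader_id}.{name}")


@dataclass(frozen=True)
class CadModel:
    """CAD mark model: case-level sensitivity on cancers, Poisson false
    marks, and clipped-normal score distributions (0-100)."""

    case_sensitivity: float = 0.98
    false_marks_per_cancer: float = 0.3
    false_marks_per_normal: float = 0.7
    score_true: Tuple[float, float] = (80.0, 12.0)   # (mean, sd)
    score_false: Tuple[float, float] = (55.0, 15.0)

    def validate(self) -> None:
        _check_prob(self.case_sensitivity, "cad.case_sensitivity")
        if self.false_marks_per_cancer < 0 or self.false_marks_per_normal < 0:
            raise ConfigError("false-mark rates must be >= 0")
        for name in ("score_true", "score_false"):
            _, sd = getattr(self, name)
            if sd <= 0:
                raise ConfigError(f"cad.{name} sd must be positive")


_DEFAULT_DENSITY_PROBS = tuple(c / sum(datasets.DENSITY_COUNTS)
                               for c in datasets.DENSITY_COUNTS)


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-generation configuration. Defaults reproduce the
    published study conditions (case mix, density mix, CAD operating
    characteristics); readers default to the published-marginals
    calibration."""

    readers: Tuple[ReaderProfile, ...]
    n_cancer: int = datasets.N_CANCER
    n_normal: int = datasets.N_NORMAL
    density_probs: Tuple[float, ...] = _DEFAULT_DENSITY_PROBS
    lesion_mix: Tuple[Tuple[Tuple[str, ...], float], ...] = datasets.LESION_MIX
    cad: CadModel = field(default_factory=CadModel)

    def validate(self) -> None:
        if self.n_cancer < 1 or self.n_normal < 0:
            raise ConfigError("need n_cancer >= 1 and n_normal >= 0")
        if not self.readers:
            raise ConfigError("at least one reader profile is required")
        for r in self.readers:
            r.validate()
        if len(self.density_probs) != 4:
            raise ConfigError("density_probs must have four entries")
        for p in self.density_probs:
            _check_prob(p, "density_probs entry")
        if abs(sum(self.density_probs) - 1.0) > 1e-9:
            raise ConfigError("density_probs must sum to 1")
        if not self.lesion_mix or any(w < 0 for _, w in self.lesion_mix):
            raise ConfigError("lesion_mix weights must be non-negative")
        self.cad.validate()

    @property
    def n_readers(self) -> int:
        return len(self.readers)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ------------------------------------------------------- calibration

def _bisect_increasing(fun, target: float, lo: float = 0.0, hi: float = 1.0,
                       tol: float = 1e-10) -> float:
    """Solve fun(x) = target for an increasing fun on [lo, hi]; clips to
    the boundary when the target is unreachable."""
    if target <= fun(lo):
        return lo
    if target >= fun(hi):
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if fun(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def calibrate_compliance(target_additional: float, sens_pre: float,
                         n_cancer: int, case_sensitivity: float) -> float:
    """Compliance probability whose expected conversion count (misses
    that carry a truth-hitting mark and convert) equals the target."""
    def expected(c: float) -> float:
        return n_cancer * (1.0 - sens_pre) * case_sensitivity * c
    return _bisect_increasing(expected, target_additional)


def paper_marginals_config() -> SimulationConfig:
    """Reader profiles calibrated to the published per-reader tables:
    unaided sensitivity and false-positive probability set to the
    printed marginals, compliance/reversal probabilities solved so the
    expected conversion and reversal counts match the printed
    conversion-accounting columns."""
    cad = CadModel()
    p_false_mark = 1.0 - math.exp(-cad.false_marks_per_normal)
    p_no_mark_normal = math.exp(-cad.false_marks_per_normal)
    readers = []
    for i in range(datasets.N_READERS):
        sens = datasets.CDR_PRE_PCT[i] / 100.0
        fp_prob = datasets.FP_PRE[i] / datasets.N_NORMAL
        add_target = datasets.CALC_ADDITIONAL[i] + datasets.MASS_ADDITIONAL[i]
        c = calibrate_compliance(add_target, sens, datasets.N_CANCER,
                                 cad.case_sensitivity)
        f = _bisect_increasing(
            lambda x: datasets.N_NORMAL * (1.0 - fp_prob) * p_false_mark * x,
            float(datasets.FP_INCREASE[i]))
        rho = _bisect_increasing(
            lambda x: datasets.N_NORMAL * fp_prob * p_no_mark_normal * x,
            float(datasets.FP_REDUCTION[i]))
        readers.append(ReaderProfile(
            reader_id=datasets.READER_IDS[i], sens_pre=sens,
            fp_prob_pre=fp_prob, compliance_correct=c, compliance_false=f,
            reversal_prob=rho))
    return SimulationConfig(readers=tuple(readers))


def default_config() -> SimulationConfig:
    return paper_marginals_config()


# ------------------------------------------------------- study generation

_IMG = 1000.0
_QUADRANT_CENTER = {"UO": (250.0, 250.0), "UI": (750.0, 250.0),
                    "LO": (250.0, 750.0), "LI": (750.0, 750.0),
                    "central": (500.0, 500.0)}
_CANCER_QUADRANTS = ("UO", "UI", "LO", "LI", "central")


def _views_for(laterality: str) -> Tuple[str, str]:
    return (f"{laterality}CC", f"{laterality}MLO")


def _clipped_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 100.0))


def _truth_box(rng: np.random.Generator, quadrant: str
               ) -> Tuple[float, float, float, float]:
    cx, cy = _QUADRANT_CENTER[quadrant]
    cx += float(rng.uniform(-60, 60))
    cy += float(rng.uniform(-60, 60))
    w = float(rng.uniform(60, 120))
    h = float(rng.uniform(60, 120))
    return (round(cx - w / 2, 1), round(cy - h / 2, 1),
            round(w, 1), round(h, 1))


def _false_box(rng: np.random.Generator, avoid, view: str
               ) -> Tuple[float, float, float, float]:
    from .io import boxes_overlap
    for _ in range(50):
        w = float(rng.uniform(50, 120))
        h = float(rng.uniform(50, 120))
        x = float(rng.uniform(0, _IMG - w))
        y = float(rng.uniform(0, _IMG - h))
        box = (round(x, 1), round(y, 1), round(w, 1), round(h, 1))
        if not any(v == view and boxes_overlap((bx, by, bw, bh), box)
                   for v, bx, by, bw, bh in avoid):
            return box
    raise RuntimeError("could not place a non-overlapping false mark")


def generate_study(config: Optional[SimulationConfig] = None,
                   seed: int = 0) -> StudyMatrix:
    """Generate a complete validated study for the given seed."""
    if config is None:
        config = default_config()
    config.validate()
    ss = np.random.SeedSequence(seed)
    case_seq, mark_seq, reader_parent = ss.spawn(3)
    case_rng = np.random.default_rng(case_seq)
    mark_rng = np.random.default_rng(mark_seq)
    reader_rngs = [np.random.default_rng(s)
                   for s in reader_parent.spawn(config.n_readers)]

    # -- cases ------------------------------------------------------
    biopsy = dt.date(2016, 1, 15)
    mix_comps = [c for c, _ in config.lesion_mix]
    mix_w = np.asarray([w for _, w in config.lesion_mix], dtype=float)
    mix_w = mix_w / mix_w.sum()
    width = max(4, len(str(config.n_cancer + config.n_normal)))
    cases = []
    for k in range(config.n_cancer):
        comps = mix_comps[int(case_rng.choice(len(mix_comps), p=mix_w))]
        density = 1 + int(case_rng.choice(4, p=np.asarray(config.density_probs)))
        lat = "L" if case_rng.random() < 0.5 else "R"
        quad = _CANCER_QUADRANTS[int(case_rng.integers(0, 5))]
        box = _truth_box(case_rng, quad)
        boxes = tuple((v,) + box for v in _views_for(lat))
        gap = int(case_rng.integers(271, 2118))
        cases.append(CaseRecord(
            case_id=f"ca{str(k + 1).zfill(width)}",
            patient_id=f"pt{str(k + 1).zfill(width)}",
            truth_label="cancer", lesion_components=comps, density=density,
            truth_laterality=lat, truth_quadrant=quad,
            exam_date=biopsy - dt.timedelta(days=gap), biopsy_date=biopsy,
            truth_boxes=boxes))
    for k in range(config.n_normal):
        density = 1 + int(case_rng.choice(4, p=np.asarray(config.density_probs)))
        cases.append(CaseRecord(
            case_id=f"no{str(k + 1).zfill(width)}",
            patient_id=f"pt{str(config.n_cancer + k + 1).zfill(width)}",
            truth_label="normal", lesion_components=(), density=density,
            truth_laterality="none", truth_quadrant="none",
            exam_date=dt.date(2014, 3, 1) + dt.timedelta(days=k)))

    # -- CAD marks --------------------------------------------------
    cad = config.cad
    marks = []
    for c in cases:
        if c.is_cancer:
            if mark_rng.random() < cad.case_sensitivity:
                view, x, y, w, h = c.truth_boxes[0]
                jx = float(mark_rng.uniform(-w / 4, w / 4))
                jy = float(mark_rng.uniform(-h / 4, h / 4))
                marks.append(CadMark(
                    case_id=c.case_id, view=view,
                    box=(round(max(0.0, x + jx), 1), round(max(0.0, y + jy), 1),
                         round(w, 1), round(h, 1)),
                    neuscore=round(_clipped_normal(mark_rng, *cad.score_true), 1)))
            lam = cad.false_marks_per_cancer
        else:
            lam = cad.false_marks_per_normal
        for _ in range(int(mark_rng.poisson(lam))):
            view = ("LCC", "RCC", "LMLO", "RMLO")[int(mark_rng.integers(0, 4))]
            box = _false_box(mark_rng, c.truth_boxes, view)
            marks.append(CadMark(
                case_id=c.case_id, view=view, box=box,
                neuscore=round(_clipped_normal(mark_rng, *cad.score_false), 1)))

    mark_map: dict = {}
    for m in marks:
        mark_map.setdefault(m.case_id, []).append(m)

    from .io import mark_hits_truth
    hit_set = {c.case_id for c in cases if c.is_cancer and any(
        mark_hits_truth(c, m) for m in mark_map.get(c.case_id, ()))}

    def _hit(case: CaseRecord) -> bool:
        return case.case_id in hit_set

    # -- reader decisions -------------------------------------------
    decisions = {}
    for profile, rng in zip(config.readers, reader_rngs):
        for c in cases:
            u_pre, u_loc, u_post, u_misc = rng.random(4)
            case_marks = mark_map.get(c.case_id, ())
            if c.is_cancer:
                recall_pre = int(u_pre < profile.sens_pre)
                if recall_pre:
                    if u_loc < profile.localization_accuracy:
                        lat, quad = c.truth_laterality, c.truth_quadrant
                    else:
                        others = [q for q in _CANCER_QUADRANTS
                                  if q != c.truth_quadrant]
                        lat = c.truth_laterality
                        quad = others[int(u_misc * len(others)) % len(others)]
                else:
                    lat, quad = "none", "none"
            else:
                recall_pre = int(u_pre < profile.fp_prob_pre)
                if recall_pre:
                    lat = "L" if u_misc < 0.5 else "R"
                    quad = _CANCER_QUADRANTS[int(u_loc * 5) % 5]
                else:
                    lat, quad = "none", "none"
            pre = ReaderDecision(profile.reader_id, c.case_id, "pre",
                                 recall_pre, lat, quad)

            if recall_pre:
                if not case_marks and u_post < profile.reversal_prob:
                    post = ReaderDecision(profile.reader_id, c.case_id,
                                          "post", 0)
                else:
                    post = ReaderDecision(profile.reader_id, c.case_id,
                                          "post", 1, lat, quad)
            else:
                if _hit(c) and u_post < profile.compliance_correct:
                    post = ReaderDecision(profile.reader_id, c.case_id, "post",
                                          1, c.truth_laterality,
                                          c.truth_quadrant)
                elif (not _hit(c)) and case_marks and \
                        u_post < profile.compliance_false:
                    best = max(case_marks, key=lambda m: m.neuscore)
                    post = ReaderDecision(profile.reader_id, c.case_id, "post",
                                          1, best.laterality,
                                          quadrant_from_box(best.box))
                else:
                    post = ReaderDecision(profile.reader_id, c.case_id,
                                          "post", 0)
            decisions[(profile.reader_id, c.case_id, "pre")] = pre
            decisions[(profile.reader_id, c.case_id, "post")] = post

    return StudyMatrix(
        readers=tuple(p.reader_id for p in config.readers),
        cases=tuple(cases), decisions=decisions, marks=mark_map)


# ------------------------------------------------------- cohort generation

@dataclass(frozen=True)
class CohortConfig:
    """Stage counts of the cohort filtering ladder; defaults match the
    published accounting exactly."""

    total_patients: int = datasets.COHORT_TOTAL_PATIENTS
    cancer_biopsy: int = datasets.COHORT_CANCER_BIOPSY
    benign_biopsy: int = datasets.COHORT_BENIGN_BIOPSY
    both_biopsy: int = datasets.COHORT_BOTH_BIOPSY
    with_priors: int = datasets.COHORT_WITH_PRIORS
    retrospective: int = datasets.COHORT_RETROSPECTIVE
    actionable: int = datasets.COHORT_ACTIONABLE
    non_actionable: int = datasets.COHORT_NON_ACTIONABLE
    excluded: int = datasets.COHORT_EXCLUDED
    actionable_exams: int = datasets.COHORT_ACTIONABLE_EXAMS
    prior_gap_days: Tuple[int, int] = datasets.PRIOR_GAP_DAYS

    def validate(self) -> None:
        if self.cancer_biopsy + self.benign_biopsy - self.both_biopsy \
                != self.total_patients:
            raise ConfigError("cancer + benign - both must equal total")
        if self.both_biopsy > min(self.cancer_biopsy, self.benign_biopsy):
            raise ConfigError("both-biopsy count exceeds a margin")
        if self.with_priors > self.cancer_biopsy:
            raise ConfigError("with_priors exceeds cancer-biopsy count")
        if self.retrospective > self.with_priors:
            raise ConfigError("retrospective exceeds with-priors count")
        if self.actionable + self.non_actionable + self.excluded \
                != self.retrospective:
            raise ConfigError(
                "actionable + non_actionable + excluded must equal "
                "retrospective")
        if self.actionable_exams < self.actionable:
            raise ConfigError("need at least one actionable exam per patient")
        lo, hi = self.prior_gap_days
        if not (270 < lo <= hi):
            raise ConfigError("prior gaps must lie strictly above 270 days")

    @property
    def de_novo(self) -> int:
        return self.with_priors - self.retrospective


def generate_cohort(config: Optional[CohortConfig] = None,
                    seed: int = 0) -> Tuple[CohortRecord, ...]:
    """Generate a cohort whose ladder counts match the config exactly."""
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    biopsy = dt.date(2016, 6, 1)
    lo, hi = config.prior_gap_days
    records = []
    width = len(str(config.total_patients))
    pid_iter = (f"pt{str(i + 1).zfill(width)}"
                for i in range(config.total_patients))

    # actionable patients get 1-2 flagged priors, totalling
    # config.actionable_exams across the group
    extra = config.actionable_exams - config.actionable
    cancer_ids = [next(pid_iter) for _ in range(config.cancer_biopsy)]
    idx = 0

    def _prior(pid: str, n: int, flagged: bool) -> Tuple[ExamEntry, ...]:
        gaps = sorted(set(int(g) for g in rng.integers(lo, hi + 1, size=4 * n)))
        while len(gaps) < n:  # extremely unlikely unless the range is tiny
            gaps.append(gaps[-1] + 1)
        gaps = gaps[:n]
        exams = [ExamEntry(exam_id=f"{pid}_p{j + 1}",
                           exam_date=biopsy - dt.timedelta(days=g),
                           retrospective_finding=flagged)
                 for j, g in enumerate(gaps)]
        exams.append(ExamEntry(exam_id=f"{pid}_cur",
                               exam_date=biopsy - dt.timedelta(
                                   days=int(rng.integers(0, 200))),
                               retrospective_finding=False))
        return tuple(exams)

    def _outcomes(i: int) -> frozenset:
        return (frozenset({"cancer", "benign"}) if i < config.both_biopsy
                else frozenset({"cancer"}))

    for j in range(config.actionable):
        pid = cancer_ids[idx]
        n_priors = 2 if j < extra else 1
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=_outcomes(idx),
            biopsy_date=biopsy, exams=_prior(pid, n_priors, True),
            retrospective_finding=True, category="actionable"))
        idx += 1
    for j in range(config.non_actionable):
        pid = cancer_ids[idx]
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=_outcomes(idx),
            biopsy_date=biopsy, exams=_prior(pid, 1, True),
            retrospective_finding=True, category="non_actionable"))
        idx += 1
    for j in range(config.excluded):
        pid = cancer_ids[idx]
        reason = ("ipsilateral_prior_lumpectomy", "tomo_or_synthesized")[j % 2]
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=_outcomes(idx),
            biopsy_date=biopsy, exams=_prior(pid, 1, True),
            retrospective_finding=True, category="excluded",
            excluded_reason=reason))
        idx += 1
    for j in range(config.de_novo):
        pid = cancer_ids[idx]
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=_outcomes(idx),
            biopsy_date=biopsy, exams=_prior(pid, 1, False),
            retrospective_finding=False, category="de_novo"))
        idx += 1
    while idx < config.cancer_biopsy:  # cancer patients without priors
        pid = cancer_ids[idx]
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=_outcomes(idx),
            biopsy_date=biopsy,
            exams=(ExamEntry(exam_id=f"{pid}_cur",
                             exam_date=biopsy - dt.timedelta(
                                 days=int(rng.integers(0, 200)))),),
            retrospective_finding=False))
        idx += 1
    for _ in range(config.benign_biopsy - config.both_biopsy):
        pid = next(pid_iter)
        records.append(CohortRecord(
            patient_id=pid, biopsy_outcomes=frozenset({"benign"}),
            biopsy_date=biopsy,
            exams=(ExamEntry(exam_id=f"{pid}_cur",
                             exam_date=biopsy - dt.timedelta(
                                 days=int(rng.integers(0, 200)))),)))
    return tuple(records)
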