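"""Model/Results surface tying the analysis stages together.

:class:`ReaderStudy` wraps a validated study (readers × cases ×
{pre, post} decisions plus CAD marks); :meth:`ReaderStudy.fit` runs the
full before/after comparison and returns a :class:`ReaderStudyResults`
carrying per-reader metrics, group summaries, density-stratified t
tests, the four ROC curves (pooled pre/post, theoretical readers,
stand-alone CAD) and the AUC change. Resampling inference hangs off
the results object via :meth:`ReaderStudyResults.bootstrap`.

    study = ReaderStudy.from_csv("cases.csv", "decisions.csv", "marks.csv")
    res = study.fit()
    print(res.summary())
    boot = res.bootstrap(axis="case", n_boot=10_000, seed=7)
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional

import pandas as pd

from . import bootstrap as _bootstrap
from . import metrics as _metrics
from . import roc as _roc
from ._format import round_half_away
from .io import StudyMatrix, load_study
from .simulate import SimulationConfig, generate_study


class ReaderStudy:
    """A sequential CAD reader study ready to be analysed."""

    def __init__(self, matrix: StudyMatrix):
        self.matrix = matrix

    @classmethod
    def from_csv(cls, cases_path, decisions_path, marks_path) -> "ReaderStudy":
        return cls(load_study(cases_path, decisions_path, marks_path))

    @classmethod
    def from_simulation(cls, config: Optional[SimulationConfig] = None,
                        seed: int = 0) -> "ReaderStudy":
        return cls(generate_study(config, seed))

    def fit(self, localization: bool = True,
            pooled_localization: bool = False,
            conversion_localization: bool = False) -> "ReaderStudyResults":
        """Run the full before/after analysis.

        ``localization`` controls the true-positive rule for per-reader
        CDRs and operating points; ``pooled_localization`` the variant
        used for the aggregate-score group ROC (default: raw recalls);
        ``conversion_localization`` the recall notion in the per-class
        conversion accounting.
        """
        return ReaderStudyResults(self, localization, pooled_localization,
                                  conversion_localization)


class ReaderStudyResults:
    """Computed estimates, curves and diagnostics of a fitted study."""

    def __init__(self, model: ReaderStudy, localization: bool,
                 pooled_localization: bool, conversion_localization: bool):
        self.model = model
        self.localization = localization
        self.pooled_localization = pooled_localization
        m = model.matrix

        self.reader_metrics: List[_metrics.ReaderMetrics] = \
            _metrics.all_reader_metrics(m, localization,
                                        conversion_localization)
        self.lesion_distribution = _metrics.lesion_distribution(m)
        self.density_deltas = _metrics.density_stratified_deltas(
            m, localization)
        self.density_tests: Dict[int, Dict[str, float]] = {}
        for density, deltas in self.density_deltas.items():
            try:
                t, p = _bootstrap.one_sample_t(deltas)
                self.density_tests[density] = {"t": t, "p": p}
            except ValueError:
                continue

        self.roc_pre = _roc.pooled_roc(m, "pre", pooled_localization)
        self.roc_post = _roc.pooled_roc(m, "post", pooled_localization)
        self.roc_theoretical = _roc.pooled_roc(
            _roc.theoretical_matrix(m), "post", pooled_localization)
        self.roc_standalone = _roc.standalone_roc(m)
        self.auc_pre = self.roc_pre.auc
        self.auc_post = self.roc_post.auc
        self.pct_change_auc = _roc.pct_change_auc(self.auc_pre, self.auc_post)

        self.operating_points = [
            _roc.reader_operating_point(m, r, p, localization)
            for r in m.readers for p in ("pre", "post")]

    # -- tabular views ---------------------------------------------

    def cdr_table(self) -> pd.DataFrame:
        rows = []
        for rm in self.reader_metrics:
            rows.append({"reader_id": rm.reader_id,
                         "cdr_pre": rm.cdr_pre, "cdr_post": rm.cdr_post,
                         "delta_cdr": rm.delta_cdr,
                         "pct_change_cdr": rm.pct_change_cdr})
        return pd.DataFrame(rows)

    def fp_table(self) -> pd.DataFrame:
        rows = []
        for rm in self.reader_metrics:
            rows.append({"reader_id": rm.reader_id, "fp_pre": rm.fp_pre,
                         "fp_increase": rm.fp_increase,
                         "fp_reduction": rm.fp_reduction,
                         "fp_post": rm.fp_post,
                         "fp_rate_change": rm.fp_rate_change})
        return pd.DataFrame(rows)

    def conversion_table(self, cls: str) -> pd.DataFrame:
        rows = []
        for rm in self.reader_metrics:
            cc = getattr(rm, cls)
            rows.append({"reader_id": rm.reader_id,
                         "recalled_pre": cc.recalled_pre,
                         "additional_recalled": cc.additional_recalled,
                         "ignored_flags": cc.ignored_flags})
        return pd.DataFrame(rows)

    def lesion_table(self) -> pd.DataFrame:
        rows = [{"lesion_components": ";".join(comps), "count": n}
                for comps, n in sorted(self.lesion_distribution.items(),
                                       key=lambda kv: (-kv[1], kv[0]))]
        return pd.DataFrame(rows)

    def group(self, metric: str) -> _metrics.GroupSummary:
        vals = []
        for rm in self.reader_metrics:
            v = getattr(rm, metric)
            if v is None:
                continue
            vals.append(v)
        return _metrics.group_summary(vals)

    def roc_points_frame(self) -> pd.DataFrame:
        frames = []
        for name, curve in (("pre", self.roc_pre), ("post", self.roc_post),
                            ("theoretical", self.roc_theoretical),
                            ("standalone_cad", self.roc_standalone)):
            frames.append(pd.DataFrame({
                "curve_id": name, "threshold": curve.thresholds,
                "fpr": curve.fpr, "tpr": curve.tpr}))
        return pd.concat(frames, ignore_index=True)

    # -- inference --------------------------------------------------

    def bootstrap(self, axis: str, n_boot: int = 10_000,
                  seed: Optional[int] = None,
                  ci_level: float = 0.99) -> _bootstrap.BootstrapResult:
        """Bootstrap the pooled-AUC change along the case or reader axis
        (uses the same pooled-score variant as the fit)."""
        return _bootstrap.bootstrap_auc_change(
            self.model.matrix, axis, n_boot=n_boot, seed=seed,
            ci_level=ci_level, localization=self.pooled_localization)

    # -- reporting --------------------------------------------------

    def to_dict(self) -> dict:
        def cs(metric: str, nd: int = 1) -> dict:
            g = self.group(metric)
            return {"mean": round_half_away(g.mean, nd),
                    "min": round_half_away(g.min, nd),
                    "max": round_half_away(g.max, nd)}

        return {
            "n_readers": self.model.matrix.n_readers,
            "n_cancer": len(self.model.matrix.cancer_cases()),
            "n_normal": len(self.model.matrix.normal_cases()),
            "localization": self.localization,
            "pooled_localization": self.pooled_localization,
            "readers": [
                {"reader_id": rm.reader_id,
                 "cdr_pre": rm.cdr_pre, "cdr_post": rm.cdr_post,
                 "delta_cdr": rm.delta_cdr,
                 "pct_change_cdr": rm.pct_change_cdr,
                 "fp_pre": rm.fp_pre, "fp_increase": rm.fp_increase,
                 "fp_reduction": rm.fp_reduction, "fp_post": rm.fp_post,
                 "fp_rate_change": rm.fp_rate_change,
                 "calc": rm.calc.__dict__, "mass": rm.mass.__dict__}
                for rm in self.reader_metrics],
            "group": {
                "cdr_pre_pct": cs("cdr_pre"), "cdr_post_pct": cs("cdr_post"),
                "delta_cdr_points": cs("delta_cdr"),
                "pct_change_cdr": cs("pct_change_cdr"),
                "fp_rate_change": cs("fp_rate_change", 2),
            },
            "density_tests": {str(k): v for k, v in self.density_tests.items()},
            "auc": {"pre": self.auc_pre, "post": self.auc_post,
                    "theoretical": self.roc_theoretical.auc,
                    "standalone_cad": self.roc_standalone.auc,
                    "pct_change": self.pct_change_auc},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def summary(self) -> str:
        """Human-readable report mirroring the study's table layout:
        lesion distribution, per-reader CDR, false-positive recalls,
        per-class conversion accounting, and the pooled ROC section."""
        m = self.model.matrix
        lines = []
        lines.append("Sequential CAD reader study")
        lines.append("=" * 64)
        lines.append(f"readers: {m.n_readers}   "
                     f"cancer cases: {len(m.cancer_cases())}   "
                     f"normal cases: {len(m.normal_cases())}")
        lines.append(f"true-positive rule: "
                     f"{'localization-aware' if self.localization else 'case-level'}")
        lines.append("")
        lines.append("Lesion distribution (cancer cases)")
        for comps, n in sorted(self.lesion_distribution.items(),
                               key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"  {' + '.join(comps):<52}{n:>4}")
        lines.append("")
        lines.append("Cancer detection rate (per-case sensitivity)")
        lines.append(f"  {'reader':<10}{'pre':>6}{'post':>6}{'delta':>7}"
                     f"{'%change':>9}")
        for rm in self.reader_metrics:
            pc = (f"{round_half_away(rm.pct_change_cdr):.0f}%"
                  if rm.pct_change_cdr is not None else "n/a")
            lines.append(
                f"  {rm.reader_id:<10}"
                f"{round_half_away(100 * rm.cdr_pre):>5.0f}%"
                f"{round_half_away(100 * rm.cdr_post):>5.0f}%"
                f"{round_half_away(rm.delta_cdr):>6.0f}%"
                f"{pc:>9}")
        g_pre, g_post = self.group("cdr_pre"), self.group("cdr_post")
        g_d, g_pc = self.group("delta_cdr"), self.group("pct_change_cdr")
        lines.append(
            f"  {'average':<10}"
            f"{round_half_away(100 * g_pre.mean):>5.0f}%"
            f"{round_half_away(100 * g_post.mean):>5.0f}%"
            f"{round_half_away(g_d.mean):>6.0f}%"
            f"{round_half_away(g_pc.mean):>8.0f}%")
        lines.append("")
        lines.append("False-positive recalls (normal cases)")
        lines.append(f"  {'reader':<10}{'pre':>5}{'inc':>5}{'red':>5}"
                     f"{'post':>6}{'rate':>8}")
        for rm in self.reader_metrics:
            lines.append(f"  {rm.reader_id:<10}{rm.fp_pre:>5}"
                         f"{rm.fp_increase:>5}{rm.fp_reduction:>5}"
                         f"{rm.fp_post:>6}"
                         f"{round_half_away(rm.fp_rate_change):>7.0f}%")
        gfp = self.group("fp_rate_change")
        lines.append(f"  {'average':<10}{'':>21}"
                     f"{round_half_away(gfp.mean, 2):>7.2f}%")
        lines.append("")
        for cls, label in (("calc", "calcification"), ("mass", "mass")):
            tab = self.conversion_table(cls)
            lines.append(f"Decision accounting, {label}-leading cancers")
            lines.append(f"  {'reader':<10}{'recalled':>9}{'additional':>11}"
                         f"{'ignored':>9}")
            for row in tab.itertuples(index=False):
                lines.append(f"  {row.reader_id:<10}{row.recalled_pre:>9}"
                             f"{row.additional_recalled:>11}"
                             f"{row.ignored_flags:>9}")
            lines.append(
                f"  {'average':<10}"
                f"{round_half_away(tab.recalled_pre.mean(), 1):>9}"
                f"{round_half_away(tab.additional_recalled.mean(), 1):>11}"
                f"{round_half_away(tab.ignored_flags.mean(), 1):>9}")
            lines.append("")
        lines.append("Pooled readers-as-a-group ROC (aggregate 0-R score)")
        lines.append(f"  AUC pre:          {self.auc_pre:.4f}")
        lines.append(f"  AUC post:         {self.auc_post:.4f}")
        lines.append(f"  AUC theoretical:  {self.roc_theoretical.auc:.4f}")
        lines.append(f"  AUC stand-alone:  {self.roc_standalone.auc:.4f}")
        lines.append(f"  % change in AUC:  "
                     f"{round_half_away(self.pct_change_auc, 1):.1f}%")
        if self.density_tests:
            lines.append("")
            lines.append("Density-stratified CDR change (one-sample t)")
            for density, res in sorted(self.density_tests.items()):
                lines.append(f"  density {density}: t = {res['t']:.3f}, "
                             f"p = {res['p']:.3f}")
        return "\n".join(lines)
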