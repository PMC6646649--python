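"""Bootstrap significance of the pooled-AUC change, and the one-sample
t test on per-reader deltas.

Two resampling axes probe two sources of variability:

* ``case`` — resample the cases with replacement (difficulty mix);
  replicates that draw a single truth class are redrawn, and the
  redraw count is reported.
* ``reader`` — resample the reader panel with replacement (experience
  mix); a reader drawn twice contributes twice to the aggregate score,
  which keeps the score range [0, R].

Each replicate rebuilds the per-case aggregate recall scores, computes
the pooled AUC before and after CAD, and records the relative AUC
change in percent. The default report is the normal-approximation CI
[mu - z*sigma, mu + z*sigma] with z = 2.58 at the 99% level (the
percentile CI is carried alongside), and "significant" means 0 lies
outside the normal CI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .io import StudyMatrix, PHASES
from .metrics import UndefinedMetricError, is_true_positive
from .roc import pct_change_auc

# z = 2.58 exactly at the 99% level, as conventionally printed.
_Z_99 = 2.58


@dataclass
class BootstrapResult:
    """Point estimate and resample-distribution summary of the relative
    pooled-AUC change (percent)."""

    axis: str
    n_boot: int
    seed: Optional[int]
    ci_level: float
    z: float
    point_estimate: float
    sample_mean: float
    sample_sd: float
    ci_normal: Tuple[float, float]
    ci_percentile: Tuple[float, float]
    n_degenerate_redraws: int
    significant: int
    replicates: np.ndarray = field(repr=False, default=None)  # type: ignore

    def to_dict(self, include_replicates: bool = False) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "replicates"}
        d["ci_normal"] = list(self.ci_normal)
        d["ci_percentile"] = list(self.ci_percentile)
        if include_replicates:
            d["replicates"] = self.replicates.tolist()
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _decision_matrices(matrix: StudyMatrix, localization: bool
                       ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(D_pre, D_post) as R x C binary arrays plus the truth vector."""
    R, C = matrix.n_readers, matrix.n_cases
    D = {p: np.zeros((R, C), dtype=np.int64) for p in PHASES}
    truth = np.zeros(C, dtype=bool)
    for j, c in enumerate(matrix.cases):
        truth[j] = c.is_cancer
        for i, r in enumerate(matrix.readers):
            for p in PHASES:
                d = matrix.decision(r, c.case_id, p)
                if localization and c.is_cancer:
                    D[p][i, j] = is_true_positive(c, d)
                else:
                    D[p][i, j] = d.recall
    return D["pre"], D["post"], truth


def _auc_from_scores(scores: np.ndarray, truth: np.ndarray) -> float:
    """Tie-corrected rank AUC (midranks); equals the trapezoidal
    threshold-sweep AUC on the same scores."""
    n1 = int(truth.sum())
    n0 = truth.size - n1
    ranks = stats.rankdata(scores)
    return float((ranks[truth].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bootstrap_auc_change(matrix: StudyMatrix, axis: str,
                         n_boot: int = 10_000,
                         seed: Optional[int] = None,
                         ci_level: float = 0.99,
                         localization: bool = False) -> BootstrapResult:
    """Bootstrap the relative change in pooled AUC along one axis.

    Returns the full replicate vector so histograms can be drawn from
    the result. Same seed, same result, bit for bit.
    """
    if axis not in ("case", "reader"):
        raise ValueError(f"axis must be 'case' or 'reader', got {axis!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    D_pre, D_post, truth = _decision_matrices(matrix, localization)
    R, C = D_pre.shape
    if truth.all() or not truth.any():
        raise UndefinedMetricError("bootstrap requires both truth classes")
    if axis == "reader" and R < 2:
        raise UndefinedMetricError("reader-axis bootstrap needs >= 2 readers")

    s_pre = D_pre.sum(axis=0)
    s_post = D_post.sum(axis=0)
    point = pct_change_auc(_auc_from_scores(s_pre, truth),
                           _auc_from_scores(s_post, truth))

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        if axis == "case":
            while True:
                idx = rng.integers(0, C, C)
                t = truth[idx]
                if t.any() and not t.all():
                    break
                n_redraws += 1
            sp, sq = s_pre[idx], s_post[idx]
        else:
            ridx = rng.integers(0, R, R)
            t = truth
            sp = D_pre[ridx].sum(axis=0)
            sq = D_post[ridx].sum(axis=0)
        reps[b] = pct_change_auc(_auc_from_scores(sp, t),
                                 _auc_from_scores(sq, t))

    mu = float(reps.mean())
    sigma = float(reps.std(ddof=1)) if n_boot > 1 else 0.0
    z = _Z_99 if ci_level == 0.99 else float(stats.norm.ppf((1 + ci_level) / 2))
    ci_norm = (mu - z * sigma, mu + z * sigma)
    alpha = (1.0 - ci_level) / 2.0
    ci_pct = tuple(np.quantile(reps, [alpha, 1.0 - alpha]).tolist())
    significant = int(not (ci_norm[0] <= 0.0 <= ci_norm[1]))
    return BootstrapResult(
        axis=axis, n_boot=n_boot, seed=seed, ci_level=ci_level, z=z,
        point_estimate=point, sample_mean=mu, sample_sd=sigma,
        ci_normal=ci_norm, ci_percentile=ci_pct,
        n_degenerate_redraws=n_redraws, significant=significant,
        replicates=reps)


def one_sample_t(deltas: Sequence[float]) -> Tuple[float, float]:
    """Two-sided one-sample Student t test against a zero mean.

    t = mean / (sd / sqrt(n)) on n-1 degrees of freedom; the p-value is
    the symmetric t-distribution tail probability. Degenerate
    zero-variance samples short-circuit: p = 1 for a zero mean, p = 0
    otherwise, each with a warning.
    """
    x = np.asarray(list(deltas), dtype=float)
    if x.size < 2:
        raise ValueError("t test needs at least two observations")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            warnings.warn("zero variance and zero mean: p = 1", stacklevel=2)
            return 0.0, 1.0
        warnings.warn("zero variance with nonzero mean: p = 0", stacklevel=2)
        return float(np.sign(mean)) * float("inf"), 0.0
    t = mean / (sd / np.sqrt(x.size))
    p = 2.0 * float(stats.t.sf(abs(t), df=x.size - 1))
    return float(t), p
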