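"""Inter-rater agreement statistics over sorts and scale scores.

Two families of statistics:

* intraclass correlation for a subjects x raters matrix of one scale's
  scores, in the two-way random-effects, absolute-agreement forms
  ICC(2,1) (single rater) and ICC(2,k) (mean of k raters);
* Q-correlation between two complete sorts, computed across the 150
  paired item ranks.

`reliability_experiment` wires these to the simulator: it generates a
rater panel, scores every sort, and reports agreement per scale — the
study design used to establish the instrument's reliability, runnable at
any noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .item_bank import ItemBank
from .qsort import (
    DEFAULT_DISTRIBUTION,
    ForcedDistribution,
    QSort,
    to_rank_vector,
    validate_sort,
)
from .scoring import SCALE_NAMES, full_profile
from .simulate import LatentProfile, RaterModel, RaterPanel, rater_panel

__all__ = [
    "ScoreMatrix",
    "AgreementResult",
    "icc",
    "q_correlation",
    "reliability_experiment",
    "panel_score_matrix",
]

ICC_FORMS = ("ICC(2,1)", "ICC(2,k)")

#: Tolerance below which total variance counts as degenerate.
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class ScoreMatrix:
    """Subjects x raters grid of one scale's scores."""

    values: np.ndarray
    scale: str = ""
    subject_labels: tuple[str, ...] = ()
    rater_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("score matrix must be 2-dimensional")
        if np.isnan(arr).any():
            raise ValueError("score matrix must have no missing cells")
        object.__setattr__(self, "values", arr)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_csv(cls, path, scale: str = "") -> "ScoreMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), scale=scale,
                   subject_labels=tuple(map(str, df.index)),
                   rater_labels=tuple(map(str, df.columns)))

    def to_csv(self, path) -> None:
        subj = self.subject_labels or [f"s{i}" for i in range(self.n_subjects)]
        rat = self.rater_labels or [f"r{j}" for j in range(self.n_raters)]
        pd.DataFrame(self.values, index=list(subj),
                     columns=list(rat)).to_csv(path, index_label="subject")


@dataclass(frozen=True)
class AgreementResult:
    statistic: str
    estimate: float
    n_subjects: int
    n_raters: int
    flags: tuple[str, ...] = ()
    components: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.estimate <= 1.0 + 1e-9):
            raise ValueError(
                f"agreement estimate outside [-1, 1]: {self.estimate}"
            )


def _mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares: rows (subjects), columns (raters),
    residual."""
    n, k = x.shape
    gm = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - gm) ** 2).sum())
    ssc = n * float(((col_means - gm) ** 2).sum())
    sst = float(((x - gm) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse, 0.0) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(matrix: ScoreMatrix, form: str = "ICC(2,1)") -> AgreementResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    With n subjects, k raters and mean squares MSR (subjects), MSC
    (raters), MSE (residual):

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    A matrix with (numerically) zero total variance carries no
    disagreement information and returns 1 with a ``degenerate`` flag.
    Negative estimates are reported as computed, flagged ``negative``.
    """
    if form not in ICC_FORMS:
        raise ValueError(f"unknown ICC form {form!r}; expected {ICC_FORMS}")
    x = matrix.values
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs >=2 subjects and >=2 raters, got {n}x{k}")
    if float(((x - x.mean()) ** 2).sum()) <= _DEGENERATE_TOL:
        return AgreementResult(statistic=form, estimate=1.0, n_subjects=n,
                               n_raters=k, flags=("degenerate",),
                               components={"MSR": 0.0, "MSC": 0.0, "MSE": 0.0})
    msr, msc, mse = _mean_squares(x)
    if form == "ICC(2,1)":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (msc - mse) / n
    est = (msr - mse) / denom
    est = float(np.clip(est, -1.0, 1.0))
    flags = ("negative",) if est < 0 else ()
    return AgreementResult(statistic=form, estimate=est, n_subjects=n,
                           n_raters=k, flags=flags,
                           components={"MSR": msr, "MSC": msc, "MSE": mse})


def q_correlation(a: QSort, b: QSort, method: str = "linear",
                  dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                  ) -> AgreementResult:
    """Correlation between two complete sorts across paired item ranks.

    ``linear`` is Pearson on the rank values; ``rank`` is Spearman.
    For two valid sorts of the same distribution both rank vectors hold
    the same multiset of values, so the statistic measures profile
    similarity, reaching 1 only for identical sorts.
    """
    if method not in ("linear", "rank"):
        raise ValueError(f"method must be 'linear' or 'rank', got {method!r}")
    for name, s in (("a", a), ("b", b)):
        rep = validate_sort(s, dist)
        if not rep.ok:
            raise ValueError(f"sort {name} is invalid: "
                             + "; ".join(rep.violations))
    if set(a.assignment) != set(b.assignment):
        raise ValueError("sorts cover different item sets")
    va = np.array(to_rank_vector(a, dist), float)
    vb = np.array(to_rank_vector(b, dist), float)
    if method == "linear":
        est = float(stats.pearsonr(va, vb).statistic)
    else:
        est = float(stats.spearmanr(va, vb).statistic)
    return AgreementResult(statistic=f"Q-correlation ({method})",
                           estimate=float(np.clip(est, -1.0, 1.0)),
                           n_subjects=1, n_raters=2)


def panel_score_matrix(panel: RaterPanel, scale: str, bank: ItemBank,
                       dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                       ) -> ScoreMatrix:
    """Score every sort in the panel and extract one scale as a matrix."""
    vals = np.empty((panel.n_subjects, panel.n_raters))
    for (s, r), qs in panel.sorts.items():
        vals[s, r] = full_profile(qs, bank, dist).get_scale(scale)
    return ScoreMatrix(
        values=vals, scale=scale,
        subject_labels=tuple(f"s{i}" for i in range(panel.n_subjects)),
        rater_labels=tuple(f"r{j}" for j in range(panel.n_raters)),
    )


def reliability_experiment(profiles: Sequence[LatentProfile],
                           raters: Sequence[RaterModel],
                           bank: ItemBank,
                           scales: Sequence[str] = ("ODF",),
                           form: str = "ICC(2,1)",
                           dist: ForcedDistribution = DEFAULT_DISTRIBUTION,
                           panel: Optional[RaterPanel] = None,
                           ) -> pd.DataFrame:
    """Simulate a panel, score all sorts, and report ICC per scale.

    Returns a DataFrame with columns scale, statistic, estimate,
    n_subjects, n_raters, flags.  Fully reproducible from the rater
    seeds; pass *panel* to reuse an already-generated panel.
    """
    unknown = [s for s in scales if s not in SCALE_NAMES]
    if unknown:
        raise ValueError(f"unknown scales: {unknown}")
    if panel is None:
        panel = rater_panel(profiles, raters, dist=dist, bank=bank)
    rows = []
    for scale in scales:
        m = panel_score_matrix(panel, scale, bank, dist)
        res = icc(m, form=form)
        rows.append({"scale": scale, "statistic": res.statistic,
                     "estimate": res.estimate,
                     "n_subjects": res.n_subjects,
                     "n_raters": res.n_raters,
                     "flags": ";".join(res.flags)})
    return pd.DataFrame(rows)
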