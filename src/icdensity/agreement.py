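"""Single-rating two-way random-effects intraclass correlation coefficients.

Two forms are implemented, both from the mean squares of the two-way
(subjects × raters) ANOVA layout without replication:

* absolute agreement, ICC(A,1): systematic offsets between raters count as
  disagreement;
* consistency, ICC(C,1): per-rater constant offsets are ignored.

Estimates are reported as computed, including negative values (a negative
ICC simply means the between-subject mean square falls below the residual).
Confidence intervals follow the conventional F-based constructions: an
exact F interval for the consistency form, and a Satterthwaite-
approximated-df interval for absolute agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DegenerateTableError",
    "MeanSquares",
    "ICCResult",
    "anova_mean_squares",
    "icc_single_absolute",
    "icc_single_consistency",
    "classify_reliability",
    "read_ratings_csv",
]


class DegenerateTableError(ValueError):
    """All cells identical: every variance component is zero and the ICC is undefined."""


@dataclass(frozen=True)
class MeanSquares:
    """Two-way ANOVA decomposition of a complete subjects × raters table."""

    ms_subjects: float
    ms_raters: float
    ms_error: float
    ss_subjects: float
    ss_raters: float
    ss_error: float
    ss_total: float
    n_subjects: int
    n_raters: int


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    model: str  # "ICC(A,1)" or "ICC(C,1)"
    alpha: float
    mean_squares: MeanSquares

    @property
    def label(self) -> str:
        return classify_reliability(self.estimate)


def _as_table(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        x = table.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings table must be 2-dimensional (subjects × raters)")
    if np.isnan(x).any():
        raise ValueError("ratings table has missing cells; no imputation is performed")
    n, r = x.shape
    if n < 2 or r < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n}×{r}")
    return x


def anova_mean_squares(table) -> MeanSquares:
    """Row (subject), column (rater) and residual mean squares.

    The layout has one observation per cell, so the residual is the
    subject × rater interaction; SS_total = SS_subjects + SS_raters +
    SS_error holds exactly.
    """
    x = _as_table(table)
    n, r = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_subjects = r * float(((row_means - grand) ** 2).sum())
    ss_raters = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_error = float((resid**2).sum())
    return MeanSquares(
        ms_subjects=ss_subjects / (n - 1),
        ms_raters=ss_raters / (r - 1),
        ms_error=ss_error / ((n - 1) * (r - 1)),
        ss_subjects=ss_subjects,
        ss_raters=ss_raters,
        ss_error=ss_error,
        ss_total=ss_total,
        n_subjects=n,
        n_raters=r,
    )


def _check_not_degenerate(ms: MeanSquares) -> None:
    if ms.ss_total == 0.0:
        raise DegenerateTableError(
            "all ratings identical: ICC undefined (zero total variance)"
        )


def icc_single_consistency(table, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1): single-rating, consistency, two-way random effects.

    estimate = (MS_S − MS_E) / (MS_S + (r−1)·MS_E); the CI comes from the
    exact distribution of F = MS_S / MS_E with df (n−1) and (n−1)(r−1).
    """
    ms = anova_mean_squares(table)
    _check_not_degenerate(ms)
    n, r = ms.n_subjects, ms.n_raters
    msr, mse = ms.ms_subjects, ms.ms_error
    if mse == 0.0:
        # raters agree perfectly (up to additive shifts absorbed in MS_raters)
        est, lower, upper = 1.0, 1.0, 1.0
    else:
        est = (msr - mse) / (msr + (r - 1) * mse)
        df1, df2 = n - 1, (n - 1) * (r - 1)
        fstat = msr / mse
        fl = fstat / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + r - 1)
        upper = (fu - 1) / (fu + r - 1)
    return ICCResult(float(est), float(lower), float(upper), "ICC(C,1)", alpha, ms)


def icc_single_absolute(table, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): single-rating, absolute agreement, two-way random effects.

    estimate = (MS_S − MS_E) / (MS_S + (r−1)·MS_E + (r/n)(MS_R − MS_E)).
    The CI uses the Satterthwaite-approximated denominator df of
    McGraw & Wong's construction.
    """
    ms = anova_mean_squares(table)
    _check_not_degenerate(ms)
    n, r = ms.n_subjects, ms.n_raters
    msr, msc, mse = ms.ms_subjects, ms.ms_raters, ms.ms_error
    denom = msr + (r - 1) * mse + (r / n) * (msc - mse)
    if denom == 0.0:
        raise DegenerateTableError("zero denominator: ICC(A,1) undefined")
    est = (msr - mse) / denom
    if mse == 0.0 and msc == 0.0:
        lower = upper = 1.0
    else:
        a = (r * est) / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + (r * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
        if np.isinf(a):
            v = r - 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (r - 1) + (b * mse) ** 2 / ((n - 1) * (r - 1))
            v = num / den if den > 0 else r - 1.0
        fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
        fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (
            n * (msr - fl * mse)
            / (fl * (r * msc + (r * n - r - n) * mse) + n * msr)
        )
        upper = (
            n * (fu * msr - mse)
            / (r * msc + (r * n - r - n) * mse + n * fu * msr)
        )
    return ICCResult(float(est), float(lower), float(upper), "ICC(A,1)", alpha, ms)


def classify_reliability(estimate: float) -> str:
    """Conventional qualitative bands: poor < 0.50 ≤ moderate < 0.75 ≤ good
    ≤ 0.90 < excellent; negative estimates are poor."""
    if estimate < 0.50:
        return "poor"
    if estimate < 0.75:
        return "moderate"
    if estimate <= 0.90:
        return "good"
    return "excellent"


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Wide ratings table: first column subject id, one column per rater."""
    frame = pd.read_csv(path)
    if frame.shape[1] < 3:
        raise ValueError("ratings CSV needs a subject column plus >= 2 rater columns")
    return frame.set_index(frame.columns[0])
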