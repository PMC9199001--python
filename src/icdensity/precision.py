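"""Confidence bands of the mean-ratio distribution and minimal sample size.

The band at level L for subset size k is mu ± t·SD, where mu and SD are the
mean and standard deviation of the pooled mean-ratio distribution and t is
the two-sided t quantile at level L (df = pooled count − 1; at the pooled
sizes involved, thousands of ratios, this is indistinguishable from the
normal quantile).  Note this is a *spread* band of the estimate
distribution, not a standard-error band of the mean: it answers "within
what relative error does a k-image estimate fall L% of the time?".

An estimate is acceptable when it is within a relative tolerance delta of
the true mean with the stated confidence: the band must lie inside
[1 − delta, 1 + delta].  The minimal sample size k_min is the smallest k
whose band satisfies that criterion (defaults delta = 0.30, level = 0.95).

Two routes are provided: enumeration of all subsets, and a closed-form
route built on the exact finite-population ratio sd; because every
participant's ratio distribution is centred at exactly 1, the pooled
variance is the participant average of the per-participant variances, so
the two routes agree to numerical precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .combinations import (
    MeanRatioDistribution,
    ZeroTrueMeanError,
    count_combinations,
    exact_ratio_sd,
    pooled_distribution,
)
from .dataset import ImageCountSet

DEFAULT_LEVELS = (0.80, 0.85, 0.90, 0.95)

__all__ = [
    "DEFAULT_LEVELS",
    "CIBand",
    "PrecisionCriterion",
    "SampleSizeResult",
    "ratio_ci",
    "band_table",
    "analytic_band_table",
    "minimal_sample_size",
    "sample_size_analysis",
    "analytic_minimal_sample_size",
]


@dataclass(frozen=True)
class CIBand:
    k: int
    level: float
    mu: float
    sd: float
    lower: float
    upper: float
    n: int

    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class PrecisionCriterion:
    """Acceptability rule: within ``delta`` of the true mean, ``level`` of the time."""

    delta: float = 0.30
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError(f"delta must be in (0,1), got {self.delta}")
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0,1), got {self.level}")

    def satisfied_by(self, band: CIBand) -> bool:
        return band.upper <= 1 + self.delta and band.lower >= 1 - self.delta


@dataclass
class SampleSizeResult:
    region: str
    criterion: PrecisionCriterion
    k_min: int | None
    bands: pd.DataFrame = field(repr=False)

    @property
    def achieved(self) -> bool:
        return self.k_min is not None

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "criterion": {"delta": self.criterion.delta, "level": self.criterion.level},
            "k_min": self.k_min if self.achieved else "not achieved",
        }


def _t_quantile(level: float, n: int) -> float:
    return float(stats.t.ppf(0.5 + level / 2.0, df=max(n - 1, 1)))


def ratio_ci(distribution: MeanRatioDistribution | np.ndarray, level: float,
             k: int | None = None) -> CIBand:
    """Spread band mu ± t·SD of a pooled ratio distribution at one level.

    SD uses the population convention (divisor N): the enumeration is the
    complete population of k-subset estimates, not a sample from it.
    """
    if isinstance(distribution, MeanRatioDistribution):
        ratios = distribution.ratios
        k = distribution.k
    else:
        ratios = np.asarray(distribution, dtype=float)
        if k is None:
            raise ValueError("k must be given when passing a bare ratio array")
    n = ratios.size
    if n < 2:
        raise ValueError("need at least 2 ratio values for a band")
    mu = float(ratios.mean())
    sd = float(ratios.std(ddof=0))
    t = _t_quantile(level, n)
    return CIBand(k=k, level=level, mu=mu, sd=sd,
                  lower=mu - t * sd, upper=mu + t * sd, n=n)


def _bands_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["region", "k", "level", "mu", "sd", "lower", "upper", "n"]
    )


def band_table(
    dataset: ImageCountSet,
    region: str,
    ks: Iterable[int] | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Enumeration-based band table over a k range, one row per (k, level)."""
    _, matrix = dataset.density_matrix(region)
    n_images = matrix.shape[1]
    if ks is None:
        ks = range(2, n_images)
    rows = []
    for k in ks:
        dist = pooled_distribution(dataset, region, k)
        for level in levels:
            band = ratio_ci(dist, level)
            rows.append(
                {"region": dist.region, "k": k, "level": level, "mu": band.mu,
                 "sd": band.sd, "lower": band.lower, "upper": band.upper, "n": band.n}
            )
    return _bands_frame(rows)


def analytic_band_table(
    dataset: ImageCountSet,
    region: str,
    ks: Iterable[int] | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> pd.DataFrame:
    """Closed-form band table: mu = 1 exactly, sd from the finite-population
    formula averaged (in variance) over participants with positive true mean."""
    pids, matrix = dataset.density_matrix(region)
    n_images = matrix.shape[1]
    rows_ok = [row for row in matrix if row.mean() > 0]
    if not rows_ok:
        raise ZeroTrueMeanError(f"no positive true mean in region {region!r}")
    if ks is None:
        ks = range(2, n_images)
    out = []
    region = region.strip().lower()
    for k in ks:
        var = float(np.mean([exact_ratio_sd(row, k) ** 2 for row in rows_ok]))
        sd = math.sqrt(var)
        n = len(rows_ok) * count_combinations(n_images, k)
        for level in levels:
            t = _t_quantile(level, n)
            out.append(
                {"region": region, "k": k, "level": level, "mu": 1.0, "sd": sd,
                 "lower": 1.0 - t * sd, "upper": 1.0 + t * sd, "n": n}
            )
    return _bands_frame(out)


def minimal_sample_size(
    bands: pd.DataFrame, criterion: PrecisionCriterion, region: str | None = None
) -> SampleSizeResult:
    """Smallest k whose band at the criterion's level lies in [1−delta, 1+delta].

    ``bands`` is a band table as produced by :func:`band_table`; it must
    contain the criterion's confidence level over a contiguous k range.
    """
    if bands.empty:
        raise ValueError("empty band table")
    sub = bands
    if region is not None:
        sub = sub.loc[sub["region"] == region.strip().lower()]
    sub = sub.loc[np.isclose(sub["level"], criterion.level)]
    if sub.empty:
        raise ValueError(
            f"band table has no rows at confidence level {criterion.level}"
        )
    sub = sub.sort_values("k")
    ks = sub["k"].to_numpy()
    if not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("band table must cover a contiguous k range")
    ok = (sub["upper"] <= 1 + criterion.delta) & (sub["lower"] >= 1 - criterion.delta)
    k_min = int(sub.loc[ok, "k"].iloc[0]) if ok.any() else None
    region_out = region or (sub["region"].iloc[0] if "region" in sub else "")
    return SampleSizeResult(
        region=str(region_out), criterion=criterion, k_min=k_min, bands=bands
    )


def sample_size_analysis(
    dataset: ImageCountSet,
    region: str,
    criterion: PrecisionCriterion = PrecisionCriterion(),
    ks: Iterable[int] | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
) -> SampleSizeResult:
    """Enumeration route end-to-end: band table plus k_min for one region."""
    levels = tuple(sorted(set(levels) | {criterion.level}))
    bands = band_table(dataset, region, ks, levels)
    return minimal_sample_size(bands, criterion, region)


def analytic_minimal_sample_size(
    dataset: ImageCountSet,
    region: str,
    criterion: PrecisionCriterion = PrecisionCriterion(),
    ks: Iterable[int] | None = None,
) -> SampleSizeResult:
    """Closed-form route: k_min from the exact finite-population ratio sd."""
    bands = analytic_band_table(dataset, region, ks, levels=(criterion.level,))
    return minimal_sample_size(bands, criterion, region)
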