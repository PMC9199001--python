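"""Evaluation of the "three representative images" selection approach.

Each observer picks 3 of a participant's 16 reference images; the mean
density of the 3, divided by the participant's true mean, is that
observer's ratio estimate.  Observer estimates are compared against the
reference distribution of *random* three-image estimates — the exhaustive
pooled enumeration of all C(16,3) = 560 combinations per participant:

* systematic bias: two-sample Student's (pooled-variance) t-test of the
  observer ratios against the random pool, Bonferroni-adjusted over the
  observer family;
* precision: variance-ratio F-test (two-sided p = 2·min(P(F≤f), P(F≥f))),
  Bonferroni-adjusted likewise;
* between-observer consistency: ICC(C,1) on the participants × observers
  ratio table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .agreement import ICCResult, icc_single_consistency
from .combinations import pooled_distribution
from .dataset import ImageCountSet

__all__ = [
    "SelectionError",
    "TestComparison",
    "observer_ratios",
    "compare_mean_to_random",
    "compare_variance_to_random",
    "representative_consistency",
    "comparison_report",
]


class SelectionError(ValueError):
    """An observer selection does not match the dataset."""


@dataclass(frozen=True)
class TestComparison:
    """One hypothesis test of an observer sample against the random pool."""

    statistic: float
    df: tuple[float, float] | float
    p_raw: float
    p_adjusted: float
    m_comparisons: int
    degenerate: bool = False


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def observer_ratios(
    selections: pd.DataFrame,
    dataset: ImageCountSet,
    region: str | None = None,
) -> pd.DataFrame:
    """Per observer × participant-region ratio estimates.

    ``selections`` is the long selections table
    (``observer_id, participant_id, region, image_id``).  Each
    observer-participant-region group must reference distinct, existing
    images.  Participant-regions with a zero true mean are dropped (their
    ratio is undefined).  Returns columns
    ``observer_id, participant_id, region, ratio``.
    """
    needed = {"observer_id", "participant_id", "region", "image_id"}
    if not needed.issubset(selections.columns):
        raise SelectionError(f"selections table needs columns {sorted(needed)}")
    sel = selections.copy()
    sel["region"] = sel["region"].astype(str).str.strip().str.lower()
    if region is not None:
        sel = sel.loc[sel["region"] == region.strip().lower()]
        if sel.empty:
            raise SelectionError(f"no selections for region {region!r}")

    dens = dataset.with_density()
    merged = sel.merge(
        dens[["participant_id", "region", "image_id", "density"]],
        on=["participant_id", "region", "image_id"],
        how="left",
    )
    if merged["density"].isna().any():
        bad = merged.loc[merged["density"].isna()].iloc[0]
        raise SelectionError(
            "selection references unknown image "
            f"{(bad['participant_id'], bad['region'], bad['image_id'])}"
        )
    dup = merged.duplicated(
        subset=["observer_id", "participant_id", "region", "image_id"], keep=False
    )
    if dup.any():
        raise SelectionError("selections contain repeated images within one group")

    true_means = dataset.true_means().set_index(["participant_id", "region"])[
        "true_mean"
    ]
    rows = []
    for (obs, pid, reg), grp in merged.groupby(
        ["observer_id", "participant_id", "region"], sort=False
    ):
        tm = true_means.loc[(pid, reg)]
        if tm <= 0:
            continue  # undefined ratio, excluded as elsewhere in the pipeline
        rows.append(
            {
                "observer_id": obs,
                "participant_id": pid,
                "region": reg,
                "ratio": float(grp["density"].mean() / tm),
            }
        )
    return pd.DataFrame(rows)


def compare_mean_to_random(
    observer_ratios_arr,
    random_ratios,
    m_comparisons: int = 3,
    welch: bool = False,
) -> TestComparison:
    """Student's t-test of observer ratio means against the random pool.

    Pooled-variance by default (``welch=True`` switches to the unequal-
    variance form).  A zero pooled variance makes the statistic undefined
    and is flagged rather than computed.
    """
    a = np.asarray(observer_ratios_arr, dtype=float)
    b = np.asarray(random_ratios, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
        return TestComparison(np.nan, np.nan, np.nan, np.nan, m_comparisons, True)
    res = stats.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df)
    p = float(res.pvalue)
    return TestComparison(
        float(res.statistic), df, p, _bonferroni(p, m_comparisons), m_comparisons
    )


def compare_variance_to_random(
    observer_ratios_arr, random_ratios, m_comparisons: int = 3
) -> TestComparison:
    """Variance-equality F-test of observer ratios against the random pool.

    F = var(observer) / var(random) with (n1−1, n2−1) df; the two-sided p
    is 2·min(P(F ≤ f), P(F ≥ f)).
    """
    a = np.asarray(observer_ratios_arr, dtype=float)
    b = np.asarray(random_ratios, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 entries")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        return TestComparison(np.nan, (a.size - 1, b.size - 1), np.nan, np.nan,
                              m_comparisons, True)
    f = va / vb
    df = (a.size - 1, b.size - 1)
    p = 2 * min(stats.f.cdf(f, *df), stats.f.sf(f, *df))
    p = min(1.0, float(p))
    return TestComparison(float(f), df, p, _bonferroni(p, m_comparisons), m_comparisons)


def representative_consistency(ratio_table: pd.DataFrame, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1) of the participants × observers ratio table.

    ``ratio_table`` may be wide (index participants, one column per
    observer) or the long output of :func:`observer_ratios` for a single
    region, which is pivoted; the table must be complete.
    """
    if {"observer_id", "participant_id", "ratio"}.issubset(ratio_table.columns):
        regions = set(ratio_table.get("region", pd.Series(["?"])))
        if len(regions) > 1:
            raise ValueError("pass ratios for a single region")
        wide = ratio_table.pivot(
            index="participant_id", columns="observer_id", values="ratio"
        )
    else:
        wide = ratio_table
    if wide.isna().any().any():
        raise ValueError("incomplete participants × observers ratio table")
    return icc_single_consistency(wide, alpha=alpha)


def comparison_report(
    dataset: ImageCountSet,
    selections: pd.DataFrame,
    region: str,
    k_reference: int = 3,
    m_comparisons: int | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> dict:
    """Full per-region report of the representative-image evaluation.

    The reference is the exhaustive pooled k-subset enumeration
    (all combinations of ``k_reference`` random images, every participant).
    The Bonferroni family defaults to the number of observers in the region.
    """
    random_pool = pooled_distribution(dataset, region, k_reference)
    ratios = observer_ratios(selections, dataset, region)
    if ratios.empty:
        raise SelectionError(f"no usable observer ratios in region {region!r}")
    observers = list(dict.fromkeys(ratios["observer_id"]))
    m = m_comparisons if m_comparisons is not None else len(observers)

    per_observer = {}
    for obs in observers:
        arr = ratios.loc[ratios["observer_id"] == obs, "ratio"].to_numpy()
        t_cmp = compare_mean_to_random(arr, random_pool.ratios, m, welch=welch)
        f_cmp = compare_variance_to_random(arr, random_pool.ratios, m)
        per_observer[obs] = {
            "n_participants": int(arr.size),
            "mean_ratio": float(arr.mean()),
            "sd_ratio": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "t": {
                "statistic": t_cmp.statistic,
                "p_raw": t_cmp.p_raw,
                "p_adjusted": t_cmp.p_adjusted,
                "degenerate": t_cmp.degenerate,
            },
            "f": {
                "statistic": f_cmp.statistic,
                "p_raw": f_cmp.p_raw,
                "p_adjusted": f_cmp.p_adjusted,
                "degenerate": f_cmp.degenerate,
            },
        }

    icc = representative_consistency(ratios, alpha=alpha)
    return {
        "region": region.strip().lower(),
        "k_reference": k_reference,
        "m_comparisons": m,
        "random": {
            "n": int(random_pool.n_total),
            "mean_ratio": float(random_pool.ratios.mean()),
            "sd_ratio": float(random_pool.ratios.std(ddof=1)),
        },
        "observers": per_observer,
        "consistency_icc": {
            "estimate": icc.estimate,
            "ci_lower": icc.ci_lower,
            "ci_upper": icc.ci_upper,
            "model": icc.model,
            "label": icc.label,
        },
    }
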