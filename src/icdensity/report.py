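"""Static figures for the pipeline outputs.

All plots are regenerable from the exported CSV/JSON tables alone; nothing
is drawn from hidden state.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .precision import PrecisionCriterion, SampleSizeResult

__all__ = ["plot_ratio_scatter", "plot_ci_bands", "plot_observer_comparison"]


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_ratio_scatter(
    ratios: pd.DataFrame,
    path: str | Path,
    region: str | None = None,
    max_points_per_k: int = 2000,
    seed: int = 0,
) -> Path:
    """Mean ratio vs number of images, one dot per combination.

    ``ratios`` is the long export table (columns ``k`` and ``ratio``); dense
    k levels are thinned to ``max_points_per_k`` points for plotting only.
    """
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for k, grp in ratios.groupby("k"):
        vals = grp["ratio"].to_numpy()
        if vals.size > max_points_per_k:
            vals = rng.choice(vals, size=max_points_per_k, replace=False)
        jitter = rng.uniform(-0.18, 0.18, size=vals.size)
        ax.plot(k + jitter, vals, ".", ms=2, alpha=0.25, color="tab:blue")
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xlabel("number of images in the estimate (k)")
    ax.set_ylabel("mean ratio (estimate / true mean)")
    title = "Mean ratios over all image combinations"
    if region:
        title += f" — {region} cornea"
    ax.set_title(title)
    return _save(fig, path)


def plot_ci_bands(
    bands: pd.DataFrame,
    path: str | Path,
    criterion: PrecisionCriterion | None = None,
    result: SampleSizeResult | None = None,
    region: str | None = None,
) -> Path:
    """Confidence bands vs k with the precision criterion overlaid.

    Horizontal lines mark 1 ± delta; a vertical line marks k_min when the
    criterion is met.
    """
    sub = bands
    if region is not None:
        sub = sub.loc[sub["region"] == region.strip().lower()]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for level, grp in sub.groupby("level"):
        grp = grp.sort_values("k")
        ax.plot(grp["k"], grp["upper"], "-o", ms=3, label=f"{level:.0%}")
        ax.plot(grp["k"], grp["lower"], "-o", ms=3,
                color=ax.get_lines()[-1].get_color())
    if criterion is not None:
        ax.axhline(1 + criterion.delta, color="k", ls="--", lw=0.9)
        ax.axhline(1 - criterion.delta, color="k", ls="--", lw=0.9)
    if result is not None and result.achieved:
        ax.axvline(result.k_min, color="r", ls=":", lw=1.2,
                   label=f"k_min = {result.k_min}")
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xlabel("number of images in the estimate (k)")
    ax.set_ylabel("mean-ratio band (mu ± t·SD)")
    title = "Precision bands of the density estimate"
    if region:
        title += f" — {region} cornea"
    ax.set_title(title)
    ax.legend(title="confidence", fontsize=8)
    return _save(fig, path)


def plot_observer_comparison(report: dict, path: str | Path) -> Path:
    """Mean ratio ± 95% band for the random pool and each observer."""
    labels = ["random"] + list(report["observers"])
    means = [report["random"]["mean_ratio"]] + [
        o["mean_ratio"] for o in report["observers"].values()
    ]
    sds = [report["random"]["sd_ratio"]] + [
        o["sd_ratio"] for o in report["observers"].values()
    ]
    half = [1.96 * s for s in sds]
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(labels))
    ax.errorbar(x, means, yerr=half, fmt="o", capsize=5)
    ax.axhline(1.0, color="k", lw=0.8)
    ax.set_xticks(x, labels)
    ax.set_ylabel("mean ratio ± 1.96·SD")
    ax.set_title(f"Three-image estimates — {report['region']} cornea")
    return _save(fig, path)
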