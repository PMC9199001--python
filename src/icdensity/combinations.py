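"""Exhaustive k-subset enumeration of the mean-ratio statistic.

For a participant with n reference images, every unordered selection of k
images yields a density estimate (the subset mean); dividing by the full-set
("true") mean gives a dimensionless *mean ratio* centred exactly at 1.  With
n = 16 the total work over k = 2..15 is 2^16 − 18 subsets per
participant-region, so full enumeration is cheap and no Monte-Carlo
approximation is needed.  The exact finite-population standard deviation of
the ratio,

    sd(ratio) = (S / m) * sqrt(1/k − 1/n),

with S the sample sd (divisor n−1) of the n densities and m their mean,
serves as an independent closed-form oracle for the enumeration.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ImageCountSet

logger = logging.getLogger(__name__)

__all__ = [
    "ZeroTrueMeanError",
    "MeanRatioDistribution",
    "count_combinations",
    "subset_indices",
    "participant_mean_ratios",
    "exact_ratio_sd",
    "pooled_distribution",
    "ratios_to_frame",
]


class ZeroTrueMeanError(ValueError):
    """The full-set mean is zero, so the mean ratio is undefined."""


def count_combinations(n: int, k: int) -> int:
    """Number of unordered k-subsets of n items, as an exact integer."""
    if n < 0 or k < 0:
        raise ValueError(f"n and k must be non-negative, got n={n}, k={k}")
    if k > n:
        raise ValueError(f"k must not exceed n, got n={n}, k={k}")
    return math.comb(n, k)


@lru_cache(maxsize=None)
def subset_indices(n: int, k: int) -> np.ndarray:
    """All k-subsets of range(n) in lexicographic order, shape (C(n,k), k).

    The lexicographic enumeration order is part of the contract: exported
    combination indices are stable across runs and platforms.
    """
    count_combinations(n, k)  # argument validation
    if k == 0:
        return np.empty((1, 0), dtype=np.intp)
    arr = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), k)),
        dtype=np.intp,
        count=math.comb(n, k) * k,
    )
    arr = arr.reshape(-1, k)
    arr.setflags(write=False)
    return arr


def participant_mean_ratios(
    densities,
    k: int,
    max_combinations: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean ratio of every k-subset of one participant's densities.

    Returns one ratio per subset, in lexicographic order of the index
    subsets: (mean of the k subset densities) / (mean of all n densities).

    ``max_combinations`` optionally caps the enumeration with a seeded
    uniform subsample of subsets (useful only for n well above 16; off by
    default, and the full enumeration is always used when C(n,k) fits).
    """
    d = np.asarray(densities, dtype=float)
    n = d.size
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    m = d.mean()
    if m <= 0:
        raise ZeroTrueMeanError(
            "true mean is zero (or negative); mean ratios are undefined"
        )
    total = math.comb(n, k)
    if max_combinations is not None and total > max_combinations:
        if rng is None:
            raise ValueError("subsampling combinations requires an rng")
        idx = subset_indices(n, k)[
            np.sort(rng.choice(total, size=max_combinations, replace=False))
        ]
    else:
        idx = subset_indices(n, k)
    return d[idx].mean(axis=1) / m


def exact_ratio_sd(densities, k: int) -> float:
    """Closed-form sd of the k-subset mean ratio (population convention).

    This is the exact standard deviation, over all C(n,k) subsets, of the
    mean of k densities drawn without replacement, divided by the full-set
    mean — the finite-population correction (1/k − 1/n) applied to the
    sample variance S² (divisor n−1).
    """
    d = np.asarray(densities, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 densities")
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    m = d.mean()
    if m <= 0:
        raise ZeroTrueMeanError("true mean is zero; ratio sd undefined")
    if k == n:
        return 0.0
    s = d.std(ddof=1)
    return float(s / m * math.sqrt(1.0 / k - 1.0 / n))


@dataclass
class MeanRatioDistribution:
    """Pooled mean-ratio values for one region and subset size k.

    ``participant_ids`` labels each entry; entries for one participant are
    contiguous and in lexicographic combination order.
    """

    k: int
    region: str
    participant_ids: np.ndarray
    ratios: np.ndarray

    @property
    def n_total(self) -> int:
        return self.ratios.size

    def frame(self) -> pd.DataFrame:
        combo_index = np.concatenate(
            [
                np.arange(np.count_nonzero(self.participant_ids == pid))
                for pid in dict.fromkeys(self.participant_ids.tolist())
            ]
        )
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "region": self.region,
                "k": self.k,
                "combination_index": combo_index,
                "ratio": self.ratios,
            }
        )


def pooled_distribution(
    dataset: ImageCountSet,
    region: str,
    k: int,
    max_combinations: int | None = None,
    rng: np.random.Generator | None = None,
) -> MeanRatioDistribution:
    """Concatenate every participant's k-subset mean ratios for one region.

    Participants whose true mean is zero have an undefined ratio and are
    excluded with a logged warning.
    """
    pids, matrix = dataset.density_matrix(region)
    ids: list[np.ndarray] = []
    ratios: list[np.ndarray] = []
    for pid, row in zip(pids, matrix):
        try:
            r = participant_mean_ratios(row, k, max_combinations, rng)
        except ZeroTrueMeanError:
            logger.warning(
                "participant %s (%s): zero true mean, excluded from ratio analysis",
                pid,
                region,
            )
            continue
        ratios.append(r)
        ids.append(np.full(r.size, pid, dtype=object))
    if not ratios:
        raise ZeroTrueMeanError(
            f"no participant in region {region!r} has a positive true mean"
        )
    return MeanRatioDistribution(
        k=k,
        region=region.strip().lower(),
        participant_ids=np.concatenate(ids),
        ratios=np.concatenate(ratios),
    )


def ratios_to_frame(distributions) -> pd.DataFrame:
    """Long-format export table over several k: one row per combination."""
    return pd.concat([d.frame() for d in distributions], ignore_index=True)


def write_ratios_csv(distributions, path: str | Path) -> None:
    ratios_to_frame(distributions).to_csv(path, index=False)
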