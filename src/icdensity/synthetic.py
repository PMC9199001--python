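"""Seeded synthetic count data with the statistical structure the analysis assumes.

The study geometry being emulated: 20 healthy participants, each with 16
non-overlapping 400 µm × 400 µm basal-epithelium images (0.16 mm²) per
corneal region, with participant-level immune-cell density heterogeneity
matching the published healthy-cornea summaries — central 21.7 ± 17.7
cells/mm², peripheral 62.0 ± 26.1 cells/mm².

Model, per region:

* participant true densities d_i ~ Gamma, moment-matched to the configured
  mean ± sd (shape = mean²/sd², scale = sd²/mean) — positive support and
  closed-form matching, with nothing beyond mean, sd and range published;
* image counts ~ negative binomial with mean λ = d_i · area and a size
  (dispersion) parameter; infinite size collapses to Poisson, the default,
  since no within-participant image-to-image variance is published;
* observer recounts: binomial thinning of the true count at a detection
  probability, plus an independent Poisson false-positive term — the
  simplest mechanism tunable to realistic inter-observer ICCs;
* "representative image" selection: n_selected images drawn without
  replacement with weight ∝ exp(β·z), z the within-participant standardized
  image density; β = 0 is uniform random selection, large β picks the
  densest images.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ImageCountSet

__all__ = [
    "RegionParams",
    "GeneratorConfig",
    "ObserverModel",
    "SelectionModel",
    "ObserverSelection",
    "draw_participant_densities",
    "generate_counts",
    "simulate_observer_counts",
    "simulate_image_selection",
    "simulate_selection_table",
]


@dataclass(frozen=True)
class RegionParams:
    """Participant-level density distribution for one corneal region."""

    density_mean: float  # cells/mm²
    density_sd: float  # cells/mm²

    def __post_init__(self) -> None:
        if self.density_mean <= 0:
            raise ValueError(f"density_mean must be positive, got {self.density_mean}")
        if self.density_sd < 0:
            raise ValueError(f"density_sd must be >= 0, got {self.density_sd}")


def _default_regions() -> dict[str, RegionParams]:
    return {
        "central": RegionParams(21.7, 17.7),
        "peripheral": RegionParams(62.0, 26.1),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of a synthetic dataset; (config, seed) reproduces it exactly."""

    n_participants: int = 20
    n_images: int = 16
    image_area: float = 0.16  # mm², 400 µm × 400 µm field of view
    regions: dict[str, RegionParams] = field(default_factory=_default_regions)
    dispersion: float = math.inf  # NB size parameter; inf => Poisson counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_images < 2:
            raise ValueError("n_images must be >= 2")
        if self.image_area <= 0:
            raise ValueError("image_area must be positive")
        if not self.regions:
            raise ValueError("at least one region is required")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive (inf for Poisson)")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = {k: dataclasses.asdict(v) for k, v in self.regions.items()}
        d["dispersion"] = "inf" if math.isinf(self.dispersion) else self.dispersion
        return d


def draw_participant_densities(
    config: GeneratorConfig, region: str, rng: np.random.Generator
) -> np.ndarray:
    """Strictly positive participant true densities for one region.

    Gamma with the configured mean and sd; sd = 0 degenerates to all-equal.
    Values below 1e-6 cells/mm² are redrawn so every participant has a
    usable (non-zero) reference density.
    """
    if region not in config.regions:
        raise ValueError(f"unknown region {region!r}; have {list(config.regions)}")
    params = config.regions[region]
    n = config.n_participants
    if params.density_sd == 0:
        return np.full(n, params.density_mean, dtype=float)
    shape = (params.density_mean / params.density_sd) ** 2
    scale = params.density_sd**2 / params.density_mean
    d = rng.gamma(shape, scale, size=n)
    tiny = d < 1e-6
    while tiny.any():
        d[tiny] = rng.gamma(shape, scale, size=int(tiny.sum()))
        tiny = d < 1e-6
    return d


def _draw_counts(
    lam: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(lam)
    p = dispersion / (dispersion + lam)
    return rng.negative_binomial(dispersion, p)


def generate_counts(config: GeneratorConfig, seed: int | None = None) -> ImageCountSet:
    """Draw a full synthetic count dataset.

    For participant i, region r, image j the expected count is
    λ = d_ir × image_area; counts are negative binomial with that mean and
    the configured dispersion (Poisson when infinite).  The returned
    :class:`~icdensity.dataset.ImageCountSet` carries (config, seed) as
    provenance.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    pid_width = max(2, len(str(config.n_participants)))
    img_width = max(2, len(str(config.n_images)))
    pids = [f"P{i + 1:0{pid_width}d}" for i in range(config.n_participants)]
    imgs = [f"I{j + 1:0{img_width}d}" for j in range(config.n_images)]
    frames = []
    for region in config.regions:
        d = draw_participant_densities(config, region, rng)
        lam = d[:, None] * config.image_area * np.ones((1, config.n_images))
        counts = _draw_counts(lam, config.dispersion, rng)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids, config.n_images),
                    "region": region,
                    "image_id": np.tile(imgs, config.n_participants),
                    "count": counts.ravel().astype(int),
                    "area_mm2": config.image_area,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return ImageCountSet(
        frame=frame, provenance={"config": config.as_dict(), "seed": seed}
    )


@dataclass(frozen=True)
class ObserverModel:
    """Imperfect manual counting: missed cells and spurious detections.

    ``detection_probability`` is the chance each true cell is counted;
    ``false_positive_rate`` the expected number of spurious cells per image.
    A perfect observer (1.0, 0.0) reproduces the reference counts exactly.
    """

    detection_probability: float = 0.95
    false_positive_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.detection_probability <= 1:
            raise ValueError("detection_probability must be in (0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")


def simulate_observer_counts(
    counts, observer: ObserverModel, rng: np.random.Generator
) -> np.ndarray:
    """Recounts of a set of images by one imperfect observer.

    Binomial thinning of each true count at the detection probability, plus
    an independent Poisson false-positive term.
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    c = c.astype(np.int64)
    detected = rng.binomial(c, observer.detection_probability)
    spurious = rng.poisson(observer.false_positive_rate, size=c.shape)
    return detected + spurious


@dataclass(frozen=True)
class SelectionModel:
    """How an observer picks "representative" images from a participant's set.

    Images are drawn without replacement with weight ∝ exp(β·z), z the
    within-participant standardized image density.  β = 0 is uniform;
    β > 0 prefers denser images (the suspected human bias).
    """

    bias_strength: float = 0.0
    n_selected: int = 3

    def __post_init__(self) -> None:
        if self.n_selected < 1:
            raise ValueError("n_selected must be >= 1")


@dataclass(frozen=True)
class ObserverSelection:
    observer_id: str
    participant_id: str
    region: str
    image_ids: tuple[str, ...]


def simulate_image_selection(
    image_densities, model: SelectionModel, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the selected images (sorted, distinct).

    Sampling without replacement with weight ∝ exp(β·z) is realised by the
    Gumbel-top-k trick (equivalent to sequential weighted draws).  When the
    within-participant density sd is zero, z ≡ 0 and selection is uniform
    regardless of β.
    """
    d = np.asarray(image_densities, dtype=float)
    n = d.size
    if model.n_selected > n:
        raise ValueError(
            f"cannot select {model.n_selected} from {n} images"
        )
    sd = d.std(ddof=0)
    z = np.zeros(n) if sd == 0 else (d - d.mean()) / sd
    keys = model.bias_strength * z + rng.gumbel(size=n)
    chosen = np.argsort(keys)[-model.n_selected :]
    return np.sort(chosen)


def simulate_selection_table(
    dataset: ImageCountSet,
    model: SelectionModel,
    rng: np.random.Generator,
    observer_ids=("rater1", "rater2", "rater3"),
) -> pd.DataFrame:
    """Simulated selections for every observer × participant-region.

    Returns the standard selections table:
    ``observer_id, participant_id, region, image_id`` with
    ``model.n_selected`` rows per observer-participant-region.
    """
    dens = dataset.with_density()
    rows = []
    for obs in observer_ids:
        for (pid, region), grp in dens.groupby(
            ["participant_id", "region"], sort=False
        ):
            grp = grp.sort_values("image_id")
            idx = simulate_image_selection(grp["density"].to_numpy(), model, rng)
            for image_id in grp["image_id"].to_numpy()[idx]:
                rows.append(
                    {
                        "observer_id": obs,
                        "participant_id": pid,
                        "region": region,
                        "image_id": image_id,
                    }
                )
    return pd.DataFrame(rows)
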