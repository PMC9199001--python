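"""Per-image cell-count tables, densities, and per-participant reference means.

The raw input of the whole pipeline is a long-format table of manual cell
counts: one row per (participant, corneal region, image), with the image
field-of-view area in mm².  Density is simply ``count / area`` in cells/mm².
Each participant-region's *true mean* density is the arithmetic mean over
its full reference image set (16 non-overlapping 400 µm × 400 µm images,
i.e. 2.56 mm² of quantified tissue, at the defaults); subset-based
estimates downstream are always judged against that reference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

REGIONS = ("central", "peripheral")
COLUMNS = ["participant_id", "region", "image_id", "count", "area_mm2"]

__all__ = [
    "REGIONS",
    "COLUMNS",
    "DatasetStructureError",
    "ImageCountSet",
    "ValidationFinding",
    "ValidationReport",
    "density_from_count",
    "true_mean_density",
    "validate_image_set",
]


class DatasetStructureError(ValueError):
    """The count table violates a structural requirement of the analysis."""


def density_from_count(count: float, area: float) -> float:
    """Cell density in cells/mm² for one image.

    Parameters
    ----------
    count
        Non-negative number of cells counted in the image.
    area
        Image field-of-view area in mm²; must be positive.
    """
    if area <= 0:
        raise ValueError(f"image area must be positive, got {area}")
    if count < 0:
        raise ValueError(f"cell count must be non-negative, got {count}")
    return count / area


def true_mean_density(
    densities: Sequence[float],
    reference_size: int | None = None,
    strict: bool = True,
) -> float:
    """Reference ("true") mean density for one participant-region.

    The arithmetic mean of the per-image densities of the full reference
    set.  If ``reference_size`` is given and the input length differs, a
    :class:`DatasetStructureError` is raised in strict mode, or a warning
    is emitted in permissive mode.
    """
    arr = np.asarray(densities, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise DatasetStructureError("densities must be a non-empty 1-d sequence")
    if reference_size is not None and arr.size != reference_size:
        msg = (
            f"expected {reference_size} images in the reference set, "
            f"got {arr.size}"
        )
        if strict:
            raise DatasetStructureError(msg)
        warnings.warn(msg, stacklevel=2)
    return float(arr.mean())


@dataclass(frozen=True)
class ValidationFinding:
    kind: str
    message: str


@dataclass
class ValidationReport:
    """Report-based validation: findings, never exceptions."""

    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, kind: str, message: str) -> None:
        self.findings.append(ValidationFinding(kind, message))

    def kinds(self) -> list[str]:
        return [f.kind for f in self.findings]

    def as_dict(self) -> dict:
        return {
            "ok": self.ok,
            "findings": [{"kind": f.kind, "message": f.message} for f in self.findings],
        }


def _normalise_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetStructureError(f"count table is missing columns: {missing}")
    out = frame.loc[:, COLUMNS].copy()
    out["participant_id"] = out["participant_id"].astype(str)
    out["region"] = out["region"].astype(str).str.strip().str.lower()
    out["image_id"] = out["image_id"].astype(str)
    out["area_mm2"] = out["area_mm2"].astype(float)
    return out.reset_index(drop=True)


def validate_image_set(
    records: pd.DataFrame, reference_size: int | None = 16
) -> ValidationReport:
    """Structural checks on a count table; returns findings, raises nothing.

    Flags duplicated (participant, region, image) keys, negative or
    non-integer counts, inconsistent areas within a participant-region,
    and participant-regions with fewer than ``reference_size`` images.
    """
    report = ValidationReport()
    frame = _normalise_frame(records)

    key_cols = ["participant_id", "region", "image_id"]
    dup = frame.duplicated(subset=key_cols, keep=False)
    for _, row in frame.loc[dup].drop_duplicates(subset=key_cols).iterrows():
        report.add(
            "duplicate-key",
            f"duplicated image key {tuple(row[c] for c in key_cols)}",
        )

    counts = frame["count"]
    bad_neg = frame.loc[pd.to_numeric(counts, errors="coerce") < 0]
    for _, row in bad_neg.iterrows():
        report.add("negative-count", f"negative count {row['count']} at "
                   f"{(row['participant_id'], row['region'], row['image_id'])}")
    numeric = pd.to_numeric(counts, errors="coerce")
    non_integer = frame.loc[numeric.notna() & (numeric % 1 != 0)]
    for _, row in non_integer.iterrows():
        report.add("non-integer-count", f"non-integer count {row['count']} at "
                   f"{(row['participant_id'], row['region'], row['image_id'])}")

    grouped = frame.groupby(["participant_id", "region"], sort=False)
    for (pid, region), grp in grouped:
        if grp["area_mm2"].nunique() > 1:
            report.add(
                "inconsistent-area",
                f"participant {pid} region {region} mixes image areas "
                f"{sorted(grp['area_mm2'].unique())}",
            )
        if reference_size is not None and len(grp) < reference_size:
            report.add(
                "short-set",
                f"participant {pid} region {region} has {len(grp)} images, "
                f"fewer than the reference {reference_size}",
            )
    return report


@dataclass
class ImageCountSet:
    """A complete per-image count dataset plus provenance.

    ``frame`` holds one row per image with columns
    ``participant_id, region, image_id, count, area_mm2``.  ``provenance``
    carries whatever is needed to regenerate the data (generator config and
    seed for synthetic sets; source path for files).
    """

    frame: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = _normalise_frame(self.frame)

    # ------------------------------------------------------------------ views
    @property
    def n_records(self) -> int:
        return len(self.frame)

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["region"]))

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.frame["participant_id"]))

    def with_density(self) -> pd.DataFrame:
        """Copy of the table with a ``density`` column (cells/mm²)."""
        out = self.frame.copy()
        if (out["area_mm2"] <= 0).any():
            raise DatasetStructureError("all image areas must be positive")
        if (out["count"] < 0).any():
            raise DatasetStructureError("all counts must be non-negative")
        out["density"] = out["count"] / out["area_mm2"]
        return out

    def density_matrix(self, region: str) -> tuple[list[str], np.ndarray]:
        """Participants × images density matrix for one region.

        Requires every participant of the region to carry the same number
        of images.  Returns (participant ids, matrix) with rows in first-
        appearance participant order and columns in sorted image-id order.
        """
        region = region.strip().lower()
        dens = self.with_density()
        sub = dens.loc[dens["region"] == region]
        if sub.empty:
            raise DatasetStructureError(f"region {region!r} absent from dataset")
        pivot = sub.pivot(index="participant_id", columns="image_id", values="density")
        if pivot.isna().any().any():
            raise DatasetStructureError(
                f"region {region!r} is ragged: participants carry different image sets"
            )
        order = [p for p in self.participants if p in pivot.index]
        pivot = pivot.loc[order]
        return list(pivot.index), pivot.to_numpy(dtype=float)

    def true_means(
        self, reference_size: int | None = None, strict: bool = False
    ) -> pd.DataFrame:
        """Per participant-region reference table.

        Columns: ``participant_id, region, true_mean, n_images,
        total_area_mm2``.  ``true_mean`` is the arithmetic mean density of
        all images of the set; ``total_area_mm2`` the summed quantified area.
        """
        dens = self.with_density()
        rows = []
        for (pid, region), grp in dens.groupby(
            ["participant_id", "region"], sort=False
        ):
            rows.append(
                {
                    "participant_id": pid,
                    "region": region,
                    "true_mean": true_mean_density(
                        grp["density"].to_numpy(), reference_size, strict=strict
                    ),
                    "n_images": len(grp),
                    "total_area_mm2": float(grp["area_mm2"].sum()),
                }
            )
        return pd.DataFrame(rows)

    def validate(self, reference_size: int | None = 16) -> ValidationReport:
        return validate_image_set(self.frame, reference_size)

    # -------------------------------------------------------------------- io
    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImageCountSet":
        frame = pd.read_csv(path, dtype={"participant_id": str, "image_id": str})
        return cls(frame=frame, provenance={"source": str(path)})

    def write(self, outdir: str | Path, stem: str = "counts") -> Path:
        """Write the counts CSV plus a sidecar provenance JSON; returns CSV path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{stem}.csv"
        self.to_csv(csv_path)
        with open(outdir / f"{stem}.provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        return csv_path
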