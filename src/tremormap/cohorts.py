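"""Clinical tremor scores per treated hemisphere.

Tremor is often asymmetric, so scores enter the analysis as hemibody
("hemi-") scores assigned to the contralateral electrode.  Because the two
disorders are rated on different scales (MDS-UPDRS-III tremor items for
Parkinson's disease, Fahn-Tolosa-Marin for essential tremor), pooled
analyses use the absolute improvement normalized by the maximum reachable
score of the respective scale, a dimensionless ratio in [-1, 1].

Hemispheres with a baseline below 3 tremor points are excluded by default:
without substantial baseline symptoms an improvement cannot be measured
properly.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import SeedMask, VolumeGrid, read_seed_mask

logger = logging.getLogger(__name__)

__all__ = [
    "HemisphereRecord",
    "OutcomeVector",
    "filter_min_baseline",
    "percent_reduction",
    "normalized_improvement",
    "read_cohort_csv",
    "write_cohort_csv",
    "cohort_hash",
]

CSV_COLUMNS = ["patient_id", "cohort", "hemisphere", "seed_path", "baseline", "post", "scale_max"]


@dataclass(frozen=True)
class HemisphereRecord:
    """One analyzed hemisphere: seed region plus its clinical outcome."""

    patient_id: str
    cohort: str
    hemisphere: str  # left | right
    baseline: float  # points on the cohort's tremor scale
    post: float      # points, post-treatment
    scale_max: float  # maximum reachable score of that scale
    seed: SeedMask | None = None

    def __post_init__(self):
        if self.scale_max <= 0:
            raise ValueError(f"{self.patient_id}/{self.hemisphere}: scale_max must be positive")
        for label, v in (("baseline", self.baseline), ("post", self.post)):
            if not (0 <= v <= self.scale_max):
                raise ValueError(
                    f"{self.patient_id}/{self.hemisphere}: {label}={v} outside [0, {self.scale_max}]"
                )
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left or right, got {self.hemisphere!r}")

    @property
    def improvement(self) -> float:
        """Absolute improvement in scale points; negative if worsened."""
        return self.baseline - self.post

    @property
    def normalized_improvement(self) -> float:
        return normalized_improvement(self)


def normalized_improvement(record: HemisphereRecord) -> float:
    """Improvement as a fraction of the maximum reachable tremor score."""
    if record.scale_max <= 0:
        raise ValueError("scale_max must be positive")
    return (record.baseline - record.post) / record.scale_max


def percent_reduction(mean_baseline: float, mean_improvement: float) -> float:
    """Mean improvement expressed as a percentage of the mean baseline score."""
    if mean_baseline <= 0:
        raise ValueError("mean baseline must be positive")
    return 100.0 * mean_improvement / mean_baseline


def filter_min_baseline(
    records: list[HemisphereRecord], min_points: float = 3
) -> list[HemisphereRecord]:
    """Drop hemispheres with baseline below ``min_points`` tremor points."""
    kept = [r for r in records if r.baseline >= min_points]
    excluded = len(records) - len(kept)
    if excluded:
        logger.info("excluded %d hemisphere(s) with baseline < %s points", excluded, min_points)
    if not kept:
        logger.warning("all %d records excluded by the baseline filter", len(records))
    return kept


class OutcomeVector:
    """Ordered cohort outcomes with derived improvement measures."""

    def __init__(self, records: list[HemisphereRecord]):
        if not records:
            raise ValueError("empty record list")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def improvement(self) -> np.ndarray:
        return np.array([r.improvement for r in self.records])

    @property
    def normalized_improvement(self) -> np.ndarray:
        return np.array([r.normalized_improvement for r in self.records])

    @property
    def percent_reduction(self) -> np.ndarray:
        """Per-record percent reduction; NaN where baseline is 0 (undefined)."""
        base = np.array([r.baseline for r in self.records], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(base > 0, 100.0 * self.improvement / base, np.nan)

    @property
    def cohorts(self) -> np.ndarray:
        return np.array([r.cohort for r in self.records])

    @property
    def patient_ids(self) -> np.ndarray:
        return np.array([r.patient_id for r in self.records])

    def summary(self) -> dict:
        base = np.array([r.baseline for r in self.records], dtype=float)
        imp = self.improvement
        return {
            "n_hemispheres": len(self.records),
            "n_patients": len(set(self.patient_ids)),
            "mean_baseline": float(base.mean()),
            "sd_baseline": float(base.std(ddof=1)) if len(base) > 1 else 0.0,
            "mean_improvement": float(imp.mean()),
            "sd_improvement": float(imp.std(ddof=1)) if len(imp) > 1 else 0.0,
            "percent_reduction": percent_reduction(base.mean(), imp.mean()),
        }


def cohort_hash(records: list[HemisphereRecord]) -> str:
    """Short content hash of a cohort's clinical data and seed geometry.

    Used to firewall hold-out cohorts: any map built from a cohort carries
    this hash in its provenance.
    """
    h = hashlib.sha1()
    for r in sorted(records, key=lambda r: (r.patient_id, r.hemisphere)):
        h.update(
            f"{r.patient_id}|{r.cohort}|{r.hemisphere}|{r.baseline}|{r.post}|{r.scale_max}".encode()
        )
        if r.seed is not None:
            h.update(r.seed.content_hash().encode())
    return h.hexdigest()[:8]


def read_cohort_csv(
    path, grid: VolumeGrid | None = None, load_seeds: bool = True
) -> list[HemisphereRecord]:
    """Read a cohort table (patient_id, cohort, hemisphere, seed_path, baseline, post, scale_max).

    ``seed_path`` entries are resolved relative to the CSV's directory and
    loaded as binary NIfTI masks on ``grid`` when ``load_seeds`` is set.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns and c != "seed_path"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    base_dir = Path(path).parent
    records = []
    for row in df.itertuples(index=False):
        seed = None
        seed_path = getattr(row, "seed_path", None)
        if load_seeds and isinstance(seed_path, str) and seed_path:
            if grid is None:
                raise ValueError("a grid is required to load seed masks")
            p = Path(seed_path)
            if not p.is_absolute():
                p = base_dir / p
            seed = read_seed_mask(p, grid, side=row.hemisphere, name=str(seed_path))
        records.append(
            HemisphereRecord(
                patient_id=str(row.patient_id),
                cohort=str(row.cohort),
                hemisphere=str(row.hemisphere),
                baseline=float(row.baseline),
                post=float(row.post),
                scale_max=float(row.scale_max),
                seed=seed,
            )
        )
    return records


def write_cohort_csv(records: list[HemisphereRecord], path, seed_paths: list[str] | None = None) -> None:
    rows = []
    for i, r in enumerate(records):
        rows.append(
            {
                "patient_id": r.patient_id,
                "cohort": r.cohort,
                "hemisphere": r.hemisphere,
                "seed_path": seed_paths[i] if seed_paths else "",
                "baseline": r.baseline,
                "post": r.post,
                "scale_max": r.scale_max,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)
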