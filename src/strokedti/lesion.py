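"""Stroke volumetry, atlas-based lesion mapping, and lesion-profile clustering.

Works on binary stroke masks that already live in atlas space.  Incidence
maps report, per atlas region, the fraction of subjects whose mask touches
the region; percent-infarct reports how much of a region is inside one
subject's mask; the consolidation slope tracks lesion shrinkage between
days 1 and 7; Ward clustering groups subjects by their lesion profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .atlas import LabelVolume, RegionMask, RegionOntology, region_mask
from .errors import EmptyRegionError, GridError, IncompleteSeriesError, ParameterError

#: fixed region order used for lesion profiles study-wide
PROFILE_REGIONS = ("cc", "SSp-un", "SSp-ul", "SSp-ll", "MOs", "MOp")

BASELINE_DAY = -3


@dataclass
class LesionMask:
    """Per-subject, per-timepoint binary stroke segmentation in atlas space."""

    grid: np.ndarray
    subject_id: str
    day: int
    modality: str = "T2WI"  # T2WI | histology

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 3:
            raise GridError("lesion grid must be 3-D")
        if self.modality not in ("T2WI", "histology"):
            raise ValueError(f"modality must be T2WI|histology, got {self.modality!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


def _check_shapes(mask: LesionMask, labels: LabelVolume) -> None:
    if mask.grid.shape != labels.shape:
        raise GridError(
            f"lesion grid {mask.grid.shape} does not match label grid {labels.shape}"
        )


def lesion_volume(mask: LesionMask, labels: LabelVolume) -> float:
    """Lesion volume in mm^3 (voxel count x voxel volume)."""
    _check_shapes(mask, labels)
    return mask.n_voxels * labels.voxel_volume_mm3


def affected_regions(
    mask: LesionMask,
    labels: LabelVolume,
    ontology: RegionOntology,
    min_voxels: int = 1,
    ipsi_side: str = "right",
    regions: tuple[str, ...] | None = None,
) -> set[str]:
    """Atlas regions with >= min_voxels ipsilesional voxels inside the mask."""
    _check_shapes(mask, labels)
    if min_voxels < 1:
        raise ParameterError("min_voxels must be >= 1")
    if regions is None:
        regions = tuple(r.acronym for r in ontology.leaves())
    hemi = labels.hemisphere_selector(ipsi_side)
    hit = set()
    for acr in regions:
        ids = ontology.descendants(acr)
        overlap = mask.grid & hemi & np.isin(labels.grid, list(ids))
        if int(overlap.sum()) >= min_voxels:
            hit.add(acr)
    return hit


def incidence_map(
    masks: list[LesionMask],
    labels: LabelVolume,
    ontology: RegionOntology,
    day: int,
    min_voxels: int = 1,
    ipsi_side: str = "right",
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-region fraction of subjects whose day-``day`` mask hits the region.

    Returns a table with columns (region, day, fraction, n_subjects).
    """
    if regions is None:
        regions = tuple(r.acronym for r in ontology.leaves())
    at_day = [m for m in masks if m.day == day]
    if not at_day:
        raise IncompleteSeriesError(f"no lesion masks at day {day}")
    counts = {acr: 0 for acr in regions}
    for m in at_day:
        for acr in affected_regions(m, labels, ontology, min_voxels, ipsi_side, regions):
            counts[acr] += 1
    n = len(at_day)
    return pd.DataFrame(
        {
            "region": list(regions),
            "day": day,
            "fraction": [counts[a] / n for a in regions],
            "n_subjects": n,
        }
    )


def percent_infarct(mask: LesionMask, region: RegionMask) -> float:
    """Percentage of the region's voxels inside the stroke mask, in [0, 100]."""
    if mask.grid.shape != region.grid.shape:
        raise GridError("lesion and region grids differ in shape")
    denom = region.n_voxels
    if denom == 0:
        raise EmptyRegionError(f"region {region.acronym!r} is empty")
    return 100.0 * int((mask.grid & region.grid).sum()) / denom


def consolidation_slope(p_day1: float, p_day7: float) -> float:
    """Change in stroke-affected area percentage per day between days 1 and 7."""
    for p in (p_day1, p_day7):
        if p is None or not np.isfinite(p):
            raise IncompleteSeriesError("both day-1 and day-7 percentages are required")
        if not 0.0 <= p <= 100.0:
            raise ParameterError(f"percent value {p} outside [0, 100]")
    return (p_day7 - p_day1) / 6.0


@dataclass
class LesionProfile:
    """Percent-infarct vector over the fixed study regions plus total volume."""

    subject_id: str
    day: int
    percent: np.ndarray = field(default=None)  # type: ignore[assignment]
    total_volume_mm3: float = 0.0
    regions: tuple[str, ...] = PROFILE_REGIONS

    def __post_init__(self):
        self.percent = np.asarray(self.percent, dtype=float)
        if self.percent.shape != (len(self.regions),):
            raise ParameterError("percent vector length must match region list")
        if np.any((self.percent < 0) | (self.percent > 100)):
            raise ParameterError("percent values must lie in [0, 100]")


def lesion_profile(
    mask: LesionMask,
    labels: LabelVolume,
    ontology: RegionOntology,
    ipsi_side: str = "right",
    regions: tuple[str, ...] = PROFILE_REGIONS,
) -> LesionProfile:
    """Percent-infarct over the fixed region list, ipsilesional hemisphere."""
    vals = []
    for acr in regions:
        rm = region_mask(labels, ontology, acr, "ipsi", ipsi_side=ipsi_side)
        vals.append(percent_infarct(mask, rm))
    return LesionProfile(
        subject_id=mask.subject_id,
        day=mask.day,
        percent=np.array(vals),
        total_volume_mm3=lesion_volume(mask, labels),
        regions=regions,
    )


@dataclass
class WardResult:
    assignments: np.ndarray  # cluster label (1..k) per row
    linkage_heights: np.ndarray  # merge heights, ascending, length n-1
    linkage_matrix: np.ndarray  # full scipy linkage
    inter_cluster_distance: float
    intra_cluster_distance: float


def ward_cluster(profiles: np.ndarray, k: int) -> WardResult:
    """Agglomerative Ward (minimum-variance) clustering of lesion profiles.

    Heights follow the standard Lance-Williams update on squared Euclidean
    distances and are reported unsquared (scipy convention).  The
    inter-cluster distance is the height of the merge that fuses the k
    retained clusters into k-1; the intra-cluster distance is the largest
    merge height inside any retained cluster (0 if every cluster is a
    singleton).
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not np.all(np.isfinite(X)):
        raise ParameterError("profiles must be finite")
    if not 1 <= k <= n:
        raise ParameterError(f"k={k} outside [1, n={n}]")
    Z = linkage(X, method="ward")
    assignments = fcluster(Z, t=k, criterion="maxclust")
    heights = Z[:, 2].copy()
    inter = float(Z[n - k, 2]) if k > 1 else float("nan")
    intra = float(Z[n - k - 1, 2]) if n - k - 1 >= 0 else 0.0
    return WardResult(
        assignments=assignments,
        linkage_heights=heights,
        linkage_matrix=Z,
        inter_cluster_distance=inter,
        intra_cluster_distance=intra,
    )
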