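"""Brain-region ontology, label volumes, and hemisphere-aware region masks.

All analyses in this package run in a common atlas space: a 3-D integer
label volume whose values index into a hierarchical region ontology
(Allen-reference-atlas style structure graph, simplified to the regions
the study actually interrogates).  Both hemispheres carry the same region
ids and are disambiguated purely by the side of a midsagittal index plane.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

from .errors import (
    GridError,
    OntologyFormatError,
    OntologyStructureError,
    RegionLookupError,
)

HEMISPHERE_TAGS = ("ipsi", "contra", "left", "right", "both")

_DEFAULT_ONTOLOGY = Path(__file__).parent / "data" / "ontology.json"


@dataclass(frozen=True)
class Region:
    region_id: int
    acronym: str
    name: str
    parent_id: int | None


class RegionOntology:
    """Hierarchical region tree with id/acronym lookup.

    The tree has a single root whose acronym is ``root``; every other
    record points to an existing parent.  Ids and acronyms are unique.
    """

    def __init__(self, regions: Iterable[Region]):
        regions = list(regions)
        by_id: dict[int, Region] = {}
        by_acronym: dict[str, Region] = {}
        for r in regions:
            if r.region_id in by_id:
                raise OntologyFormatError(f"duplicate region id {r.region_id}")
            if r.acronym in by_acronym:
                raise OntologyFormatError(f"duplicate acronym {r.acronym!r}")
            if r.region_id <= 0:
                raise OntologyFormatError(f"region id must be positive, got {r.region_id}")
            by_id[r.region_id] = r
            by_acronym[r.acronym] = r
        roots = [r for r in regions if r.parent_id is None]
        if len(roots) != 1:
            raise OntologyStructureError(f"expected exactly one root, found {len(roots)}")
        if roots[0].acronym != "root":
            raise OntologyStructureError("root region must have acronym 'root'")
        children: dict[int, list[int]] = {r.region_id: [] for r in regions}
        for r in regions:
            if r.parent_id is not None:
                if r.parent_id not in by_id:
                    raise OntologyStructureError(
                        f"region {r.acronym!r} points to missing parent {r.parent_id}"
                    )
                children[r.parent_id].append(r.region_id)
        # reject cycles / disconnected components: walk from root
        seen: set[int] = set()
        stack = [roots[0].region_id]
        while stack:
            rid = stack.pop()
            if rid in seen:
                raise OntologyStructureError("cycle detected in ontology")
            seen.add(rid)
            stack.extend(children[rid])
        if seen != set(by_id):
            raise OntologyStructureError("ontology is not a single tree rooted at 'root'")
        self._regions = regions
        self._by_id = by_id
        self._by_acronym = by_acronym
        self._children = children
        self.root = roots[0]

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self):
        return iter(self._regions)

    def __contains__(self, acronym: str) -> bool:
        return acronym in self._by_acronym

    def by_id(self, region_id: int) -> Region:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise RegionLookupError(f"unknown region id {region_id}") from None

    def by_acronym(self, acronym: str) -> Region:
        try:
            return self._by_acronym[acronym]
        except KeyError:
            raise RegionLookupError(f"unknown region acronym {acronym!r}") from None

    def children(self, region_id: int) -> list[int]:
        return list(self._children[region_id])

    def descendants(self, acronym: str) -> set[int]:
        """Region id plus all transitive children (leaf -> singleton)."""
        start = self.by_acronym(acronym).region_id
        out: set[int] = set()
        stack = [start]
        while stack:
            rid = stack.pop()
            out.add(rid)
            stack.extend(self._children[rid])
        return out

    def leaves(self) -> list[Region]:
        return [r for r in self._regions if not self._children[r.region_id]]

    def depth(self, acronym: str) -> int:
        """Number of nodes on the path from root to the region (root = 1)."""
        r = self.by_acronym(acronym)
        d = 1
        while r.parent_id is not None:
            r = self._by_id[r.parent_id]
            d += 1
        return d


def load_ontology(path: str | Path | None = None) -> RegionOntology:
    """Load a region ontology from a JSON structure-graph file.

    The file holds a flat list of records ``{"id": int, "acronym": str,
    "name": str, "parent_id": int | null}``.  With ``path=None`` the
    packaged default ontology (11 analysis regions plus containers) is
    loaded.
    """
    path = _DEFAULT_ONTOLOGY if path is None else Path(path)
    try:
        records = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise OntologyFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(records, list):
        raise OntologyFormatError("ontology file must hold a list of region records")
    regions = []
    for rec in records:
        try:
            regions.append(
                Region(
                    region_id=int(rec["id"]),
                    acronym=str(rec["acronym"]),
                    name=str(rec.get("name", rec["acronym"])),
                    parent_id=None if rec.get("parent_id") is None else int(rec["parent_id"]),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise OntologyFormatError(f"bad region record {rec!r}") from exc
    return RegionOntology(regions)


def descendants(ontology: RegionOntology, acronym: str) -> set[int]:
    """Functional alias for :meth:`RegionOntology.descendants`."""
    return ontology.descendants(acronym)


@dataclass
class LabelVolume:
    """Voxelized region labels in atlas space.

    ``midline_index`` is the sagittal index plane splitting hemispheres:
    voxels with x-index < midline_index are *left*, > are *right*, == are
    on the midline and belong to neither hemisphere.
    """

    grid: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    midline_index: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise GridError("label grid must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise GridError("label grid must be integer-typed")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise GridError("voxel_size_mm must be 3 positive reals")
        self.voxel_size_mm = vs
        if self.affine is None:
            self.affine = np.diag([*vs, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-30:
            raise GridError("affine must be an invertible 4x4 matrix")
        if not 0 <= self.midline_index < self.grid.shape[0]:
            raise GridError("midline_index outside grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    def validate_labels(self, ontology: RegionOntology) -> None:
        ids = np.unique(self.grid)
        ids = ids[ids != 0]
        known = {r.region_id for r in ontology}
        extra = set(ids.tolist()) - known
        if extra:
            raise GridError(f"label values not in ontology: {sorted(extra)}")

    def hemisphere_selector(self, side: str) -> np.ndarray:
        """Boolean grid selecting one hemisphere (midline plane excluded)."""
        x = np.arange(self.shape[0])
        if side == "left":
            sel = x < self.midline_index
        elif side == "right":
            sel = x > self.midline_index
        elif side == "both":
            sel = np.ones_like(x, dtype=bool)
        else:
            raise ValueError(f"side must be left|right|both, got {side!r}")
        return np.broadcast_to(sel[:, None, None], self.shape)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.grid.astype(np.int32), self.affine)
        img.header["pixdim"][1:4] = self.voxel_size_mm
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, midline_index: int) -> "LabelVolume":
        img = nib.load(str(path))
        grid = np.asanyarray(img.dataobj).astype(np.int32)
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(grid=grid, voxel_size_mm=vs, affine=np.asarray(img.affine),
                   midline_index=midline_index)


@dataclass
class RegionMask:
    """Boolean mask of one region (one hemisphere or both) in atlas space."""

    grid: np.ndarray
    acronym: str
    hemisphere: str

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.hemisphere not in HEMISPHERE_TAGS:
            raise ValueError(f"hemisphere must be one of {HEMISPHERE_TAGS}")

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())

    def __bool__(self) -> bool:
        return self.n_voxels > 0

    def to_nifti(self, path: str | Path, affine: np.ndarray) -> None:
        nib.save(nib.Nifti1Image(self.grid.astype(np.uint8), affine), str(path))


def region_mask(
    labels: LabelVolume,
    ontology: RegionOntology,
    acronym: str,
    hemisphere: str = "both",
    ipsi_side: str | None = None,
) -> RegionMask:
    """Extract the voxel mask of a region (and its descendants).

    A voxel is included iff its label lies in ``descendants(acronym)`` and
    it lies on the requested side of the midline plane; midline voxels are
    excluded from both hemispheres.  ``ipsi``/``contra`` tags require
    ``ipsi_side`` ("left" or "right").
    """
    if hemisphere not in HEMISPHERE_TAGS:
        raise ValueError(f"hemisphere must be one of {HEMISPHERE_TAGS}")
    ids = ontology.descendants(acronym)
    in_region = np.isin(labels.grid, list(ids))
    side = hemisphere
    if hemisphere in ("ipsi", "contra"):
        if ipsi_side not in ("left", "right"):
            raise ValueError("ipsi_side ('left'|'right') required for ipsi/contra masks")
        side = ipsi_side if hemisphere == "ipsi" else ("left" if ipsi_side == "right" else "right")
    grid = in_region & labels.hemisphere_selector(side)
    mask = RegionMask(grid=grid, acronym=acronym, hemisphere=hemisphere)
    if not mask:
        warnings.warn(
            f"region mask {acronym!r} ({hemisphere}) is empty", stacklevel=2
        )
    return mask
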