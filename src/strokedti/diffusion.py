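"""Diffusion-tensor eigen-metrics and region-level aggregation.

The per-voxel symmetric tensor D (mm^2/s) yields the standard scalar
measures from its sorted eigenvalues l1 >= l2 >= l3:

    MD = (l1 + l2 + l3) / 3          mean (molecular) diffusivity
    AD = l1                           axial diffusivity
    RD = (l2 + l3) / 2                radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy in [0, 1]

Regional values are voxel means; hemispheric asymmetry is expressed as
(ipsi - contra) / contra x 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import nibabel as nib
import numpy as np

from .atlas import RegionMask
from .errors import EmptyRegionError, GridError
from .lesion import LesionMask

#: component order of the 6-vector tensor representation
TENSOR_COMPONENTS = ("xx", "xy", "xz", "yy", "yz", "zz")

METRIC_NAMES = ("FA", "MD", "AD", "RD")

_NEG_EIG_TOL = 1e-12


class EigenMetrics(NamedTuple):
    l1: np.ndarray | float
    l2: np.ndarray | float
    l3: np.ndarray | float
    FA: np.ndarray | float
    MD: np.ndarray | float
    AD: np.ndarray | float
    RD: np.ndarray | float
    degenerate: np.ndarray | bool  # eigenvalue < -tolerance


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    """(..., 6) unique components (xx,xy,xz,yy,yz,zz) -> (..., 3, 3) symmetric."""
    t6 = np.asarray(t6, dtype=float)
    m = np.empty(t6.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = t6[..., 0]
    m[..., 0, 1] = m[..., 1, 0] = t6[..., 1]
    m[..., 0, 2] = m[..., 2, 0] = t6[..., 2]
    m[..., 1, 1] = t6[..., 3]
    m[..., 1, 2] = m[..., 2, 1] = t6[..., 4]
    m[..., 2, 2] = t6[..., 5]
    return m


def eigen_metrics(tensor: np.ndarray) -> EigenMetrics:
    """Eigenvalues (descending) and FA/MD/AD/RD for one tensor or an array.

    Accepts a (..., 6) component vector or a (..., 3, 3) symmetric matrix.
    Tensors with an eigenvalue below -1e-12 are flagged degenerate; their
    metrics are still returned.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-1] == 6 and (tensor.ndim == 1 or tensor.shape[-2:] != (3, 3)):
        mat = tensor6_to_matrix(tensor)
    elif tensor.shape[-2:] == (3, 3):
        mat = tensor
    else:
        raise ValueError("tensor must be (...,6) components or (...,3,3) matrix")
    lam = np.linalg.eigvalsh(mat)[..., ::-1]  # descending
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    degenerate = lam[..., -1] < -_NEG_EIG_TOL
    md = (l1 + l2 + l3) / 3.0
    ad = l1
    rd = (l2 + l3) / 2.0
    dev = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    norm = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * dev / norm
    fa = np.where(norm > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    if lam.ndim == 1:
        return EigenMetrics(*(float(v) for v in (l1, l2, l3, fa, md, ad, rd)),
                            bool(degenerate))
    return EigenMetrics(l1, l2, l3, fa, md, ad, rd, degenerate)


@dataclass
class ScalarVolume:
    """A scalar map (T2WI intensity or a diffusion metric) in atlas space."""

    data: np.ndarray
    affine: np.ndarray
    modality: str  # T2WI | FA | MD | AD | RD

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise GridError("scalar volume must be 3-D")
        self.affine = np.asarray(self.affine, dtype=float)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path, modality: str) -> "ScalarVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(float), np.asarray(img.affine), modality)


@dataclass
class TensorVolume:
    """Per-voxel diffusion tensor as 6 unique components (xx,xy,xz,yy,yz,zz)."""

    data: np.ndarray  # (X, Y, Z, 6), mm^2/s
    brain_mask: np.ndarray  # (X, Y, Z) bool
    affine: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 6:
            raise GridError("tensor volume must be (X, Y, Z, 6)")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise GridError("brain mask shape must match tensor grid")
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def _eigensystem(self):
        """Cached voxelwise eigendecomposition (values descending)."""
        if self._eig is None:
            mat = tensor6_to_matrix(self.data)
            vals, vecs = np.linalg.eigh(mat)
            object.__setattr__(self, "_eig", (vals[..., ::-1], vecs[..., ::-1]))
        return self._eig

    def metrics(self) -> EigenMetrics:
        vals, _ = self._eigensystem()
        l1, l2, l3 = vals[..., 0], vals[..., 1], vals[..., 2]
        md = (l1 + l2 + l3) / 3.0
        rd = (l2 + l3) / 2.0
        dev = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
        norm = np.sqrt(l1**2 + l2**2 + l3**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            fa = np.sqrt(1.5) * dev / norm
        fa = np.clip(np.where(norm > 0, fa, 0.0), 0.0, 1.0)
        return EigenMetrics(l1, l2, l3, fa, md, l1, rd, vals[..., -1] < -_NEG_EIG_TOL)

    def principal_direction(self) -> np.ndarray:
        """(X, Y, Z, 3) unit eigenvector of the largest eigenvalue."""
        _, vecs = self._eigensystem()
        return vecs[..., :, 0]

    def metric_volume(self, name: str) -> ScalarVolume:
        if name not in METRIC_NAMES:
            raise ValueError(f"metric must be one of {METRIC_NAMES}")
        m = self.metrics()
        return ScalarVolume(getattr(m, name), self.affine, name)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(
        cls, path: str | Path, brain_mask: np.ndarray,
        voxel_size_mm: tuple[float, float, float],
    ) -> "TensorVolume":
        img = nib.load(str(path))
        return cls(np.asanyarray(img.dataobj).astype(float), brain_mask,
                   np.asarray(img.affine), voxel_size_mm)


def region_mean(metric_volume: ScalarVolume, region: RegionMask,
                brain_mask: np.ndarray | None = None) -> float:
    """Arithmetic mean of a scalar map over a region (within the brain mask)."""
    sel = region.grid
    if brain_mask is not None:
        sel = sel & brain_mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyRegionError(
            f"region {region.acronym!r} has no voxels inside the brain mask"
        )
    return float(metric_volume.data[sel].mean())


def ipsi_contra_norm(ipsi: float, contra: float) -> float:
    """(ipsi - contra) / contra x 100%."""
    if contra == 0:
        raise ZeroDivisionError("contralesional reference value is zero")
    return (ipsi - contra) / contra * 100.0


def integrated_density_ratio(
    t2: ScalarVolume, region_ipsi: RegionMask, region_contra: RegionMask
) -> float:
    """Ipsi/contra ratio of region-size-normalized summed intensity.

    'Integrated density' of a region is its summed intensity divided by its
    voxel count, i.e. the mean intensity; the returned value is the
    ipsilesional/contralesional ratio of these means.
    """
    for r in (region_ipsi, region_contra):
        if r.n_voxels == 0:
            raise EmptyRegionError(f"region {r.acronym!r} ({r.hemisphere}) is empty")
    mean_ipsi = float(t2.data[region_ipsi.grid].sum()) / region_ipsi.n_voxels
    mean_contra = float(t2.data[region_contra.grid].sum()) / region_contra.n_voxels
    if mean_contra == 0:
        raise ZeroDivisionError("contralesional mean intensity is zero")
    return mean_ipsi / mean_contra


def lesion_roi_metrics(tensors: TensorVolume, mask: LesionMask) -> dict[str, float]:
    """Mean FA/MD/AD/RD over the lesion mask (per-voxel metrics, then mean)."""
    if mask.grid.shape != tensors.shape:
        raise GridError("lesion mask shape does not match tensor grid")
    if mask.n_voxels == 0:
        raise EmptyRegionError("lesion mask is empty")
    m = tensors.metrics()
    sel = mask.grid
    return {name: float(getattr(m, name)[sel].mean()) for name in METRIC_NAMES}
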