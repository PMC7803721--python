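"""Deterministic tensor-line streamline tracking and region-pair connectivity.

A FACT-style tracker: from each seed the streamline follows the principal
eigenvector of the nearest voxel's tensor with a fixed Euler step, in both
directions, sign-aligning each step with the previous one.  Tracking stops
when FA drops below ``fa_stop``, the turning angle exceeds
``angle_stop_deg``, the position leaves the brain mask, or ``max_steps``
is reached.  Fiber density of a region pair is the number of streamlines
(seeded in the source) that touch the target, normalized by seed count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import LabelVolume, RegionMask, RegionOntology, region_mask
from .diffusion import ScalarVolume, TensorVolume
from .errors import EmptyRegionError, ParameterError


@dataclass(frozen=True)
class TrackingParams:
    """Tracking configuration; ``step_mm=None`` resolves to 0.25 x min voxel."""

    step_mm: float | None = None
    fa_stop: float = 0.15
    angle_stop_deg: float = 60.0
    max_steps: int = 2000
    seeds_per_voxel: int = 3
    rng_seed: int = 0

    def resolve_step(self, voxel_size_mm: Sequence[float]) -> float:
        step = self.step_mm if self.step_mm is not None else 0.25 * min(voxel_size_mm)
        if step <= 0 or step >= min(voxel_size_mm):
            raise ParameterError(
                f"step_mm must lie in (0, min voxel dimension), got {step}"
            )
        return step


@dataclass
class StreamlineSet:
    """Polylines (world mm) from one tracking run, with seeding metadata.

    ``n_seeds`` counts all attempted seeds, including rejected ones, so
    densities derived from this set are normalized per seed.
    """

    streamlines: list[np.ndarray]
    seed_region: str
    params: TrackingParams
    n_seeds: int
    seed_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.streamlines)


def _world_to_voxel(points: np.ndarray, inv_affine: np.ndarray) -> np.ndarray:
    return points @ inv_affine[:3, :3].T + inv_affine[:3, 3]


def _voxel_to_world(vox: np.ndarray, affine: np.ndarray) -> np.ndarray:
    return vox @ affine[:3, :3].T + affine[:3, 3]


def seed_points(region: RegionMask, affine: np.ndarray, params: TrackingParams) -> np.ndarray:
    """Jittered seed points (world mm), ``seeds_per_voxel`` per region voxel.

    Deterministic given ``params.rng_seed``; every seed lies strictly
    inside its source voxel.
    """
    if region.n_voxels == 0:
        raise EmptyRegionError(f"seed region {region.acronym!r} is empty")
    rng = np.random.default_rng(params.rng_seed)
    idx = np.argwhere(region.grid).astype(float)  # (M, 3) voxel centers
    vox = np.repeat(idx, params.seeds_per_voxel, axis=0)
    vox = vox + rng.uniform(-0.499, 0.499, size=vox.shape)
    return _voxel_to_world(vox, np.asarray(affine, dtype=float))


def _track_batch(
    tensors: TensorVolume,
    fa: np.ndarray,
    seeds_world: np.ndarray,
    params: TrackingParams,
) -> list[np.ndarray | None]:
    """Integrate all seeds in parallel; None for rejected seeds."""
    shape = np.array(tensors.shape)
    affine = tensors.affine
    inv_affine = np.linalg.inv(affine)
    step = params.resolve_step(tensors.voxel_size_mm)
    cos_limit = np.cos(np.deg2rad(params.angle_stop_deg))
    e1 = tensors.principal_direction()
    mask = tensors.brain_mask & (fa >= params.fa_stop)

    n = len(seeds_world)
    vox0 = np.rint(_world_to_voxel(seeds_world, inv_affine)).astype(int)
    inside0 = np.all((vox0 >= 0) & (vox0 < shape), axis=1)
    ok = np.zeros(n, dtype=bool)
    ok[inside0] = mask[tuple(vox0[inside0].T)]

    halves: list[list[list[np.ndarray]]] = []
    for sign in (1.0, -1.0):
        pts: list[list[np.ndarray]] = [[] for _ in range(n)]
        pos = seeds_world.copy()
        d0 = np.zeros((n, 3))
        d0[ok] = e1[tuple(vox0[ok].T)]
        prev = sign * d0
        active = ok.copy()
        for _ in range(params.max_steps):
            if not active.any():
                break
            new_pos = pos + step * prev  # Euler step along current direction
            vox = np.rint(_world_to_voxel(new_pos, inv_affine)).astype(int)
            inb = np.all((vox >= 0) & (vox < shape), axis=1) & active
            good = np.zeros(n, dtype=bool)
            good[inb] = mask[tuple(vox[inb].T)]
            # direction at the new voxel, sign-aligned with the last step
            new_dir = np.zeros((n, 3))
            new_dir[good] = e1[tuple(vox[good].T)]
            dots = np.einsum("ij,ij->i", new_dir, prev)
            flip = dots < 0
            new_dir[flip] *= -1.0
            dots = np.abs(dots)
            good &= dots >= cos_limit  # turning-angle stop
            for i in np.nonzero(good)[0]:
                pts[i].append(new_pos[i].copy())
            pos = np.where(good[:, None], new_pos, pos)
            prev = np.where(good[:, None], new_dir, prev)
            active = good
        halves.append(pts)

    out: list[np.ndarray | None] = []
    for i in range(n):
        if not ok[i]:
            out.append(None)
            continue
        back = halves[1][i][::-1]
        line = back + [seeds_world[i]] + halves[0][i]
        if len(line) < 2:
            out.append(None)
        else:
            out.append(np.asarray(line))
    return out


def track_streamline(
    tensors: TensorVolume,
    fa_map: ScalarVolume,
    seed: Sequence[float],
    params: TrackingParams,
) -> np.ndarray | None:
    """Track a single seed; returns the polyline or None for a rejected seed."""
    res = _track_batch(tensors, fa_map.data, np.asarray([seed], dtype=float), params)
    return res[0]


def track_region(
    tensors: TensorVolume,
    fa_map: ScalarVolume,
    source: RegionMask,
    params: TrackingParams,
) -> StreamlineSet:
    """Seed the source region and track every seed."""
    seeds = seed_points(source, tensors.affine, params)
    lines = _track_batch(tensors, fa_map.data, seeds, params)
    keep = [i for i, ln in enumerate(lines) if ln is not None]
    return StreamlineSet(
        streamlines=[lines[i] for i in keep],
        seed_region=source.acronym,
        params=params,
        n_seeds=len(seeds),
        seed_indices=np.asarray(keep, dtype=int),
    )


def fiber_density(
    streamlines: StreamlineSet,
    target: RegionMask,
    affine: np.ndarray,
) -> tuple[int, float]:
    """(raw_count, density): streamlines with >=1 point in the target.

    Each streamline contributes at most 1 regardless of re-entries;
    density = raw_count / n_seeds.
    """
    if streamlines.n_seeds == 0:
        raise ParameterError("streamline set has zero seeds")
    inv_affine = np.linalg.inv(np.asarray(affine, dtype=float))
    shape = np.array(target.grid.shape)
    count = 0
    for line in streamlines.streamlines:
        vox = np.rint(_world_to_voxel(line, inv_affine)).astype(int)
        inb = np.all((vox >= 0) & (vox < shape), axis=1)
        if inb.any() and target.grid[tuple(vox[inb].T)].any():
            count += 1
    return count, count / streamlines.n_seeds


def pathway_profile(
    tensors: TensorVolume,
    fa_map: ScalarVolume,
    labels: LabelVolume,
    ontology: RegionOntology,
    source: tuple[str, str],
    targets: Sequence[tuple[str, str]],
    params: TrackingParams,
    ipsi_side: str = "right",
    subject_id: str = "",
    day: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Fiber density from one source region to each target region.

    ``source`` and each target are (acronym, hemisphere-tag) pairs; one
    tracking run from the source serves all targets.  Returns per-target
    rows and the summed density.
    """
    src_acr, src_hemi = source
    src = region_mask(labels, ontology, src_acr, src_hemi, ipsi_side=ipsi_side)
    if src.n_voxels == 0:
        raise EmptyRegionError(f"source region {src_acr!r} ({src_hemi}) is empty")
    sls = track_region(tensors, fa_map, src, params)
    rows = []
    for tgt_acr, tgt_hemi in targets:
        tgt = region_mask(labels, ontology, tgt_acr, tgt_hemi, ipsi_side=ipsi_side)
        raw, dens = fiber_density(sls, tgt, tensors.affine)
        rows.append(
            {
                "subject_id": subject_id,
                "day": day,
                "source": src_acr,
                "source_hemisphere": src_hemi,
                "target": tgt_acr,
                "target_hemisphere": tgt_hemi,
                "raw_count": raw,
                "fiber_density": dens,
                "n_seeds": sls.n_seeds,
            }
        )
    df = pd.DataFrame(rows)
    return df, float(df["fiber_density"].sum())


@dataclass
class TracerAgreement:
    covariance: float
    correlation: float
    p_value: float
    method: str
    dti_rank_order: list[int]  # indices, descending density
    tracer_rank_order: list[int]


def tracer_agreement(
    dti_densities: Sequence[float],
    tracer_densities: Sequence[float],
    method: str = "pearson",
) -> TracerAgreement:
    """Agreement between tractography and tracer projection densities.

    Sample covariance, correlation (Pearson by default, Spearman as
    option), and the descending rank order of each vector.
    """
    x = np.asarray(dti_densities, dtype=float)
    y = np.asarray(tracer_densities, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ParameterError("need equal-length 1-D vectors with >= 3 entries")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined: zero variance")
    cov = float(np.cov(x, y, ddof=1)[0, 1])
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ParameterError("method must be 'pearson' or 'spearman'")
    return TracerAgreement(
        covariance=cov,
        correlation=float(r),
        p_value=float(p),
        method=method,
        dti_rank_order=list(np.argsort(-x, kind="stable")),
        tracer_rank_order=list(np.argsort(-y, kind="stable")),
    )


def save_streamlines_json(sls: StreamlineSet, path: str | Path) -> None:
    payload = {
        "seed_region": sls.seed_region,
        "n_seeds": sls.n_seeds,
        "params": {
            "step_mm": sls.params.step_mm,
            "fa_stop": sls.params.fa_stop,
            "angle_stop_deg": sls.params.angle_stop_deg,
            "max_steps": sls.params.max_steps,
            "seeds_per_voxel": sls.params.seeds_per_voxel,
            "rng_seed": sls.params.rng_seed,
        },
        "streamlines": [ln.tolist() for ln in sls.streamlines],
    }
    Path(path).write_text(json.dumps(payload))


def load_streamlines_json(path: str | Path) -> StreamlineSet:
    payload = json.loads(Path(path).read_text())
    return StreamlineSet(
        streamlines=[np.asarray(ln, dtype=float) for ln in payload["streamlines"]],
        seed_region=payload["seed_region"],
        params=TrackingParams(**payload["params"]),
        n_seeds=payload["n_seeds"],
    )
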