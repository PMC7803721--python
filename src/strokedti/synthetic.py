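"""Synthetic two-protocol longitudinal stroke study generator.

Emulates the study design the analysis expects: a small- and a
large-stroke photothrombosis protocol plus sham controls, imaged at
baseline and days 1, 3, 7, 14, 21 and 28.  Everything is generated
directly in atlas space on a simplified bilateral Allen-style atlas:

* ellipsoidal cortical lesions whose day-1 to day-7 shrinkage and
  group-size separation follow the study's cohort factors (4.3x / 1.7x
  shrinkage; 1.8x day-1 and 2.7x day-28 separation), with a day-28
  "histology" mask calibrated to the groups' MOp coverage;
* diffusion tensors with three planted anisotropic pathways (ipsilesional
  thalamocortical, midline-crossing contralesional thalamocortical,
  transcallosal homotopic motor), degraded or enhanced per group and day;
* T2-like intensity volumes with a fading acute lesion and late
  ipsilesional thalamic hypointensity in the large group;
* behavior scores whose deficit scales with the day-1 lesion volume and
  recovers faster in the large group so the groups converge by day 28;
* a tracer projection-density reference whose rank order matches the
  planted bundle cross-sections.

All randomness flows from ``StudyDesign.rng_seed``; identical designs
produce identical studies.  Every planted effect can be switched off
(``EffectSizes.null()``), making the groups exchangeable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import LabelVolume, RegionOntology, load_ontology
from .diffusion import ScalarVolume, TensorVolume
from .errors import DesignError
from .lesion import BASELINE_DAY, LesionMask

DAYS = (-3, 1, 3, 7, 14, 21, 28)

GROUPS = ("small", "large", "control")

#: cortical targets of the thalamocortical pathways, strongest first
PATHWAY_TARGETS = ("SSp-ul", "SSp-ll", "MOp", "MOs", "SSs")


@dataclass(frozen=True)
class EffectSizes:
    """Planted effect sizes, defaulting to the study's cohort calibration."""

    # lesion geometry
    shrink_small: float = 4.3  # day-1 / day-7 volume fold
    shrink_large: float = 1.7
    protocol_contrast: float = 1.0  # 0 -> both protocols share one geometry
    size_jitter_sigma: float = 0.15  # lognormal sd of per-subject size factor
    center_jitter_sd: float = 0.5  # voxels, in-plane
    day_noise_sigma: float = 0.03  # lognormal sd of per-day size noise
    # diffusion effects
    thalamic_rd_gain: float = 0.20  # peak ipsi DORsm RD elevation, large group
    ipsi_degradation: float = 0.45  # peak ipsi-bundle radius loss, large group
    contra_gain: float = 1.0  # day-28 crossing-bundle recovery level, large group
    tensor_noise_sigma: float = 0.03
    # T2 effects
    t2_lesion_gain: float = 60.0  # acute lesion hyperintensity
    t2_dorsm_drop: float = 0.10  # late ipsi DORsm hypointensity, large group
    t2_noise_sd: float = 2.0
    # behavior
    behavior_coupling: float = 1.0  # scales deficit-per-mm3 of all measures
    behavior_noise_scale: float = 1.0

    @classmethod
    def null(cls) -> "EffectSizes":
        """All group-differential effects zeroed: groups are exchangeable."""
        return cls(
            shrink_small=1.0,
            shrink_large=1.0,
            protocol_contrast=0.0,
            thalamic_rd_gain=0.0,
            ipsi_degradation=0.0,
            contra_gain=0.0,
            t2_lesion_gain=0.0,
            t2_dorsm_drop=0.0,
            behavior_coupling=0.0,
        )


@dataclass(frozen=True)
class StudyDesign:
    n_small: int = 5
    n_large: int = 4
    n_control: int = 4
    days: tuple[int, ...] = DAYS
    rng_seed: int = 0
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (0.2, 0.2, 0.2)
    ipsi_side: str = "right"
    effects: EffectSizes = field(default_factory=EffectSizes)

    def __post_init__(self):
        if min(self.n_small, self.n_large, self.n_control) < 1:
            raise DesignError("all group sizes must be >= 1")
        if tuple(sorted(self.days)) != tuple(self.days):
            raise DesignError("days must be sorted")

    def subjects(self) -> list[tuple[str, str]]:
        out = []
        for g, n in (("small", self.n_small), ("large", self.n_large),
                     ("control", self.n_control)):
            out.extend((f"{g}_{i + 1:02d}", g) for i in range(n))
        return out


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    ipsi_side: str
    index: int  # position in the study roster, used for rng streams
    masks: dict[tuple[int, str], LesionMask] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# atlas layout.  Boxes are (lo, hi) index fractions of the 48-voxel
# reference grid, right hemisphere; the left hemisphere is the mirror
# image.  The x midline gap keeps the volume flip-symmetric.

_R = 48.0


def _frac(lo: float, hi: float) -> tuple[float, float]:
    return lo / _R, hi / _R


_RIGHT_BOXES: dict[str, tuple] = {
    # acronym: (x, y, z) fraction ranges
    "MOs": (_frac(28, 46), _frac(4, 11), _frac(34, 44)),
    "MOp": (_frac(28, 46), _frac(11, 19), _frac(34, 44)),
    "SSp-ul": (_frac(28, 46), _frac(19, 25), _frac(34, 44)),
    "SSp-un": (_frac(28, 46), _frac(25, 31), _frac(34, 44)),
    "SSp-ll": (_frac(28, 46), _frac(31, 37), _frac(34, 44)),
    "SSs": (_frac(25, 46), _frac(37, 45), _frac(34, 44)),
    "ACA": (_frac(25, 28), _frac(4, 37), _frac(34, 44)),
    "cc": (_frac(25, 46), _frac(4, 45), _frac(31, 34)),
    "DORsm": (_frac(26, 33), _frac(19, 28), _frac(18, 27)),
    "DORpm": (_frac(26, 33), _frac(28, 37), _frac(18, 27)),
    "STRd": (_frac(34, 43), _frac(8, 19), _frac(18, 29)),
}

#: dorsal right-quadrant box lesions are clipped to (cortex + callosum depth)
_LESION_CLIP = (_frac(25, 46), _frac(4, 45), _frac(30, 44))

#: brain mask box (generous hull around all labels)
_BRAIN_BOX = (_frac(2, 46), _frac(2, 46), _frac(10, 46))


def _box_slices(box, shape) -> tuple[slice, slice, slice]:
    return tuple(
        slice(int(round(lo * dim)), int(round(hi * dim)))
        for (lo, hi), dim in zip(box, shape)
    )


def make_atlas(
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size_mm: tuple[float, float, float] = (0.2, 0.2, 0.2),
    rng_seed: int = 0,
) -> tuple[RegionOntology, LabelVolume]:
    """Bilateral mirror-symmetric label volume plus its region ontology.

    The layout is deterministic (``rng_seed`` is accepted for interface
    symmetry but the labels carry no random texture); region volumes
    depend only on ``shape``.
    """
    shape = tuple(int(s) for s in shape)
    if min(shape) < 32:
        raise DesignError(f"shape {shape} too small; need >= 32 per axis")
    if shape[0] % 2:
        raise DesignError("x dimension must be even (mirror symmetry)")
    ontology = load_ontology()
    grid = np.zeros(shape, dtype=np.int32)
    for acr, box in _RIGHT_BOXES.items():
        rid = ontology.by_acronym(acr).region_id
        grid[_box_slices(box, shape)] = rid
    # mirror right -> left; the two central x columns stay background
    half = shape[0] // 2
    grid[: half - 1] = 0
    grid[half - 1] = 0
    grid[half] = 0
    grid[: half] = grid[::-1][: half]
    labels = LabelVolume(
        grid=grid,
        voxel_size_mm=voxel_size_mm,
        midline_index=half,
    )
    labels.validate_labels(ontology)
    for acr in _RIGHT_BOXES:
        ids = list(ontology.descendants(acr))
        for sel in ("left", "right"):
            hemi = labels.hemisphere_selector(sel)
            if not (np.isin(grid, ids) & hemi).any():
                raise DesignError(f"region {acr!r} empty on {sel} at shape {shape}")
    return ontology, labels


def brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[_box_slices(_BRAIN_BOX, shape)] = True
    return mask


# ---------------------------------------------------------------------------
# lesions

#: ellipsoid geometry per protocol at the 48-voxel reference scale
#: (center x/y/z, day-1 in-plane semi-axes ax/ay, vertical semi-axis az);
#: the histology entries are the separately calibrated day-28 masks.
_LESION_GEOMETRY = {
    "small": {"center": (37.0, 21.9, 41.0), "ax": 8.4, "ay": 9.9, "az": 9.0},
    "large": {"center": (36.0, 16.0, 41.0), "ax": 9.8, "ay": 13.0, "az": 11.0},
    "small_histology": {"center": (37.0, 19.2, 41.0), "ax": 4.9, "ay": 6.2, "az": 9.0},
    "large_histology": {"center": (36.0, 16.0, 41.0), "ax": 7.2, "ay": 9.6, "az": 11.0},
}

#: T2 in-plane scale relative to day 1 (day-7 values are filled in from the
#: configured shrinkage factors; later days keep shrinking mildly)
_T2_DAY_SCALE_TAIL = {14: 0.95, 21: 0.90, 28: 0.85}  # x day-7 scale


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[k] - center[k]) / semiaxes[k]) ** 2 for k in range(3))
    return q <= 1.0


def _lesion_day_scales(effects: EffectSizes, group: str, days) -> dict[int, float]:
    shrink = effects.shrink_small if group == "small" else effects.shrink_large
    s7 = 1.0 / np.sqrt(shrink)  # in-plane scale; volume scales with its square
    scales = {}
    for d in days:
        if d <= 0:
            continue
        if d == 1:
            scales[d] = 1.0
        elif d < 7:
            scales[d] = float(s7 ** ((d - 1) / 6.0))
        elif d == 7:
            scales[d] = s7
        else:
            scales[d] = s7 * _T2_DAY_SCALE_TAIL.get(d, 0.85)
    return scales


def make_lesions(
    design: StudyDesign, atlas: tuple[RegionOntology, LabelVolume]
) -> dict[str, SyntheticSubject]:
    """Per-subject lesion-mask series (T2 at every day, histology at day 28).

    Controls get empty masks.  Stroke subjects get an ellipsoidal cortical
    lesion clipped to the dorsal ipsilesional quadrant, with lognormal
    per-subject size jitter shared across days so cohort volume ratios
    concentrate around the configured shrinkage and separation factors.
    """
    _, labels = atlas
    shape = labels.shape
    ref = shape[1] / _R  # geometry scale factor relative to the 48 grid
    eff = design.effects
    clip = np.zeros(shape, dtype=bool)
    clip[_box_slices(_LESION_CLIP, shape)] = True
    subjects: dict[str, SyntheticSubject] = {}
    for index, (sid, group) in enumerate(design.subjects()):
        rng = np.random.default_rng([design.rng_seed, 101, index])
        subj = SyntheticSubject(sid, group, design.ipsi_side, index)
        if group == "control":
            for d in design.days:
                subj.masks[(d, "T2WI")] = LesionMask(
                    np.zeros(shape, bool), sid, d, "T2WI")
            subj.masks[(28, "histology")] = LesionMask(
                np.zeros(shape, bool), sid, 28, "histology")
            subjects[sid] = subj
            continue
        size = float(rng.lognormal(0.0, eff.size_jitter_sigma))
        jitter = rng.normal(0.0, eff.center_jitter_sd, size=2)
        geo_group = group if eff.protocol_contrast else "small"
        geo = _LESION_GEOMETRY[geo_group]
        cx = geo["center"][0] * ref + jitter[0]
        cy = geo["center"][1] * ref + jitter[1]
        cz = geo["center"][2] * ref
        scales = _lesion_day_scales(eff, group, design.days)
        for d in design.days:
            if d == BASELINE_DAY or d <= 0:
                subj.masks[(d, "T2WI")] = LesionMask(np.zeros(shape, bool), sid, d, "T2WI")
                continue
            s = scales[d] * size * float(rng.lognormal(0.0, eff.day_noise_sigma))
            grid = _ellipsoid_mask(
                shape, (cx, cy, cz),
                (geo["ax"] * ref * s, geo["ay"] * ref * s, geo["az"] * ref),
            ) & clip
            subj.masks[(d, "T2WI")] = LesionMask(grid, sid, d, "T2WI")
        hist = _LESION_GEOMETRY[f"{geo_group}_histology"]
        s = size * float(rng.lognormal(0.0, eff.day_noise_sigma))
        grid = _ellipsoid_mask(
            shape,
            (hist["center"][0] * ref + jitter[0], hist["center"][1] * ref + jitter[1],
             hist["center"][2] * ref),
            (hist["ax"] * ref * s, hist["ay"] * ref * s, hist["az"] * ref),
        ) & clip
        subj.masks[(28, "histology")] = LesionMask(grid, sid, 28, "histology")
        subjects[sid] = subj
    return subjects


def lesion_volume_table(
    subjects: dict[str, SyntheticSubject], labels: LabelVolume
) -> pd.DataFrame:
    rows = []
    for subj in subjects.values():
        for (day, modality), mask in subj.masks.items():
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "group": subj.group,
                    "day": day,
                    "modality": modality,
                    "volume_mm3": mask.n_voxels * labels.voxel_volume_mm3,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tensors

_BG_LAM = (0.786e-3, 0.670e-3, 0.670e-3)  # background, FA ~ 0.1
_TUBE_LAM = (1.60e-3, 0.35e-3)  # (parallel, perpendicular), FA ~ 0.75
_LESION_LAM = 1.5e-3  # near-isotropic, elevated MD

#: pathway tube definitions at the 48 reference scale: waypoints the
#: smooth centerline passes through (voxel coordinates, right = ipsi)
#: and the baseline tube radius in voxels.
_IPSI_TUBES = [  # DORsm -> cortical targets; radii set the planted strengths
    ("SSp-ul", [(27.5, 20.5, 19), (27.5, 20.5, 26), (30, 21, 32), (35, 22, 37), (37, 22, 43)], 2.0),
    ("SSp-ll", [(31.0, 24.5, 19), (31.0, 25.0, 26), (33, 28, 32), (36, 32, 37), (37, 34, 43)], 1.7),
    ("MOp", [(27.5, 25.5, 19), (27.5, 24.5, 25), (33, 20, 30), (34, 16, 36), (35, 14, 43)], 1.4),
    ("MOs", [(31.0, 19.5, 19), (31.5, 17.5, 25), (33, 13.5, 31), (34.5, 9.5, 37), (35, 8, 43)], 1.35),
    ("SSs", [(29.5, 27.5, 19), (30.0, 28.5, 25), (32, 32, 31), (34, 38, 37), (35, 41, 43)], 1.2),
]
_CONTRA_DORSM_TUBE = (
    [(18, 24, 24), (18, 24, 28), (22, 24.5, 32), (35, 25, 32.5), (41, 24, 36), (42, 23.5, 43)],
    1.5,
)
_TRANSCALLOSAL_TUBES = [
    ("MOp", [(8, 16.5, 43), (8, 16.0, 36), (11, 15.5, 33), (24, 15, 32),
             (40, 15, 33), (42, 15, 36), (42, 15, 43)], 2.0),
    ("MOs", [(8, 11.5, 43), (8, 11.5, 36), (12, 11, 33), (24, 10, 32),
             (37, 9, 33), (39, 8.5, 36), (39, 8.5, 43)], 1.2),
]

#: per-(group, day) multiplicative schedules for bundle radius (density)
#: and anisotropy.  Values at day 1 encode the acute state, day 28 the
#: chronic state; controls sit at 1.0 throughout.
_SCHED_DAYS = (1, 3, 7, 14, 21, 28)


def _interp_schedule(day: int, knots: dict[int, float]) -> float:
    if day <= 0:
        return 1.0
    days = sorted(knots)
    return float(np.interp(day, days, [knots[d] for d in days]))


def _ipsi_radius_scale(group: str, day: int, eff: EffectSizes) -> float:
    if group != "large":
        return 1.0
    peak = 1.0 - eff.ipsi_degradation  # day-28 level
    knots = {1: 1.0, 3: 0.98, 7: 0.93, 14: 1.0 - 0.55 * eff.ipsi_degradation,
             21: 1.0 - 0.8 * eff.ipsi_degradation, 28: peak}
    return _interp_schedule(day, knots)


def _contra_radius_scale(group: str, day: int, eff: EffectSizes) -> float:
    if group == "control":
        return 1.0
    if eff.contra_gain == 0 and eff.ipsi_degradation == 0:
        return 1.0  # null study: no planted crossing effect
    if group == "large":
        knots = {1: 0.55, 3: 0.60, 7: 0.70, 14: 0.85, 21: 0.95,
                 28: min(1.05, eff.contra_gain)}
    else:
        knots = {1: 0.80, 3: 0.75, 7: 0.70, 14: 0.65, 21: 0.60, 28: 0.55}
    return _interp_schedule(day, knots)


def _transcallosal_radius_scale(group: str, day: int, eff: EffectSizes) -> float:
    if group == "control":
        return 1.0
    if eff.contra_gain == 0 and eff.ipsi_degradation == 0:
        return 1.0
    if group == "large":
        knots = {1: 0.60, 3: 0.65, 7: 0.75, 14: 0.9, 21: 1.0, 28: 1.05}
    else:
        knots = {1: 0.90, 3: 0.90, 7: 0.90, 14: 0.90, 21: 0.90, 28: 0.90}
    return _interp_schedule(day, knots)


def _ipsi_fa_scale(group: str, day: int, eff: EffectSizes) -> float:
    if group != "large" or eff.ipsi_degradation == 0:
        return 1.0
    return _interp_schedule(day, {1: 1.0, 7: 0.95, 28: 0.75})


def _rd_gain(group: str, day: int, eff: EffectSizes) -> float:
    """Ipsilesional DORsm radial-diffusivity elevation (large group only)."""
    if group != "large" or eff.thalamic_rd_gain == 0:
        return 0.0
    knots = {1: 0.0, 3: -0.25, 7: 0.1, 14: 0.4, 21: 0.7, 28: 1.0}
    return eff.thalamic_rd_gain * _interp_schedule(day, {1: 0.0, **knots})


def _bezier_like(points: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Smooth curve through waypoints (cubic-spline resample) + tangents."""
    from scipy.interpolate import CubicSpline

    points = np.asarray(points, float)
    t = np.linspace(0, 1, len(points))
    cs = CubicSpline(t, points, axis=0)
    u = np.linspace(0, 1, n)
    pts = cs(u)
    tan = cs(u, 1)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    return pts, tan


def _paint_tube(
    data: np.ndarray,
    center_pts: np.ndarray,
    tangents: np.ndarray,
    radius: float,
    lam_par: float,
    lam_perp: float,
) -> None:
    """Write prolate tensors (aligned with the local tangent) into a tube."""
    shape = data.shape[:3]
    r_int = int(np.ceil(radius))
    offs = np.array(
        [
            (i, j, k)
            for i in range(-r_int, r_int + 1)
            for j in range(-r_int, r_int + 1)
            for k in range(-r_int, r_int + 1)
            if i * i + j * j + k * k <= radius * radius
        ],
        dtype=int,
    )
    centers = np.rint(center_pts).astype(int)
    for c, t in zip(centers, tangents):
        vox = c + offs
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        outer = np.outer(t, t)
        d = lam_perp * np.eye(3) + (lam_par - lam_perp) * outer
        t6 = np.array([d[0, 0], d[0, 1], d[0, 2], d[1, 1], d[1, 2], d[2, 2]])
        data[vox[:, 0], vox[:, 1], vox[:, 2]] = t6


def _mirror_path(points: np.ndarray, shape_x: int) -> np.ndarray:
    pts = np.asarray(points, float).copy()
    pts[:, 0] = (shape_x - 1) - pts[:, 0]
    return pts


def make_tensors(
    design: StudyDesign,
    atlas: tuple[RegionOntology, LabelVolume],
    subject: SyntheticSubject,
    day: int,
) -> tuple[TensorVolume, ScalarVolume]:
    """Tensor volume and FA map for one subject/day.

    Background is mildly anisotropic (FA ~ 0.1, below the tracking
    threshold); the three pathway systems are painted as prolate-tensor
    tubes whose radius and anisotropy follow the group x day schedules;
    lesion voxels are near-isotropic with elevated MD.
    """
    ontology, labels = atlas
    shape = labels.shape
    ref = shape[1] / _R
    eff = design.effects
    rng = np.random.default_rng([design.rng_seed, 202, subject.index, max(day, 0)])

    data = np.zeros(shape + (6,), dtype=float)
    data[..., 0] = _BG_LAM[0]
    data[..., 3] = _BG_LAM[1]
    data[..., 5] = _BG_LAM[2]

    n_samples = int(180 * ref)
    radius_noise = float(rng.lognormal(0.0, 0.04))

    def paint(points, radius, scale, fa_scale=1.0):
        if radius * scale <= 0:
            return
        pts, tan = _bezier_like(np.asarray(points, float) * ref, n_samples)
        lam_perp = _TUBE_LAM[1]
        lam_par = lam_perp + (_TUBE_LAM[0] - lam_perp) * fa_scale
        _paint_tube(data, pts, tan, radius * ref * scale * radius_noise,
                    lam_par, lam_perp)

    # lesion voxels: near-isotropic with elevated MD.  Painted before the
    # pathway tubes so bundle degradation follows the group x day schedules
    # rather than the acute edema footprint.
    mask = subject.masks.get((day, "T2WI"))
    if mask is not None and mask.n_voxels:
        lam = _LESION_LAM * (1.0 + _interp_schedule(day, {1: 0.0, 28: 0.3}))
        data[mask.grid, :] = 0.0
        data[mask.grid, 0] = lam
        data[mask.grid, 3] = lam * 0.98
        data[mask.grid, 5] = lam * 0.96

    ipsi_right = subject.ipsi_side == "right"

    def side(points, mirror=False):  # geometry is defined for a right-side stroke
        pts = np.asarray(points, float)
        if mirror != (not ipsi_right):
            pts = _mirror_path(pts, _R)
        return pts

    # healthy-hemisphere thalamocortical system: mirror image of the
    # ipsilesional tubes, never modulated
    for _, points, radius in _IPSI_TUBES:
        paint(side(points, mirror=True), radius, 1.0)
    for _, points, radius in _TRANSCALLOSAL_TUBES:
        paint(side(points), radius,
              _transcallosal_radius_scale(subject.group, day, eff))
    # midline-crossing contralesional DORsm -> ipsilesional cortex bundle
    paint(side(_CONTRA_DORSM_TUBE[0]), _CONTRA_DORSM_TUBE[1],
          _contra_radius_scale(subject.group, day, eff))
    # ipsilesional thalamocortical tubes, painted last so their corridors
    # win boundary grazes with the crossing bundle
    fa_s = _ipsi_fa_scale(subject.group, day, eff)
    for _, points, radius in _IPSI_TUBES:
        paint(side(points), radius, _ipsi_radius_scale(subject.group, day, eff), fa_s)

    # ipsilesional DORsm radial-diffusivity elevation (secondary degeneration)
    gain = _rd_gain(subject.group, day, eff)
    if gain:
        hemi = labels.hemisphere_selector(subject.ipsi_side)
        dorsm = np.isin(labels.grid, list(ontology.descendants("DORsm"))) & hemi
        data[dorsm, 3] *= 1.0 + gain
        data[dorsm, 5] *= 1.0 + gain

    # subject/day noise: overall scale (FA-invariant) + small diagonal jitter
    bm = brain_mask(shape)
    scale = rng.lognormal(0.0, eff.tensor_noise_sigma, size=shape)
    data *= scale[..., None]
    diag_noise = rng.normal(0.0, 0.5e-5, size=shape + (3,))
    data[..., 0] += diag_noise[..., 0]
    data[..., 3] += diag_noise[..., 1]
    data[..., 5] += diag_noise[..., 2]
    data[~bm] = 0.0
    data[~bm, 0] = data[~bm, 3] = data[~bm, 5] = 1e-5

    affine = np.diag([*labels.voxel_size_mm, 1.0])
    tensors = TensorVolume(data=data, brain_mask=bm, affine=affine,
                           voxel_size_mm=labels.voxel_size_mm)
    fa_map = tensors.metric_volume("FA")
    return tensors, fa_map


# ---------------------------------------------------------------------------
# T2 and behavior


def make_t2(
    design: StudyDesign,
    atlas: tuple[RegionOntology, LabelVolume],
    subject: SyntheticSubject,
    day: int,
) -> ScalarVolume:
    """T2-like intensity volume: uniform tissue, fading acute lesion
    hyperintensity, and late ipsilesional DORsm hypointensity in the
    large group (iron accumulation)."""
    ontology, labels = atlas
    shape = labels.shape
    eff = design.effects
    rng = np.random.default_rng([design.rng_seed, 303, subject.index, max(day, 0)])
    bm = brain_mask(shape)
    data = np.where(bm, 100.0, 0.0)
    mask = subject.masks.get((day, "T2WI"))
    if mask is not None and mask.n_voxels and day >= 1:
        data[mask.grid] += eff.t2_lesion_gain * np.exp(-(day - 1) / 7.0)
    if subject.group == "large" and eff.t2_dorsm_drop:
        drop = eff.t2_dorsm_drop * _interp_schedule(day, {1: 0.0, 7: 0.2, 14: 0.5, 28: 1.0})
        hemi = labels.hemisphere_selector(subject.ipsi_side)
        dorsm = np.isin(labels.grid, list(ontology.descendants("DORsm"))) & hemi
        data[dorsm] *= 1.0 - drop
    if eff.t2_noise_sd > 0:
        data = data + rng.normal(0.0, eff.t2_noise_sd, size=shape) * bm
    return ScalarVolume(data, np.diag([*labels.voxel_size_mm, 1.0]), "T2WI")


#: behavior measures: (baseline level, deficit per severity unit, noise sd)
_BEHAVIOR_MEASURES = {
    "hindlimb_drops": (2.0, 0.25, 0.6),
    "paw_drags_pct": (12.0, 0.6, 1.5),
    "foot_faults_pct": (5.0, 0.5, 1.0),
}

#: recovery time constants (days); larger strokes recover faster so the
#: group behavior curves converge by day 28
_RECOVERY_TAU = {"small": 12.0, "large": 7.5}

#: extra deficit weight per unit of day-1 MOp involvement (fraction 0-1):
#: lesions that hit the motor cortex hurt disproportionately
_MOP_SEVERITY_WEIGHT = 2.0

#: fraction of a subject's severity deviation (from the group mean) that
#: reaches the behavioral readout
_SEVERITY_SHRINKAGE = 0.25


def make_behavior(
    design: StudyDesign,
    volumes: pd.DataFrame,
    mop_coverage: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format behavior table coupled to lesion size and location.

    ``volumes`` must hold T2WI volumes with columns (subject_id, group,
    day, volume_mm3); ``mop_coverage`` optionally maps subject to day-1
    MOp percent-infarct.  The severity of a subject is
    V(day 1) x (1 + w x MOp_coverage), and the deficit at day d >= 1 is
    coupling x severity x exp(-(d - 1)/tau_group) on top of a flat
    baseline, with truncated-normal noise; controls stay at baseline.
    """
    eff = design.effects
    v1 = (
        volumes[(volumes["day"] == 1)]
        .set_index("subject_id")["volume_mm3"]
        .to_dict()
    )
    mop_coverage = mop_coverage or {}
    groups = dict(design.subjects())
    raw_sev = {
        sid: v1.get(sid, 0.0)
        * (1.0 + _MOP_SEVERITY_WEIGHT * mop_coverage.get(sid, 0.0) / 100.0)
        for sid, _ in design.subjects()
    }
    # behavior integrates damage imperfectly: subjects express the
    # group-typical severity plus a damped individual deviation, which
    # keeps the deficit-volume coupling positive at realistic group spread
    group_mean = {
        g: np.mean([raw_sev[s] for s, gg in design.subjects() if gg == g])
        for g in ("small", "large")
    }
    rows = []
    for index, (sid, group) in enumerate(design.subjects()):
        rng = np.random.default_rng([design.rng_seed, 404, index])
        if group in group_mean:
            severity = group_mean[group] + _SEVERITY_SHRINKAGE * (
                raw_sev[sid] - group_mean[group]
            )
        else:
            severity = 0.0
        for day in design.days:
            for measure, (base, coupling, sd) in _BEHAVIOR_MEASURES.items():
                level = base
                if group in _RECOVERY_TAU and day >= 1:
                    level += (eff.behavior_coupling * coupling * severity
                              * np.exp(-(day - 1) / _RECOVERY_TAU[group]))
                noise = rng.normal(0.0, sd * eff.behavior_noise_scale)
                value = max(0.0, level + noise)  # truncated at the valid floor
                if measure.endswith("_pct"):
                    value = min(value, 100.0)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": groups[sid],
                        "day": day,
                        "measure": measure,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tracer reference


def make_tracer_reference(
    atlas: tuple[RegionOntology, LabelVolume] | None = None,
) -> pd.DataFrame:
    """Viral projection-density reference table.

    DORsm densities are proportional to the planted bundle cross-sections
    (radius squared), so their rank order matches the synthetic anatomy;
    DORpm projections are weak and flat.
    """
    rows = []
    total = sum(r * r for _, _, r in _IPSI_TUBES)
    for target, _, radius in _IPSI_TUBES:
        rows.append({"source": "DORsm", "target": target,
                     "projection_density": 0.6 * radius**2 / total})
    for i, target in enumerate(PATHWAY_TARGETS):
        rows.append({"source": "DORpm", "target": target,
                     "projection_density": 0.02 + 0.002 * i})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study assembly and disk round-trip


@dataclass
class SyntheticStudy:
    design: StudyDesign
    ontology: RegionOntology
    labels: LabelVolume
    subjects: dict[str, SyntheticSubject]
    volumes: pd.DataFrame
    behavior: pd.DataFrame
    tracer_reference: pd.DataFrame

    def tensors(self, subject_id: str, day: int) -> tuple[TensorVolume, ScalarVolume]:
        return make_tensors(self.design, (self.ontology, self.labels),
                            self.subjects[subject_id], day)

    def t2(self, subject_id: str, day: int) -> ScalarVolume:
        return make_t2(self.design, (self.ontology, self.labels),
                       self.subjects[subject_id], day)


def generate_study(design: StudyDesign) -> SyntheticStudy:
    """Generate the full in-memory study (volumes are created on demand)."""
    ontology, labels = make_atlas(design.shape, design.voxel_size_mm, design.rng_seed)
    subjects = make_lesions(design, (ontology, labels))
    volumes = lesion_volume_table(subjects, labels)
    t2_vols = volumes[volumes["modality"] == "T2WI"]
    from .atlas import region_mask
    from .lesion import percent_infarct

    mop = region_mask(labels, ontology, "MOp", "ipsi", ipsi_side=design.ipsi_side)
    coverage = {
        sid: percent_infarct(subj.masks[(1, "T2WI")], mop)
        for sid, subj in subjects.items()
    }
    behavior = make_behavior(design, t2_vols, mop_coverage=coverage)
    tracer = make_tracer_reference((ontology, labels))
    return SyntheticStudy(design, ontology, labels, subjects, volumes, behavior, tracer)


def write_study(design: StudyDesign, out_dir: str | Path) -> Path:
    """Materialize a study directory: NIfTI volumes, CSV tables, manifest."""
    study = generate_study(design)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.labels.to_nifti(out / "atlas_labels.nii.gz")
    (out / "ontology.json").write_text(
        json.dumps(
            [
                {"id": r.region_id, "acronym": r.acronym, "name": r.name,
                 "parent_id": r.parent_id}
                for r in study.ontology
            ]
        )
    )
    study.volumes.to_csv(out / "lesion_volumes.csv", index=False)
    study.behavior.to_csv(out / "behavior.csv", index=False)
    study.tracer_reference.to_csv(out / "tracer_reference.csv", index=False)
    (out / "design.yaml").write_text(
        yaml.safe_dump(
            {
                "n_small": design.n_small,
                "n_large": design.n_large,
                "n_control": design.n_control,
                "days": list(design.days),
                "rng_seed": design.rng_seed,
                "shape": list(design.shape),
                "voxel_size_mm": list(design.voxel_size_mm),
                "ipsi_side": design.ipsi_side,
                "effects": {k: float(v) for k, v in design.effects.__dict__.items()},
            }
        )
    )
    manifest = {"subjects": [], "days": list(design.days)}
    affine = np.diag([*design.voxel_size_mm, 1.0])
    for sid, subj in study.subjects.items():
        subj_dir = out / "subjects" / sid
        subj_dir.mkdir(parents=True, exist_ok=True)
        entry = {"subject_id": sid, "group": subj.group,
                 "ipsi_side": subj.ipsi_side, "masks": []}
        for (day, modality), mask in subj.masks.items():
            name = f"lesion_day{day:+03d}_{modality}.nii.gz"
            import nibabel as nib

            nib.save(nib.Nifti1Image(mask.grid.astype(np.uint8), affine),
                     str(subj_dir / name))
            entry["masks"].append({"day": day, "modality": modality, "file": name})
        manifest["subjects"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_study(study_dir: str | Path) -> SyntheticStudy:
    """Reload a study directory written by :func:`write_study`.

    Volumetric modalities (tensors, T2) are regenerated on demand from the
    stored design, which is exact because generation is deterministic.
    """
    import nibabel as nib

    study_dir = Path(study_dir)
    cfg = yaml.safe_load((study_dir / "design.yaml").read_text())
    eff = EffectSizes(**cfg.pop("effects"))
    design = StudyDesign(
        effects=eff,
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in cfg.items()
        },
    )
    ontology = load_ontology(study_dir / "ontology.json")
    labels = LabelVolume.from_nifti(study_dir / "atlas_labels.nii.gz",
                                    midline_index=design.shape[0] // 2)
    manifest = json.loads((study_dir / "manifest.json").read_text())
    subjects: dict[str, SyntheticSubject] = {}
    for index, entry in enumerate(manifest["subjects"]):
        subj = SyntheticSubject(entry["subject_id"], entry["group"],
                                entry["ipsi_side"], index)
        for m in entry["masks"]:
            img = nib.load(str(study_dir / "subjects" / entry["subject_id"] / m["file"]))
            subj.masks[(m["day"], m["modality"])] = LesionMask(
                np.asanyarray(img.dataobj).astype(bool),
                entry["subject_id"], m["day"], m["modality"])
        subjects[entry["subject_id"]] = subj
    volumes = pd.read_csv(study_dir / "lesion_volumes.csv")
    behavior = pd.read_csv(study_dir / "behavior.csv")
    tracer = pd.read_csv(study_dir / "tracer_reference.csv")
    return SyntheticStudy(design, ontology, labels, subjects, volumes, behavior, tracer)
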