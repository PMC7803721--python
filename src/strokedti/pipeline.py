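"""End-to-end study analysis: lesion mapping, diffusion, tracking, statistics.

``run_study`` drives the four analysis stages over a study directory (or
an in-memory synthetic study), writing one CSV per analysis table plus a
versioned JSON report.  Stage outputs are pure functions of (inputs,
config); existing stage tables are reused on rerun unless ``overwrite``
is set, and a rerun with the same config reproduces byte-identical
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffusion as dif
from . import lesion as les
from . import stats as st
from .atlas import region_mask
from .synthetic import (
    PATHWAY_TARGETS,
    SyntheticStudy,
    load_study,
)
from .tractography import TrackingParams, pathway_profile, tracer_agreement

log = logging.getLogger("strokedti")

REPORT_SCHEMA_VERSION = 1

#: the three study pathways: (name, source (region, hemi), targets)
STUDY_PATHWAYS = (
    ("ipsi_thalamocortical", ("DORsm", "ipsi"),
     tuple((t, "ipsi") for t in PATHWAY_TARGETS)),
    ("contra_thalamocortical", ("DORsm", "contra"),
     tuple((t, "ipsi") for t in PATHWAY_TARGETS)),
    ("transcallosal_motor", ("MOp", "contra"),
     tuple((t, "ipsi") for t in PATHWAY_TARGETS)),
)


@dataclass
class PipelineConfig:
    study_dir: str | Path | None = None
    out_dir: str | Path = "strokedti_out"
    alpha: float = 0.05
    profile_regions: tuple[str, ...] = les.PROFILE_REGIONS
    tracking: TrackingParams = field(default_factory=TrackingParams)
    track_days: tuple[int, ...] = (1, 28)
    diffusion_days: tuple[int, ...] = (1, 3, 7, 14, 21, 28)
    rng_seed: int = 0
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        tracking = TrackingParams(**cfg.pop("tracking", {}))
        for key in ("profile_regions", "track_days", "diffusion_days"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return cls(tracking=tracking, **cfg)


def _stage_table(config: PipelineConfig, name: str, compute) -> pd.DataFrame:
    """Run one stage with file-level caching."""
    out = Path(config.out_dir) / "tables" / f"{name}.csv"
    if out.exists() and not config.overwrite:
        log.info("stage %s: cached (%s)", name, out)
        return pd.read_csv(out)
    log.info("stage %s: computing", name)
    df = compute()
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    return df


# ---------------------------------------------------------------------------
# stages


def lesion_stage(study: SyntheticStudy, config: PipelineConfig):
    labels, ontology = study.labels, study.ontology
    ipsi = study.design.ipsi_side
    volumes = study.volumes.copy()

    def incidence():
        frames = []
        for day, modality in ((1, "T2WI"), (7, "T2WI"), (28, "histology")):
            masks = [s.masks[(day, modality)] for s in study.subjects.values()
                     if s.group in ("small", "large")]
            for group in ("small", "large"):
                gmasks = [m for m in masks
                          if study.subjects[m.subject_id].group == group]
                t = les.incidence_map(gmasks, labels, ontology, day, ipsi_side=ipsi)
                t["modality"] = modality
                t["group"] = group
                frames.append(t)
        return pd.concat(frames, ignore_index=True)

    def profiles():
        rows = []
        for subj in study.subjects.values():
            if subj.group == "control":
                continue
            for (day, modality), mask in sorted(subj.masks.items()):
                if day < 1:
                    continue
                prof = les.lesion_profile(mask, labels, ontology, ipsi_side=ipsi,
                                          regions=config.profile_regions)
                for region, pct in zip(prof.regions, prof.percent):
                    rows.append({"subject_id": subj.subject_id, "group": subj.group,
                                 "day": day, "modality": modality, "region": region,
                                 "percent_infarct": pct,
                                 "total_volume_mm3": prof.total_volume_mm3})
        return pd.DataFrame(rows)

    inc = _stage_table(config, "incidence", incidence)
    prof = _stage_table(config, "lesion_profiles", profiles)

    def slopes():
        rows = []
        t2 = prof[prof["modality"] == "T2WI"]
        for (sid, region), g in t2.groupby(["subject_id", "region"]):
            by_day = g.set_index("day")["percent_infarct"]
            if 1 in by_day.index and 7 in by_day.index:
                rows.append({
                    "subject_id": sid,
                    "group": g["group"].iloc[0],
                    "region": region,
                    "slope_pct_per_day": les.consolidation_slope(
                        by_day.loc[1], by_day.loc[7]),
                })
        return pd.DataFrame(rows)

    slope = _stage_table(config, "consolidation_slopes", slopes)

    # Ward clustering of day-7 lesion profiles (percent-infarct vector
    # plus total volume), k = 2
    t2d7 = prof[(prof["modality"] == "T2WI") & (prof["day"] == 7)]
    wide = t2d7.pivot_table(index="subject_id", columns="region",
                            values="percent_infarct")
    wide = wide[list(config.profile_regions)]
    vol7 = t2d7.groupby("subject_id")["total_volume_mm3"].first()
    X = np.column_stack([wide.to_numpy(), vol7[wide.index].to_numpy()])
    ward = les.ward_cluster(X, k=2)
    cluster = pd.DataFrame({
        "subject_id": wide.index,
        "group": [study.subjects[s].group for s in wide.index],
        "cluster": ward.assignments,
    })
    cluster = _stage_table(config, "ward_clusters", lambda: cluster)
    return {
        "volumes": volumes,
        "incidence": inc,
        "profiles": prof,
        "slopes": slope,
        "clusters": cluster,
        "ward": ward,
    }


def diffusion_stage(study: SyntheticStudy, config: PipelineConfig):
    labels, ontology = study.labels, study.ontology
    ipsi = study.design.ipsi_side

    def compute():
        rows = []
        for subj in study.subjects.values():
            for day in config.diffusion_days:
                if day not in study.design.days:
                    continue
                tensors, _ = study.tensors(subj.subject_id, day)
                t2 = study.t2(subj.subject_id, day)
                for region in ("DORsm", "DORpm"):
                    r_ipsi = region_mask(labels, ontology, region, "ipsi", ipsi)
                    r_contra = region_mask(labels, ontology, region, "contra", ipsi)
                    for metric in ("RD", "FA"):
                        vol = tensors.metric_volume(metric)
                        vi = dif.region_mean(vol, r_ipsi, tensors.brain_mask)
                        vc = dif.region_mean(vol, r_contra, tensors.brain_mask)
                        rows.append({
                            "subject_id": subj.subject_id, "group": subj.group,
                            "day": day, "region": region, "metric": metric,
                            "ipsi": vi, "contra": vc,
                            "norm_pct": dif.ipsi_contra_norm(vi, vc),
                        })
                    rows.append({
                        "subject_id": subj.subject_id, "group": subj.group,
                        "day": day, "region": region, "metric": "T2_density_ratio",
                        "ipsi": np.nan, "contra": np.nan,
                        "norm_pct": dif.integrated_density_ratio(t2, r_ipsi, r_contra),
                    })
                mask = subj.masks.get((day, "T2WI"))
                if mask is not None and mask.n_voxels:
                    roi = dif.lesion_roi_metrics(tensors, mask)
                    for metric, value in roi.items():
                        rows.append({
                            "subject_id": subj.subject_id, "group": subj.group,
                            "day": day, "region": "lesion", "metric": metric,
                            "ipsi": value, "contra": np.nan, "norm_pct": np.nan,
                        })
        return pd.DataFrame(rows)

    return {"region_metrics": _stage_table(config, "region_metrics", compute)}


def tractography_stage(study: SyntheticStudy, config: PipelineConfig):
    labels, ontology = study.labels, study.ontology
    ipsi = study.design.ipsi_side

    def compute():
        frames = []
        for subj in study.subjects.values():
            for day in config.track_days:
                tensors, fa = study.tensors(subj.subject_id, day)
                for name, source, targets in STUDY_PATHWAYS:
                    df, total = pathway_profile(
                        tensors, fa, labels, ontology, source, targets,
                        config.tracking, ipsi_side=ipsi,
                        subject_id=subj.subject_id, day=day)
                    df["pathway"] = name
                    df["group"] = subj.group
                    df["total_density"] = total
                    frames.append(df)
        return pd.concat(frames, ignore_index=True)

    conn = _stage_table(config, "connectivity", compute)

    def agreement():
        ref = study.tracer_reference
        ref_d = ref[ref["source"] == "DORsm"].set_index("target")["projection_density"]
        rows = []
        day = config.track_days[0]
        sub = conn[(conn["pathway"] == "ipsi_thalamocortical") & (conn["day"] == day)]
        for sid, g in sub.groupby("subject_id"):
            if study.subjects[sid].group != "control":
                continue
            dens = g.set_index("target")["fiber_density"]
            targets = [t for t in PATHWAY_TARGETS if t in dens.index]
            agr = tracer_agreement(dens[targets].to_numpy(),
                                   ref_d[targets].to_numpy())
            rows.append({"subject_id": sid, "day": day,
                         "covariance": agr.covariance,
                         "correlation": agr.correlation,
                         "p_value": agr.p_value})
        return pd.DataFrame(rows)

    agr = _stage_table(config, "tracer_agreement", agreement)
    return {"connectivity": conn, "tracer_agreement": agr}


def stats_stage(study: SyntheticStudy, config: PipelineConfig,
                lesion_out, diffusion_out, tract_out):
    alpha = config.alpha
    results: list[st.TestResult] = []
    post_days = [d for d in study.design.days if d >= 1]

    # behavior: group x time per measure
    for measure in sorted(study.behavior["measure"].unique()):
        results.extend(st.group_time_test(
            study.behavior, measure, ["small", "large", "control"],
            post_days, alpha=alpha))

    # lesion volumetry: small vs large at days 1 and 7 (Holm-Sidak family)
    vols = lesion_out["volumes"]
    t2 = vols[vols["modality"] == "T2WI"]
    pairs, labels_ = [], []
    for day in (1, 7):
        a = t2[(t2["group"] == "small") & (t2["day"] == day)]["volume_mm3"].to_numpy()
        b = t2[(t2["group"] == "large") & (t2["day"] == day)]["volume_mm3"].to_numpy()
        pairs.append((a, b))
        labels_.append(f"lesion volume day {day}: small vs large")
    results.extend(st.holm_sidak_ttests(pairs, labels_, alpha=alpha))

    # consolidation slope per region: small vs large
    slopes = lesion_out["slopes"]
    pairs, labels_ = [], []
    for region, g in slopes.groupby("region"):
        pairs.append((g[g["group"] == "small"]["slope_pct_per_day"].to_numpy(),
                      g[g["group"] == "large"]["slope_pct_per_day"].to_numpy()))
        labels_.append(f"consolidation slope {region}: small vs large")
    results.extend(st.holm_sidak_ttests(pairs, labels_, alpha=alpha))

    # thalamic RD asymmetry over time
    rm = diffusion_out["region_metrics"]
    rd = rm[(rm["region"] == "DORsm") & (rm["metric"] == "RD")]
    if not rd.empty:
        rd_table = rd.rename(columns={"norm_pct": "value"})[
            ["subject_id", "group", "day", "value"]].assign(measure="DORsm_RD_norm")
        results.extend(st.group_time_test(
            rd_table, "DORsm_RD_norm", ["small", "large", "control"],
            sorted(rd["day"].unique()), alpha=alpha))

    # fiber densities: three-group Kruskal-Wallis + Dunn, per pathway/day
    conn = tract_out["connectivity"]
    totals = conn.groupby(["pathway", "day", "subject_id", "group"])[
        "total_density"].first().reset_index()
    for (pathway, day), g in totals.groupby(["pathway", "day"]):
        samples = [g[g["group"] == grp]["total_density"].to_numpy()
                   for grp in ("small", "large", "control")]
        if any(len(s) < 2 for s in samples):
            continue
        for r in st.kruskal_dunn(samples, ["small", "large", "control"], alpha=alpha):
            r.comparison = f"{pathway} day {day}: {r.comparison}"
            results.append(r)

    # lesion-behavior correlations
    beh = study.behavior
    stroke = t2[t2["group"].isin(["small", "large"])]
    v1 = stroke[stroke["day"] == 1].set_index("subject_id")["volume_mm3"]
    v28 = stroke[stroke["day"] == 28].set_index("subject_id")["volume_mm3"]
    corr_rows = []
    for measure in sorted(beh["measure"].unique()):
        d3 = beh[(beh["day"] == 3) & (beh["measure"] == measure)
                 & beh["group"].isin(["small", "large"])]
        d3 = d3.set_index("subject_id")["value"]
        for vol, vol_name in ((v1, "day-1 volume"), (v28, "day-28 volume")):
            common = [s for s in vol.index if s in d3.index]
            r, r2, p = st.correlate(d3[common].to_numpy(), vol[common].to_numpy())
            corr_rows.append({"measure": measure, "against": vol_name,
                              "r": r, "r_squared": r2, "p": p, "n": len(common)})
    correlations = pd.DataFrame(corr_rows)

    tests = st.results_frame(results)
    tests = _stage_table(config, "tests", lambda: tests)
    correlations = _stage_table(config, "correlations", lambda: correlations)
    return {"tests": tests, "correlations": correlations}


# ---------------------------------------------------------------------------


def run_study(config: PipelineConfig,
              study: SyntheticStudy | None = None) -> dict:
    """Run the full analysis and write the report bundle.

    ``study`` may be passed directly (synthetic in-memory study);
    otherwise ``config.study_dir`` is loaded.
    """
    if study is None:
        if config.study_dir is None:
            raise ValueError("either study or config.study_dir is required")
        study = load_study(config.study_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("lesion mapping stage")
    lesion_out = lesion_stage(study, config)
    log.info("diffusion stage")
    diffusion_out = diffusion_stage(study, config)
    log.info("tractography stage")
    tract_out = tractography_stage(study, config)
    log.info("statistics stage")
    stats_out = stats_stage(study, config, lesion_out, diffusion_out, tract_out)

    clusters = lesion_out["clusters"]
    small_clusters = set(clusters[clusters["group"] == "small"]["cluster"])
    large_clusters = set(clusters[clusters["group"] == "large"]["cluster"])
    agr = tract_out["tracer_agreement"]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "n_subjects": len(study.subjects),
        "groups": {g: int((study.volumes.groupby("subject_id")["group"].first() == g).sum())
                   for g in ("small", "large", "control")},
        "ward": {
            "inter_cluster_distance": lesion_out["ward"].inter_cluster_distance,
            "intra_cluster_distance": lesion_out["ward"].intra_cluster_distance,
            "clusters_match_protocols": bool(not (small_clusters & large_clusters)),
        },
        "tracer_agreement": {
            "mean_covariance": float(agr["covariance"].mean()) if len(agr) else None,
            "mean_correlation": float(agr["correlation"].mean()) if len(agr) else None,
            "n_controls": int(len(agr)),
        },
        "n_significant_tests": int(stats_out["tests"]["significant"].sum()),
        "tables": sorted(p.name for p in (out / "tables").glob("*.csv")),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return {
        **lesion_out,
        **diffusion_out,
        **tract_out,
        **stats_out,
        "report": report,
    }
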