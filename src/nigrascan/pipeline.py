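"""End-to-end composition: phantoms -> maps -> VOIs -> features -> statistics.

``run_pipeline`` simulates a cohort, fits T2* maps, normalizes neuromelanin
images, builds control-group population templates, segments them into the
six MRI VOIs, extracts every subject's 58 MRI features, computes the seven
DAT-SPECT SBR values, runs the group statistics, and evaluates the
classifier suite on both feature families, writing each artifact (CSV/JSON
plus a provenance sidecar) under the configured output directory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import train_eval_cv
from .config import PipelineConfig
from .datspect import SBR_COLUMNS, compute_sbr_record, normalize_uptake
from .phantom import (DAT_LABELS, CohortSpec, cohort_to_frame, generate_cohort,
                      generate_datspect_phantom, generate_multiecho_phantom)
from .radiomics import extract_feature_vector, mri_feature_names
from .relaxometry import (NormalizedNMMap, extract_neuromelanin, fit_t2star,
                          normalize_neuromelanin)
from .stats import compare_groups, correlate_with_lr
from .voi import (build_population_template, define_dat_vois, define_nm_vois,
                  define_t2star_vois, kmeans_segment)

__all__ = ["run_pipeline", "extract_mri_features", "build_mri_vois"]


def build_mri_vois(nm_maps: list, t2_maps: list, midbrain_masks: list,
                   config: PipelineConfig):
    """Control-group templates -> k-means (k=3) -> the six MRI VOIs."""
    nm_template = build_population_template([m.values for m in nm_maps],
                                            midbrain_masks)
    t2_values = [np.where(t.valid_mask, t.values, np.nan) for t in t2_maps]
    t2_template = build_population_template(t2_values, midbrain_masks)

    nm_mask = np.isfinite(nm_template)
    nm_labels = kmeans_segment(nm_template, nm_mask, k=config.kmeans_k,
                               seed=config.seed)
    nm_vois = define_nm_vois(nm_labels, nm_template,
                             min_component=config.min_component,
                             voxel_size=config.voxel_size)
    t2_mask = np.isfinite(t2_template)
    t2_labels = kmeans_segment(t2_template, t2_mask, k=config.kmeans_k,
                               seed=config.seed)
    t2_vois = define_t2star_vois(t2_labels, t2_template,
                                 min_component=config.min_component,
                                 voxel_size=config.voxel_size)
    merged = dict(nm_vois.masks)
    merged.update(t2_vois.masks)
    from .voi import VOISet
    return VOISet(masks=merged, voxel_size=tuple(config.voxel_size)), \
        nm_template, t2_template


def extract_mri_features(nm: NormalizedNMMap, t2, vois,
                         config: PipelineConfig) -> dict:
    return extract_feature_vector(
        nm, t2, vois, n_levels=config.glcm_levels,
        distance=config.glcm_distance,
        nm_volume_threshold=config.nm_volume_threshold)


def _stage(log: list, name: str, **info):
    log.append({"stage": name, **info})


def run_pipeline(config: PipelineConfig, spec: CohortSpec | None = None) -> dict:
    """Run the full pipeline on a simulated cohort; write artifacts.

    Returns a dict with the feature table, VOI sets, statistics frames, and
    the two classification reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list = []
    if spec is None:
        spec = CohortSpec(n_per_group=dict(config.n_per_group),
                          echo_times=tuple(config.echo_times),
                          voxel_size=tuple(config.voxel_size),
                          seed=config.seed)

    cohort = generate_cohort(spec)
    meta = cohort_to_frame(cohort)
    _stage(log, "simulate", n_subjects=len(cohort))

    # relaxometry per subject
    nm_maps, t2_maps, midbrains = {}, {}, {}
    for subj in cohort:
        vol, midbrain, reference = generate_multiecho_phantom(spec, subj)
        nm_raw = extract_neuromelanin(vol)
        nm_maps[subj.subject_id] = normalize_neuromelanin(
            nm_raw, reference, voxel_size=spec.voxel_size)
        t2_maps[subj.subject_id] = fit_t2star(vol, mask=None,
                                              t2star_cap=config.t2star_cap)
        midbrains[subj.subject_id] = midbrain
    _stage(log, "relaxometry", n_maps=len(t2_maps))

    # population templates from the control group, VOIs for everyone
    controls = [s.subject_id for s in cohort if s.group == "NMNC"]
    if not controls:
        raise RuntimeError("pipeline requires NMNC subjects to build templates")
    mri_vois, nm_template, t2_template = build_mri_vois(
        [nm_maps[s] for s in controls], [t2_maps[s] for s in controls],
        [midbrains[s] for s in controls], config)
    _stage(log, "voi", counts=mri_vois.counts())

    rows = []
    for subj in cohort:
        feats = extract_mri_features(nm_maps[subj.subject_id],
                                     t2_maps[subj.subject_id], mri_vois, config)
        rows.append(feats)
    features = pd.concat([meta, pd.DataFrame(rows, index=meta.index)], axis=1)
    _stage(log, "features", n_columns=len(mri_feature_names()))

    # DAT-SPECT: control ratio template defines the VOIs applied to everyone
    uptakes = {s.subject_id: generate_datspect_phantom(spec, s) for s in cohort}
    occ = DAT_LABELS["occipital"]
    ratios = {sid: normalize_uptake(u.values, u.label_map == occ,
                                    voxel_size=u.voxel_size)
              for sid, u in uptakes.items()}
    ratio_template = np.mean([ratios[s].values for s in controls], axis=0)
    dat_vois = define_dat_vois(ratio_template,
                               uptakes[controls[0]].label_map, DAT_LABELS,
                               striatal_threshold=config.dat_striatal_threshold,
                               brainstem_threshold=config.dat_brainstem_threshold,
                               voxel_size=spec.dat_voxel_size)
    for col in SBR_COLUMNS:
        features[col] = [compute_sbr_record(ratios[s.subject_id], dat_vois)[col]
                         for s in cohort]
    _stage(log, "sbr", counts=dat_vois.counts())

    # statistics: PD vs low-LR controls; LR correlations in the NM groups
    feature_cols = mri_feature_names() + list(SBR_COLUMNS)
    lr = features["lr_score"].astype(float)
    pd_vs_ctrl = features[(features["group"] == "PD")
                          | ((features["group"] == "NMNC")
                             & (lr < config.lr_cutoff))]
    comparisons = compare_groups(pd_vs_ctrl, "group", feature_cols)
    nonmanifest = features[features["group"].isin(["NMC", "NMNC"])]
    correlations = correlate_with_lr(nonmanifest, "lr_score", feature_cols,
                                     q=config.fdr_q)
    _stage(log, "stats", n_comparisons=len(comparisons))

    # classification on both feature families
    labels = pd_vs_ctrl["group"].to_numpy()
    mri_report = train_eval_cv(pd_vs_ctrl[mri_feature_names()], labels,
                               n_folds=config.n_folds, seed=config.seed,
                               variance_target=config.pca_variance)
    sbr_report = train_eval_cv(pd_vs_ctrl[list(SBR_COLUMNS)], labels,
                               n_folds=config.n_folds, seed=config.seed)
    _stage(log, "classify", best_mri=mri_report.best_algorithm,
           best_sbr=sbr_report.best_algorithm)

    # artifacts
    features.to_csv(out / "features.csv", index=False)
    _comparison_frame(comparisons).to_csv(out / "stats_groups.csv", index=False)
    _correlation_frame(correlations).to_csv(out / "stats_lr.csv", index=False)
    (out / "voi_manifest.json").write_text(json.dumps(
        {"mri": mri_vois.counts(), "dat": dat_vois.counts()}, indent=2))
    (out / "classification.json").write_text(json.dumps({
        "mri": {"metrics": mri_report.metrics,
                "n_components_retained": mri_report.n_components_retained,
                "best": mri_report.best_algorithm},
        "sbr": {"metrics": sbr_report.metrics,
                "best": sbr_report.best_algorithm},
    }, indent=2, default=float))
    (out / "provenance.json").write_text(json.dumps({
        "config": json.loads(config.to_json()),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "version": __version__,
        "log": log,
    }, indent=2))

    return {"features": features, "mri_vois": mri_vois, "dat_vois": dat_vois,
            "nm_template": nm_template, "t2_template": t2_template,
            "comparisons": comparisons, "correlations": correlations,
            "mri_report": mri_report, "sbr_report": sbr_report, "log": log}


def _comparison_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"feature": r.feature, "F": r.statistic, "p": r.p_value,
               "degenerate": r.degenerate}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
            row[f"sd_{g}"] = r.group_sds[g]
        rows.append(row)
    return pd.DataFrame(rows)


def _correlation_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{"feature": r.feature, "r": r.r, "p": r.p_value,
                          "n": r.n, "fdr_significant": r.fdr_significant,
                          "degenerate": r.degenerate} for r in results])
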