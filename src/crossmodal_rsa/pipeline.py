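"""End-to-end orchestration: simulate -> searchlight -> clusters -> ROI fits.

The two analysis pipelines are (1) discovery: map within-modality (or
modality-difference) distances with the searchlight, run group cluster
inference, and turn surviving clusters into ROIs; and (2) ROI model fitting:
average the per-searchlight RDMs inside each ROI per subject, fit the model
battery with tau-a, and test the group.  Producer-identity models are routed
through leave-one-participant-out ROIs because they are not orthogonal to
the selection statistic (see :mod:`crossmodal_rsa.roi`).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .conditions import ConditionSpace, cell_mask
from .io import RunConfig
from .models import ModelRDM
from .roi import (
    LeaveOneOutROISet,
    ROI,
    ROISet,
    clusters_to_rois,
    leave_one_out_rois,
    match_rois_by_overlap,
    orthogonality_guard,
    roi_mean_rdm,
)
from .searchlight import (
    ClusterResult,
    RDMStore,
    SearchlightSpec,
    StatMap,
    cluster_inference,
    group_map,
    run_searchlight,
    sphere_offsets,
)
from .simulate import Cohort, SceneConfig, box_region, generate_cohort
from .stats import RegionFit, fit_models_in_region, fit_rdm, one_sample_t

SELECTOR_NAMES = ("within_modality_combined", "within_speech_across_speaker",
                  "within_sign_across_signer")


def default_scene_config(cfg: RunConfig) -> SceneConfig:
    """Four planted box regions — one per archetype — in separate octants."""
    dims = cfg.dims
    size = cfg.region_size
    corners = {
        "shared_semantic": (1, 1, 1),
        "speech_form": (dims[0] - size[0] - 1, 1, 1),
        "sign_form": (1, dims[1] - size[1] - 1, 1),
        "null": (dims[0] - size[0] - 1, dims[1] - size[1] - 1, 1),
    }
    regions = [
        box_region(name, dims, corner, size, archetype=name,
                   strength=0.0 if name == "null" else cfg.region_strength)
        for name, corner in corners.items()
    ]
    return SceneConfig(
        n_subjects=cfg.n_subjects,
        n_runs=cfg.n_runs,
        dims=dims,
        voxel_size_mm=cfg.voxel_size_mm,
        regions=regions,
        noise_sd=cfg.noise_sd,
        smooth_fwhm_mm=cfg.smooth_fwhm_mm,
        n_residual_frames=cfg.n_residual_frames,
        subject_jitter_sd=cfg.subject_jitter_sd,
        seed=cfg.seed,
    )


@dataclass
class SearchlightResult:
    maps: dict[str, list[StatMap]]      # selector name -> per-subject maps
    stores: list[RDMStore]
    spec: SearchlightSpec
    lam: float | None


def searchlight_cohort(
    cohort: Cohort,
    spec: SearchlightSpec | None = None,
    radius_mm: float = 8.0,
    lam: float | None = None,
    store_rdms: bool = True,
) -> SearchlightResult:
    """Run the three within-modality searchlight statistics for every subject
    in one pass per subject, keeping per-center RDMs for ROI averaging."""
    space = cohort.space
    if spec is None:
        spec = sphere_offsets(cohort.config.voxel_size_mm, radius_mm)
    selectors = [cell_mask(space, name) for name in SELECTOR_NAMES]
    maps: dict[str, list[StatMap]] = {name: [] for name in SELECTOR_NAMES}
    stores: list[RDMStore] = []
    for subj in cohort.subjects:
        smaps, store = run_searchlight(
            subj, spec, selectors, lam=lam, store_rdms=store_rdms
        )
        for name in SELECTOR_NAMES:
            maps[name].append(smaps[name])
        if store is not None:
            stores.append(store)
    return SearchlightResult(maps=maps, stores=stores, spec=spec, lam=lam)


@dataclass
class DiscoveryResult:
    statistic: str
    tmap: StatMap
    clusters: ClusterResult
    rois: ROISet


def discover_regions(
    sl: SearchlightResult,
    statistic: str = "within_modality_combined",
    cluster_forming_p: float = 0.005,
    q: float = 0.05,
    n_permutations: int = 500,
    seed: int = 0,
) -> DiscoveryResult:
    """Group cluster inference on one searchlight statistic.

    ``statistic`` is a selector name for a greater-than-zero test, or
    ``"speech_gt_sign"`` / ``"sign_gt_speech"`` for the paired contrasts
    between the two within-modality maps.
    """
    paired = {
        "speech_gt_sign": ("within_speech_across_speaker",
                           "within_sign_across_signer"),
        "sign_gt_speech": ("within_sign_across_signer",
                           "within_speech_across_speaker"),
    }
    if statistic in paired:
        a, b = paired[statistic]
        tmap = group_map(sl.maps[a], test="paired", maps_b=sl.maps[b])
        clusters = cluster_inference(
            tmap, sl.maps[a], maps_b=sl.maps[b],
            cluster_forming_p=cluster_forming_p, q=q,
            n_permutations=n_permutations, seed=seed,
        )
    else:
        tmap = group_map(sl.maps[statistic], test="one_sample")
        clusters = cluster_inference(
            tmap, sl.maps[statistic],
            cluster_forming_p=cluster_forming_p, q=q,
            n_permutations=n_permutations, seed=seed,
        )
    rois = clusters_to_rois(clusters, prefix=statistic,
                            provenance={"statistic": statistic})
    return DiscoveryResult(statistic=statistic, tmap=tmap,
                           clusters=clusters, rois=rois)


@dataclass
class ROIAnalysis:
    roi: ROI
    fit: RegionFit
    identity_fits: pd.DataFrame | None = None


def analyze_roi(
    roi: ROI,
    sl: SearchlightResult,
    models: dict[str, ModelRDM],
    space: ConditionSpace,
    selection_statistic: str = "within_modality_combined",
    loo_rois: LeaveOneOutROISet | None = None,
    alpha: float = 0.05,
) -> ROIAnalysis:
    """Fit the model battery inside one ROI with the orthogonality guard.

    Selection-orthogonal models are fit on the ROI's own mean RDMs; the
    producer-identity models are instead fit inside the matching
    leave-one-out ROI of each subject's family (skipped, with a note, when
    no leave-one-out set is supplied).
    """
    selection = cell_mask(space, selection_statistic) \
        if selection_statistic in SELECTOR_NAMES else \
        cell_mask(space, "within_modality_combined")
    subject_rdms = [roi_mean_rdm(store, roi) for store in sl.stores]
    safe_models = {}
    blocked = {}
    for key, model in models.items():
        if orthogonality_guard(model, selection, roi) == "pass":
            safe_models[key] = model
        else:
            blocked[key] = model
    fit = fit_models_in_region(subject_rdms, safe_models, region=roi.name,
                               alpha=alpha)

    identity_fits = None
    if blocked and loo_rois is not None:
        matched = match_rois_by_overlap(loo_rois, roi)
        rows = []
        for key, model in blocked.items():
            zs = []
            for s, store in enumerate(sl.stores):
                fam_roi = matched.get(s)
                if fam_roi is None:
                    continue
                rdm = roi_mean_rdm(store, fam_roi)
                fr = fit_rdm(rdm, model, subject=s, region=fam_roi.name)
                zs.append(fr.z)
            if len(zs) >= 2:
                gt = one_sample_t(zs, tail="greater")
                rows.append({
                    "model_key": key, "model": model.name,
                    "t": gt.t, "df": gt.df, "p": gt.p, "d_z": gt.d_z,
                    "n": gt.n, "significant": gt.p < fit.alpha,
                })
        identity_fits = pd.DataFrame(rows)
        # identity evidence feeds the verdict (it was withheld from the
        # same-data fit for orthogonality)
        pvals = {r["model_key"]: r["p"] for r in fit.group.to_dict("records")}
        for r in (identity_fits.to_dict("records") if not identity_fits.empty else []):
            pvals[r["model_key"]] = r["p"]
        from .stats import classify_region
        fit.verdict = classify_region(pvals, fit.alpha)
    return ROIAnalysis(roi=roi, fit=fit, identity_fits=identity_fits)


def run_discovery_pipeline(
    cfg: RunConfig,
    features: pd.DataFrame,
    statistic: str = "within_modality_combined",
    cohort: Cohort | None = None,
) -> tuple[Cohort, SearchlightResult, DiscoveryResult, list[ROIAnalysis]]:
    """The full chain on a synthetic scene: simulate, map, cluster, fit."""
    from .stats import standard_model_set

    if cohort is None:
        cohort = generate_cohort(default_scene_config(cfg), seed=cfg.seed,
                                 features=features)
    sl = searchlight_cohort(cohort, radius_mm=cfg.radius_mm, lam=cfg.shrinkage)
    disc = discover_regions(
        sl, statistic=statistic, cluster_forming_p=cfg.cluster_forming_p,
        q=cfg.q, n_permutations=cfg.n_permutations, seed=cfg.seed,
    )
    sel_for_loo = statistic if statistic in SELECTOR_NAMES else None
    if sel_for_loo is not None:
        loo = leave_one_out_rois(sl.maps[sel_for_loo],
                                 threshold_p=cfg.loo_threshold_p)
    else:
        a, b = (("within_speech_across_speaker", "within_sign_across_signer")
                if statistic == "speech_gt_sign" else
                ("within_sign_across_signer", "within_speech_across_speaker"))
        loo = leave_one_out_rois(sl.maps[a], maps_b=sl.maps[b],
                                 threshold_p=cfg.loo_threshold_p)
    models = standard_model_set(cohort.space, features)
    from .stats import adjust_alpha

    alpha = adjust_alpha(cfg.base_alpha, max(1, len(disc.rois)))
    analyses = [
        analyze_roi(roi, sl, models, cohort.space,
                    selection_statistic=statistic, loo_rois=loo,
                    alpha=alpha)
        for roi in disc.rois
    ]
    return cohort, sl, disc, analyses
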