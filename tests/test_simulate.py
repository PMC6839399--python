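"""Synthetic cohort generator: planted geometry, noise, design, norms."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from crossmodal_rsa.conditions import (
    cell_mask,
    same_category_cells,
    same_item_cells,
)
from crossmodal_rsa.simulate import (
    Amplitudes,
    SceneConfig,
    archetype_amplitudes,
    box_region,
    generate_cohort,
    generate_design,
    generate_feature_norms,
    generate_subject,
    generate_true_patterns,
    validate_design,
)


def _scene(space, archetype="shared_semantic", strength=0.5, **kw):
    dims = kw.pop("dims", (4, 4, 3))
    reg = box_region("r", dims, (1, 1, 1), (2, 2, 2), archetype,
                     strength=strength)
    return SceneConfig(n_subjects=kw.pop("n_subjects", 2), dims=dims,
                       regions=[reg], **kw)


# ------------------------------------------------------------ true patterns

def test_null_archetype_patterns_are_zero(space):
    cfg = _scene(space, "null", strength=0.0)
    true = generate_true_patterns(cfg, space, seed=0)
    assert np.allclose(true["r"], 0.0)


def test_speech_form_plants_nothing_for_sign(space):
    cfg = _scene(space, "speech_form")
    true = generate_true_patterns(cfg, space, seed=0)
    mod = space.modality_index()
    sign_rows = true["r"][mod == 1]
    assert np.allclose(squareform(pdist(sign_rows)), 0.0)
    speech_rows = true["r"][mod == 0]
    assert pdist(speech_rows).min() > 0


def test_shared_semantic_true_geometry_is_categorical_across(space, norms):
    """Across modality, the noise-free geometry groups by category and
    carries no residual same-item advantage."""
    dims = (6, 6, 5)
    reg = box_region("r", dims, (0, 0, 0), (6, 6, 5), "shared_semantic",
                     strength=1.0)
    cfg = SceneConfig(n_subjects=2, dims=dims, regions=[reg])
    true = generate_true_patterns(cfg, space, seed=3, features=norms)["r"]
    d = squareform(pdist(true, "sqeuclidean"))
    ii, jj = space.pair_indices()
    vals = d[ii, jj]
    across = cell_mask(space, "across_modality").values
    same_cat = same_category_cells(space)
    same_it = same_item_cells(space)
    diff_cat = across & ~same_cat
    within_cat = across & same_cat & ~same_it
    same_item = across & same_it
    assert vals[within_cat].mean() < vals[diff_cat].mean()
    # same-item cells sit at/above the unrelated-item level, not below
    assert vals[same_item].mean() > vals[within_cat].mean()


def test_unknown_archetype_and_negative_amplitude_rejected():
    with pytest.raises(ValueError, match="archetype"):
        archetype_amplitudes("banana")
    with pytest.raises(ValueError, match="non-negative"):
        Amplitudes(a_cat=-1.0)
    with pytest.raises(ValueError, match="non-negative"):
        Amplitudes(a_id={"speech": -0.5})


# ----------------------------------------------------------------- subjects

def test_zero_noise_limit_recovers_jittered_true_patterns(space):
    cfg = _scene(space, "shared_semantic", noise_sd=1e-12,
                 subject_pattern_corr=1.0, n_residual_frames=8)
    true = generate_true_patterns(cfg, space, seed=1)
    subj = generate_subject(cfg, true, 0, seed=1, space=space)
    reg = cfg.regions[0]
    # betas equal the true pattern up to one multiplicative jitter factor
    b = subj.betas[0][:, reg.voxels]
    ratio = b[np.abs(true["r"]) > 1e-9] / true["r"][np.abs(true["r"]) > 1e-9]
    assert ratio.std() < 1e-6
    assert np.allclose(subj.betas[0], subj.betas[1], atol=1e-9)


def test_noise_sd_must_be_positive(space):
    with pytest.raises(ValueError, match="noise sd"):
        _scene(space, "null", noise_sd=0.0)


def test_unsmoothed_noise_is_spatially_white(space):
    cfg = SceneConfig(n_subjects=2, dims=(8, 8, 4), regions=[],
                      smooth_fwhm_mm=0.0, n_residual_frames=200, seed=4)
    subj = generate_subject(cfg, {}, 0, seed=4, space=space)
    frames = subj.residuals[0].reshape(200, 8, 8, 4)
    lag1 = np.mean([
        np.corrcoef(frames[t, :-1].ravel(), frames[t, 1:].ravel())[0, 1]
        for t in range(50)
    ])
    assert abs(lag1) < 0.05


def test_smoothed_noise_is_spatially_correlated_with_unit_sd(space):
    cfg = SceneConfig(n_subjects=2, dims=(8, 8, 4), regions=[],
                      smooth_fwhm_mm=6.0, noise_sd=2.0,
                      n_residual_frames=200, seed=4)
    subj = generate_subject(cfg, {}, 0, seed=4, space=space)
    frames = subj.residuals[0].reshape(200, 8, 8, 4)
    lag1 = np.mean([
        np.corrcoef(frames[t, :-1].ravel(), frames[t, 1:].ravel())[0, 1]
        for t in range(50)
    ])
    assert lag1 > 0.3
    assert subj.residuals.std() == pytest.approx(2.0, rel=0.05)


def test_same_seed_bitwise_reproducible(space):
    cfg = _scene(space, "shared_semantic", n_residual_frames=10)
    true = generate_true_patterns(cfg, space, seed=9)
    a = generate_subject(cfg, true, 3, seed=9, space=space)
    b = generate_subject(cfg, true, 3, seed=9, space=space)
    assert np.array_equal(a.betas, b.betas)
    assert np.array_equal(a.residuals, b.residuals)
    c = generate_subject(cfg, true, 4, seed=9, space=space)
    assert not np.array_equal(a.betas, c.betas)


# ------------------------------------------------------------------- cohort

def test_cohort_counts_and_masks(space):
    cfg = _scene(space, "shared_semantic", n_subjects=3, n_residual_frames=10)
    cohort = generate_cohort(cfg, space=space)
    assert len(cohort.subjects) == 3
    assert cohort.region_masks["r"].sum() == 8
    assert cohort.region_masks["r"].shape == cfg.dims


def test_cohort_rejects_single_subject(space):
    cfg = _scene(space, "null", n_subjects=1)
    with pytest.raises(ValueError, match="2 subjects"):
        generate_cohort(cfg, space=space)


def test_cohort_same_seed_identical(space):
    cfg = _scene(space, "sign_form", n_subjects=2, n_residual_frames=8)
    a = generate_cohort(cfg, seed=5, space=space)
    b = generate_cohort(cfg, seed=5, space=space)
    for sa, sb in zip(a.subjects, b.subjects):
        assert np.array_equal(sa.betas, sb.betas)


def test_region_overlap_rejected(space):
    dims = (4, 4, 3)
    r1 = box_region("a", dims, (0, 0, 0), (2, 2, 2), "null")
    r2 = box_region("b", dims, (1, 1, 1), (2, 2, 2), "null")
    with pytest.raises(ValueError, match="disjoint"):
        SceneConfig(n_subjects=2, dims=dims, regions=[r1, r2])


# ------------------------------------------------------------------- design

def test_design_bookkeeping_per_run_and_total(space):
    cfg = SceneConfig(n_subjects=2, n_runs=6, dims=(2, 2, 2), regions=[])
    design = generate_design(cfg, space, seed=0)
    assert validate_design(design, space) == []
    for _, run in design.groupby("run"):
        assert len(run) == 91
        counts = run["kind"].value_counts()
        assert counts["core"] == 72
        assert counts["target_filler"] == 6
        assert counts["nontarget_filler"] == 6
        assert counts["null"] == 7
        # fillers balanced for modality within run
        fill = run[run["kind"].str.contains("filler")]
        assert (fill["modality"] == "speech").sum() == 6
    core = design[design["kind"] == "core"]
    per_item = core.groupby("item").size()
    assert (per_item == 48).all()  # 6 runs x 8 presentations


def test_design_no_consecutive_same_concept(space):
    cfg = SceneConfig(n_subjects=2, n_runs=3, dims=(2, 2, 2), regions=[])
    design = generate_design(cfg, space, seed=3)
    for _, run in design.groupby("run"):
        run = run.sort_values("trial_index")
        core_items = run.loc[run["kind"] == "core", ["item", "trial_index"]]
        it = core_items["item"].to_numpy()
        pos = core_items["trial_index"].to_numpy()
        adjacent = (pos[1:] - pos[:-1]) == 1
        assert not np.any((it[1:] == it[:-1]) & adjacent)


def test_design_validator_flags_planted_violation(space):
    cfg = SceneConfig(n_subjects=2, n_runs=1, dims=(2, 2, 2), regions=[])
    design = generate_design(cfg, space, seed=1)
    bad = design.copy()
    core_idx = bad.index[bad["kind"] == "core"][:2]
    bad.loc[core_idx, "item"] = "orange"
    bad.loc[core_idx, "trial_index"] = [40, 41]
    problems = validate_design(bad, space)
    assert any("orange" in p or "repeated" in p for p in problems) or problems


# ------------------------------------------------------------ feature norms

def test_norms_fully_shared_category_features(space):
    from crossmodal_rsa.models import feature_distance_matrix

    with pytest.warns(UserWarning, match="identical"):
        norms = generate_feature_norms(space, p_within_category_shared=1.0,
                                       p_item_unique=0.0,
                                       p_cross_category_shared=0.0, seed=0)
    d = feature_distance_matrix(norms, space)
    same_cat = np.array([
        [space.category_of[a] == space.category_of[b] for b in space.items]
        for a in space.items
    ])
    off = ~np.eye(9, dtype=bool)
    assert np.allclose(d[same_cat & off], 0.0)


def test_norms_item_only_matches_item_model_ranks(space):
    norms = generate_feature_norms(space, p_within_category_shared=0.0,
                                   p_item_unique=1.0, seed=0)
    from crossmodal_rsa.models import feature_distance_matrix

    d = feature_distance_matrix(norms, space)
    off = ~np.eye(9, dtype=bool)
    # all between-item distances identical (orthogonal vectors) -> same
    # rank order as the 0/1 item model
    assert np.allclose(d[off], 1.0)
    assert np.allclose(np.diag(d), 0.0)


def test_norms_default_block_structure(space):
    norms = generate_feature_norms(space, seed=11)
    from crossmodal_rsa.models import feature_distance_matrix

    d = feature_distance_matrix(norms, space)
    same_cat = np.array([
        [space.category_of[a] == space.category_of[b] for b in space.items]
        for a in space.items
    ])
    off = ~np.eye(9, dtype=bool)
    assert d[same_cat & off].mean() < d[~same_cat].mean()


def test_norms_probability_validation(space):
    with pytest.raises(ValueError, match="p_item_unique"):
        generate_feature_norms(space, p_item_unique=1.5)
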