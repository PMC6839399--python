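"""Synthetic multi-subject cohorts with planted representational geometry.

The generator emulates the data the analysis consumes — run-wise condition
beta patterns plus GLM residual frames on a regular voxel grid — for a cohort
of subjects sharing one grid.  Signal is planted in disjoint regions, each
following one of four archetypes of representational geometry:

``shared_semantic``
    modality-invariant category code plus a modality-specific item code:
    categories cross-decode between speech and sign, items do not;
``speech_form``
    item and producer-identity codes for speech only (abstract spoken word
    forms), nothing for sign;
``sign_form``
    the mirror image for sign;
``null``
    no signal at all, for calibration.

Each pattern component is drawn standard-normal per voxel per level and then
frozen; amplitudes scale the components in beta units.  Noise is injected at
the beta level: a spatially smoothed Gaussian field, independent per run,
with matched residual frames drawn from the identical process so that the
noise-covariance estimator sees the covariance that actually corrupted the
betas.  Simulating the haemodynamic time series and the first-level GLM is
deliberately out of scope — the analysis starts at betas + residuals.

The module also generates the trial-level experimental design (91 trials per
run: 72 core, 6 target fillers, 6 non-target fillers, 7 nulls, with no
concept repeated back-to-back) and synthetic binary feature norms whose
induced dissimilarities have the within-category < between-category block
structure of published concept property norms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .conditions import ConditionSpace, build_condition_space

ARCHETYPES = ("shared_semantic", "speech_form", "sign_form", "null")

#: mean measured stimulus durations in seconds (spoken tokens are shorter
#: than signed ones) and the fixed null-trial duration
SPEECH_DURATION_S = 0.558
SIGN_DURATION_S = 1.107
NULL_DURATION_S = 4.0

N_TARGET_FILLERS_PER_RUN = 6
N_NONTARGET_FILLERS_PER_RUN = 6
N_NULLS_PER_RUN = 7
CORE_REPS_PER_RUN = 2

_TARGET_FILLER_POOL = (
    "house", "chair", "table", "shirt", "shoe", "hat",
    "guitar", "hammer", "spoon", "lamp", "door", "window",
    "book", "phone", "cup", "bed", "clock", "pen",
)
_NONTARGET_FILLER_POOL = (
    "banana", "pear", "cherry", "peach", "melon", "plum",
    "dog", "cat", "horse", "sheep", "rabbit", "bird",
    "car", "boat", "plane", "tram", "lorry", "scooter",
)


def _per_modality(value, modalities=("speech", "sign")) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {m: float(value.get(m, 0.0)) for m in modalities}
    else:
        out = {m: float(value) for m in modalities}
    if any(v < 0 for v in out.values()):
        raise ValueError("amplitudes must be non-negative")
    return out


@dataclass
class Amplitudes:
    """Pattern strengths (beta units) for the signal components.

    ``a_cat`` and ``a_item_shared`` are modality-invariant; ``a_item_within``
    and ``a_id`` may differ per modality (float applies to both).
    ``a_item_cross`` drives a modality-antisymmetric item component (speech
    maps it positively, sign negatively): it cancels out of every
    within-modality comparison but pushes same-item *across*-modality
    distances up to the level of unrelated items, emulating the empirical
    finding that a concept's spoken and signed forms are no closer than two
    arbitrary same-category concepts — without it, a categorical shared
    code mechanically leaves same-item cells lowest (same item implies same
    category) and an item model would always fit across modality.
    """

    a_cat: float = 0.0
    a_item_within: float | Mapping[str, float] = 0.0
    a_item_shared: float = 0.0
    a_id: float | Mapping[str, float] = 0.0
    a_item_cross: float = 0.0

    def __post_init__(self):
        if self.a_cat < 0 or self.a_item_shared < 0 or self.a_item_cross < 0:
            raise ValueError("amplitudes must be non-negative")
        self.a_item_within = _per_modality(self.a_item_within)
        self.a_id = _per_modality(self.a_id)


def archetype_amplitudes(archetype: str, strength: float = 0.5) -> Amplitudes:
    """Amplitude preset for one of the named geometry archetypes."""
    if strength < 0:
        raise ValueError("strength must be non-negative")
    if archetype == "shared_semantic":
        return Amplitudes(a_cat=strength, a_item_within=strength,
                          a_item_cross=strength)
    if archetype == "speech_form":
        return Amplitudes(a_item_within={"speech": strength}, a_id={"speech": strength})
    if archetype == "sign_form":
        return Amplitudes(a_item_within={"sign": strength}, a_id={"sign": strength})
    if archetype == "null":
        return Amplitudes()
    raise ValueError(f"unknown archetype {archetype!r}")


@dataclass
class Region:
    """A named voxel set carrying one geometry archetype."""

    name: str
    voxels: np.ndarray  # flat indices into the grid
    archetype: str
    amplitudes: Amplitudes | None = None
    strength: float = 0.5

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.amplitudes is None:
            self.amplitudes = archetype_amplitudes(self.archetype, self.strength)


def box_region(
    name: str,
    dims: tuple[int, int, int],
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
    archetype: str,
    strength: float = 0.5,
) -> Region:
    """Axis-aligned box region, specified in voxel coordinates."""
    grid = np.zeros(dims, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    grid[sl] = True
    return Region(name, np.flatnonzero(grid.ravel()), archetype, strength=strength)


@dataclass
class SceneConfig:
    """Everything that defines a synthetic cohort.

    Defaults mirror the acquisition being emulated: 17 subjects, 6 runs,
    3 x 3 x 4 mm voxels, and per-run residual frames for covariance
    estimation.  ``smooth_fwhm_mm`` sets the spatial correlation of the
    noise field (0 disables smoothing); ``subject_jitter_sd`` is the log-sd
    of a per-subject, per-region multiplicative amplitude factor.
    """

    n_subjects: int = 17
    n_runs: int = 6
    dims: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    regions: list[Region] = field(default_factory=list)
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 6.0
    n_residual_frames: int = 100
    subject_jitter_sd: float = 0.2
    subject_pattern_corr: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        if not 0.0 <= self.subject_pattern_corr <= 1.0:
            raise ValueError("subject_pattern_corr must be in [0, 1]")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be non-negative")
        seen = np.zeros(int(np.prod(self.dims)), dtype=bool)
        for reg in self.regions:
            if reg.voxels.size and reg.voxels.max() >= seen.size:
                raise ValueError(f"region {reg.name!r} exceeds the grid")
            if seen[reg.voxels].any():
                raise ValueError("region voxel sets must be disjoint")
            seen[reg.voxels] = True

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))


@dataclass
class SubjectData:
    """Per-run condition patterns and residual frames on a flat voxel grid."""

    subject_id: int
    betas: np.ndarray  # (runs, conditions, voxels)
    residuals: np.ndarray  # (runs, frames, voxels)
    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    space: ConditionSpace = field(repr=False)

    def __post_init__(self):
        if self.betas.shape[0] != self.residuals.shape[0]:
            raise ValueError("betas and residuals disagree on run count")
        if self.betas.shape[2] != self.residuals.shape[2]:
            raise ValueError("betas and residuals disagree on voxel count")
        if self.betas.shape[1] != self.space.n_conditions:
            raise ValueError("betas condition count does not match the space")
        if not (np.isfinite(self.betas).all() and np.isfinite(self.residuals).all()):
            raise ValueError("non-finite values in subject data")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[2]

    def run_residuals(self) -> list[np.ndarray]:
        return [self.residuals[r] for r in range(self.n_runs)]


@dataclass
class Cohort:
    subjects: list[SubjectData]
    region_masks: dict[str, np.ndarray]  # name -> 3D bool grid
    config: SceneConfig
    space: ConditionSpace = field(repr=False)


# --------------------------------------------------------------------- signal

def _category_profiles(space: ConditionSpace,
                       features: "pd.DataFrame | None") -> np.ndarray | None:
    """Unit-norm category feature profiles (categories x features), or None.

    The profile of a category is the mean feature vector of its items; the
    planted category code uses these so that between-category pattern
    distances inherit the graded geometry of the norms instead of being
    uniformly far apart.
    """
    if features is None:
        return None
    mat = features.loc[list(space.items)].to_numpy(dtype=float)
    cats = space.categories
    prof = np.stack([
        mat[[i for i, it in enumerate(space.items)
             if space.category_of[it] == c]].mean(axis=0)
        for c in cats
    ])
    norms = np.linalg.norm(prof, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return prof / norms


def _region_pattern(reg: Region, space: ConditionSpace,
                    rng: np.random.Generator,
                    category_profiles: np.ndarray | None = None) -> np.ndarray:
    """One draw of a region's component patterns, amplitude-weighted.

    Without feature norms the category code is an independent draw per
    category (all categories equally dissimilar); with norms it is a random
    linear encoding of the unit-norm category profiles, so expected squared
    pattern distances between categories are proportional to the profiles'
    cosine distances.
    """
    cat_idx = space.category_index()
    item_idx = space.item_index()
    mod_idx = space.modality_index()
    grp_idx = space.model_index()
    v = reg.voxels.size
    if category_profiles is None:
        p_cat = rng.standard_normal((len(space.categories), v))
    else:
        w = rng.standard_normal((category_profiles.shape[1], v))
        p_cat = category_profiles @ w
    p_item_mod = rng.standard_normal((len(space.modalities), len(space.items), v))
    p_item = rng.standard_normal((len(space.items), v))
    p_id = rng.standard_normal((len(space.modalities), len(space.model_ids), v))
    p_cross = rng.standard_normal((len(space.items), v))
    amp = reg.amplitudes
    a_iw = np.array([amp.a_item_within[m] for m in space.modalities])
    a_id = np.array([amp.a_id[m] for m in space.modalities])
    # the antisymmetric component flips sign between the two modalities
    cross_sign = np.where(mod_idx == 0, 1.0, -1.0)
    return (
        amp.a_cat * p_cat[cat_idx]
        + a_iw[mod_idx, None] * p_item_mod[mod_idx, item_idx]
        + amp.a_item_shared * p_item[item_idx]
        + a_id[mod_idx, None] * p_id[mod_idx, grp_idx]
        + amp.a_item_cross * cross_sign[:, None] * p_cross[item_idx]
    )


def generate_true_patterns(
    config: SceneConfig,
    space: ConditionSpace,
    seed: int | None = None,
    features: "pd.DataFrame | None" = None,
) -> dict[str, np.ndarray]:
    """Noise-free cohort-level condition patterns per region
    (conditions x region voxels).

    These are the shared component draws; each subject's planted pattern
    correlates with them at ``config.subject_pattern_corr`` (see
    :func:`generate_subject`).  Draws are deterministic for a given seed.
    """
    root = np.random.SeedSequence([0 if seed is None else int(seed), 101])
    profiles = _category_profiles(space, features)
    out: dict[str, np.ndarray] = {}
    for reg, child in zip(config.regions, root.spawn(len(config.regions))):
        out[reg.name] = _region_pattern(reg, space,
                                        np.random.default_rng(child), profiles)
    return out


def _smoothing_norm(dims, sigma_vox) -> float:
    """L2 norm of the (circular) smoothing kernel on this grid."""
    impulse = np.zeros(dims)
    impulse[tuple(d // 2 for d in dims)] = 1.0
    k = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    return float(np.sqrt((k * k).sum()))


class _NoiseField:
    """Stationary spatially correlated Gaussian noise on a fixed grid.

    White noise is smoothed with a Gaussian kernel (circular boundary, which
    keeps the field stationary) and rescaled so the marginal standard
    deviation equals ``sd`` exactly, independent of the FWHM.
    """

    def __init__(self, dims, voxel_size_mm, fwhm_mm, sd):
        self.dims = tuple(dims)
        self.sd = float(sd)
        if fwhm_mm > 0:
            self.sigma = tuple(
                fwhm_mm / (vs * 2.0 * np.sqrt(2.0 * np.log(2.0)))
                for vs in voxel_size_mm
            )
            self.scale = sd / _smoothing_norm(self.dims, self.sigma)
        else:
            self.sigma = None
            self.scale = sd

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """(n, V) noise frames."""
        white = rng.standard_normal((n, *self.dims))
        if self.sigma is not None:
            white = ndimage.gaussian_filter(
                white, sigma=(0.0, *self.sigma), mode="wrap"
            )
        return (white * self.scale).reshape(n, -1)


def generate_subject(
    config: SceneConfig,
    true_patterns: Mapping[str, np.ndarray],
    subject_index: int,
    seed: int | None = None,
    space: ConditionSpace | None = None,
    features: "pd.DataFrame | None" = None,
) -> SubjectData:
    """One subject: run betas = jittered subject patterns + noise, + residuals.

    The subject's planted pattern mixes the cohort-level component draws
    with subject-unique draws so that it correlates with the shared
    geometry at ``config.subject_pattern_corr`` (1.0 = identical geometry
    in every subject); a per-region lognormal amplitude jitter scales it.
    The per-run noise and the residual frames come from the identical
    spatially correlated process, so covariance estimated from the
    residuals matches the covariance corrupting the betas.  Output is
    bit-reproducible for a fixed seed.
    """
    if space is None:
        space = build_condition_space()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else int(seed),
                                202, int(subject_index)])
    )
    field_ = _NoiseField(config.dims, config.voxel_size_mm,
                         config.smooth_fwhm_mm, config.noise_sd)
    n_cond = space.n_conditions
    v = config.n_voxels
    rho = config.subject_pattern_corr
    profiles = _category_profiles(space, features)
    signal = np.zeros((n_cond, v))
    for reg in config.regions:
        jitter = float(np.exp(rng.normal(0.0, config.subject_jitter_sd)))
        pattern = np.asarray(true_patterns[reg.name])
        if rho < 1.0:
            unique = _region_pattern(reg, space, rng, profiles)
            pattern = np.sqrt(rho) * pattern + np.sqrt(1.0 - rho) * unique
        signal[:, reg.voxels] += jitter * pattern
    betas = np.empty((config.n_runs, n_cond, v))
    residuals = np.empty((config.n_runs, config.n_residual_frames, v))
    for r in range(config.n_runs):
        betas[r] = signal + field_.draw(rng, n_cond)
        residuals[r] = field_.draw(rng, config.n_residual_frames)
    return SubjectData(
        subject_id=int(subject_index),
        betas=betas,
        residuals=residuals,
        dims=tuple(config.dims),
        voxel_size_mm=tuple(config.voxel_size_mm),
        space=space,
    )


def generate_cohort(
    config: SceneConfig,
    seed: int | None = None,
    space: ConditionSpace | None = None,
    features: "pd.DataFrame | None" = None,
) -> Cohort:
    """Generate all subjects of a scene plus the planted-region masks.

    ``features`` (item x feature norms) grades the planted category code;
    pass the same norms the model battery is built from.
    """
    if config.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects for group statistics")
    if space is None:
        space = build_condition_space()
    base = config.seed if seed is None else int(seed)
    true = generate_true_patterns(config, space, seed=base, features=features)
    subjects = [
        generate_subject(config, true, s, seed=base, space=space,
                         features=features)
        for s in range(config.n_subjects)
    ]
    masks = {}
    for reg in config.regions:
        m = np.zeros(config.n_voxels, dtype=bool)
        m[reg.voxels] = True
        masks[reg.name] = m.reshape(config.dims)
    return Cohort(subjects=subjects, region_masks=masks,
                  config=config, space=space)


# --------------------------------------------------------------------- design

class DesignError(RuntimeError):
    pass


def _core_sequence(space: ConditionSpace, rng: np.random.Generator,
                   max_tries: int = 2000) -> list[tuple[str, str, int]]:
    """Two concatenated mini-blocks, each one pass over all conditions,
    randomized so the same concept never occurs back-to-back."""
    conds = list(space.conditions)
    for _ in range(max_tries):
        order: list[tuple[str, str, int]] = []
        ok = True
        for _block in range(CORE_REPS_PER_RUN):
            block = list(conds)
            rng.shuffle(block)
            if order and block[0][0] == order[-1][0]:
                ok = False
                break
            if any(a[0] == b[0] for a, b in zip(block, block[1:])):
                ok = False
                break
            order.extend(block)
        if ok:
            return order
    raise DesignError(f"could not satisfy the no-repeat constraint in {max_tries} tries")


def generate_design(config: SceneConfig, space: ConditionSpace,
                    seed: int | None = None) -> pd.DataFrame:
    """Trial-level design table for all runs.

    Per run: 72 core trials (each condition twice, as two randomized
    mini-blocks with no concept repeated consecutively), 6 target fillers,
    6 non-target fillers and 7 nulls.  The 19 non-core trials are placed
    regularly but unpredictably: the 91 trial slots are divided into 19
    contiguous blocks and one slot is drawn uniformly within each.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed if seed is None else int(seed), 303])
    )
    n_special = (N_TARGET_FILLERS_PER_RUN + N_NONTARGET_FILLERS_PER_RUN
                 + N_NULLS_PER_RUN)
    n_core = CORE_REPS_PER_RUN * space.n_conditions
    n_total = n_core + n_special
    rows = []
    for run in range(1, config.n_runs + 1):
        core = _core_sequence(space, rng)
        # stratified placement of the non-core trials
        edges = np.linspace(0, n_total, n_special + 1).astype(int)
        special_pos = np.array(
            [rng.integers(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
        )
        kinds = (["target_filler"] * N_TARGET_FILLERS_PER_RUN
                 + ["nontarget_filler"] * N_NONTARGET_FILLERS_PER_RUN
                 + ["null"] * N_NULLS_PER_RUN)
        rng.shuffle(kinds)
        tgt_items = list(rng.choice(_TARGET_FILLER_POOL,
                                    N_TARGET_FILLERS_PER_RUN, replace=False))
        ntg_items = list(rng.choice(_NONTARGET_FILLER_POOL,
                                    N_NONTARGET_FILLERS_PER_RUN, replace=False))
        # fillers balanced for modality and producer within run
        filler_mods = ["speech", "sign"] * 6
        filler_grps = [1, 2, 2, 1] * 3
        rng.shuffle(filler_mods)
        rng.shuffle(filler_grps)
        special_iter = iter(range(n_special))
        core_iter = iter(core)
        fm = iter(filler_mods)
        fg = iter(filler_grps)
        is_special = np.zeros(n_total, dtype=bool)
        is_special[special_pos] = True
        for t in range(n_total):
            if is_special[t]:
                k = kinds[next(special_iter)]
                if k == "null":
                    rows.append((run, t, "null", "", "", 0, NULL_DURATION_S))
                else:
                    item = tgt_items.pop() if k == "target_filler" else ntg_items.pop()
                    mo, g = next(fm), next(fg)
                    dur = SPEECH_DURATION_S if mo == "speech" else SIGN_DURATION_S
                    rows.append((run, t, k, item, mo, g, dur))
            else:
                item, mo, g = next(core_iter)
                dur = SPEECH_DURATION_S if mo == "speech" else SIGN_DURATION_S
                rows.append((run, t, "core", item, mo, g, dur))
    return pd.DataFrame(
        rows,
        columns=["run", "trial_index", "kind", "item", "modality",
                 "model_id", "duration_s"],
    )


def validate_design(table: pd.DataFrame, space: ConditionSpace) -> list[str]:
    """Check the design invariants; returns a list of violations (empty = ok)."""
    problems = []
    for run, grp in table.groupby("run"):
        grp = grp.sort_values("trial_index")
        counts = grp["kind"].value_counts()
        expect = {
            "core": CORE_REPS_PER_RUN * space.n_conditions,
            "target_filler": N_TARGET_FILLERS_PER_RUN,
            "nontarget_filler": N_NONTARGET_FILLERS_PER_RUN,
            "null": N_NULLS_PER_RUN,
        }
        for kind, n in expect.items():
            if counts.get(kind, 0) != n:
                problems.append(f"run {run}: {kind} count {counts.get(kind, 0)} != {n}")
        core = grp[grp["kind"] == "core"]
        combo = core.groupby(["item", "modality", "model_id"]).size()
        if not (combo == CORE_REPS_PER_RUN).all():
            problems.append(f"run {run}: core conditions not each repeated "
                            f"{CORE_REPS_PER_RUN} times")
        items = core["item"].tolist()
        pos = core["trial_index"].tolist()
        for (i1, p1), (i2, p2) in zip(zip(items, pos), zip(items[1:], pos[1:])):
            # consecutive core trials (possibly separated by fillers) may not
            # repeat a concept; adjacency in the table is the strict case
            if i1 == i2 and p2 == p1 + 1:
                problems.append(f"run {run}: concept {i1!r} repeated at "
                                f"trials {p1},{p2}")
    return problems


# --------------------------------------------------------------- feature norms

def generate_feature_norms(
    space: ConditionSpace,
    n_features: int = 60,
    p_within_category_shared: float = 0.5,
    p_item_unique: float = 0.5,
    p_cross_category_shared: float = 0.35,
    seed: int | None = None,
) -> pd.DataFrame:
    """Synthetic binary concept-feature norms (items x features).

    Half of the features are category-level: a category feature is either
    present in all items of its category (with probability
    ``p_within_category_shared``) or in none, and an active category
    feature additionally extends to all items of one other category with
    probability ``p_cross_category_shared`` — real property norms share
    features gradedly across categories (fruit and animals are both
    natural kinds), which is what gives between-category dissimilarities
    their graded structure.  The remaining features are item-level,
    present in their single item with probability ``p_item_unique``.  The
    induced cosine dissimilarities therefore show the within-category <
    between-category block structure of real property norms.
    """
    for name, p in [("p_within_category_shared", p_within_category_shared),
                    ("p_item_unique", p_item_unique),
                    ("p_cross_category_shared", p_cross_category_shared)]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([0 if seed is None else int(seed), 404]))
    items = space.items
    cats = space.categories
    n_cat_feat = n_features // 2
    n_item_feat = n_features - n_cat_feat
    mat = np.zeros((len(items), n_features), dtype=float)
    cols = []
    for f in range(n_cat_feat):
        cat = cats[f % len(cats)]
        cols.append(f"cat_{cat}_{f}")
        if rng.random() < p_within_category_shared:
            active = {cat}
            others = [c for c in cats if c != cat]
            if others and rng.random() < p_cross_category_shared:
                active.add(others[int(rng.integers(len(others)))])
            for i, it in enumerate(items):
                if space.category_of[it] in active:
                    mat[i, f] = 1.0
    for f in range(n_item_feat):
        it = items[f % len(items)]
        cols.append(f"item_{it}_{f}")
        if rng.random() < p_item_unique:
            mat[items.index(it), n_cat_feat + f] = 1.0
    # cosine needs non-zero vectors: an all-zero item pulls in one shared
    # feature for its whole category (keeps within-category identity intact)
    for ci, cat in enumerate(cats):
        rows = [i for i, it in enumerate(items) if space.category_of[it] == cat]
        if any(not mat[r].any() for r in rows):
            mat[rows, ci % max(n_cat_feat, 1)] = 1.0
    df = pd.DataFrame(mat, index=list(items), columns=cols)
    uniq = df.drop_duplicates()
    if len(uniq) < len(df):
        warnings.warn("some items have identical feature vectors; "
                      "item-level structure is degenerate", stacklevel=2)
    return df
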