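"""Model fitting and group inference for RDMs.

Model fits use Kendall's tau-a — the rank correlation with the full
``m(m-1)/2`` pair denominator — because model RDMs are full of tied
predictions, which tau-b and Spearman handle less gracefully.  Tau is mapped
to a Pearson-scale coefficient through Greiner's relation
``r = sin(pi * tau / 2)`` and then Fisher-transformed, so group-level
inference can use ordinary t statistics on approximately normal values.
Positive model fits are tested one-tailed against zero (negative rank
correlations with a dissimilarity model are not meaningful); differences
between model fits use two-tailed paired t tests.  Noise ceilings bound the
fit any model could achieve given between-subject inconsistency:
leave-one-out group-mean correlation from below, grand-mean correlation from
above.
"""
from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import CellMask, ConditionSpace, cell_mask
from .distances import RDM
from .models import (
    ModelRDM,
    category_model,
    identity_model,
    item_model,
    semantic_feature_model,
)

_R_CLAMP = 1.0 - 1e-12


# ----------------------------------------------------------------- tau-a

def _tau_a_exact(x: np.ndarray, y: np.ndarray) -> float:
    """O(m^2) reference: count concordant minus discordant pairs directly."""
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(x.size, k=1)
    s = float((dx[iu] * dy[iu]).sum())
    m = x.size
    return s / (m * (m - 1) / 2)


def _tau_a_fast(x: np.ndarray, y: np.ndarray) -> float:
    """O(m log m) path: recover the integer concordant-discordant balance
    from tau-b's statistic and its tie-corrected denominator."""
    m = x.size
    n0 = m * (m - 1) // 2
    def ties(v):
        _, counts = np.unique(v, return_counts=True)
        return int((counts * (counts - 1) // 2).sum())
    n1, n2 = ties(x), ties(y)
    if n1 == n0 or n2 == n0:
        return 0.0  # one input fully tied: no (dis)concordant pairs at all
    tau_b = sps.kendalltau(x, y).statistic
    s = tau_b * np.sqrt((n0 - n1) * (n0 - n2))
    return float(np.rint(s)) / n0


def tau_a(data, model, method: str = "fast") -> float:
    """Kendall tau-a between a data RDM and a model over the model's mask.

    Accepts plain arrays or an (:class:`RDM`, :class:`ModelRDM`) pair; ties
    in either input count as neither concordant nor discordant.  ``method``
    is ``"fast"`` (default) or ``"exact"`` (the quadratic reference); the two
    agree exactly.
    """
    if isinstance(model, ModelRDM):
        if model.is_constant:
            raise ValueError(
                f"model {model.name!r} is constant over its mask; "
                "a rank correlation is undefined"
            )
        x = data.masked_values(model.mask) if isinstance(data, RDM) else \
            np.asarray(data, float)[model.mask.values]
        y = model.masked_values
    else:
        x = np.asarray(data, dtype=float)
        y = np.asarray(model, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("data and model must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 cells")
    if np.all(y == y[0]):
        raise ValueError("model is constant (no rank variation)")
    if method == "exact":
        return _tau_a_exact(x, y)
    if method == "fast":
        return _tau_a_fast(x, y)
    raise ValueError(f"unknown method {method!r}")


def tau_to_z(tau: float) -> tuple[float, float]:
    """Map tau-a to a Pearson-scale r (Greiner's relation) and Fisher z.

    ``r = sin(pi * tau / 2)``; |r| is clamped just below 1 so perfect fits
    stay finite after ``atanh``.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must be in [-1, 1], got {tau}")
    r = float(np.sin(np.pi * tau / 2.0))
    z = float(np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)))
    return r, z


# ------------------------------------------------------------- group tests

@dataclass
class GroupTest:
    kind: str  # "one_sample_greater" | "paired_two_tailed"
    t: float
    df: int
    p: float
    d_z: float
    n: int


def one_sample_t(values: Sequence[float], tail: str = "greater") -> GroupTest:
    """One-sample t test of subject-level values against zero."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 subjects")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance across subjects; t undefined")
    res = sps.ttest_1samp(v, 0.0, alternative=tail)
    return GroupTest(
        kind=f"one_sample_{tail}",
        t=float(res.statistic),
        df=v.size - 1,
        p=float(res.pvalue),
        d_z=float(v.mean() / sd),
        n=v.size,
    )


def paired_t(z1: Sequence[float], z2: Sequence[float]) -> GroupTest:
    """Two-tailed paired t test on the subject-wise differences."""
    a = np.asarray(z1, dtype=float)
    b = np.asarray(z2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if d.size < 2:
        raise ValueError("need at least 2 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = sps.ttest_rel(a, b)
    return GroupTest(
        kind="paired_two_tailed",
        t=float(res.statistic),
        df=d.size - 1,
        p=float(res.pvalue),
        d_z=float(d.mean() / sd),
        n=d.size,
    )


def adjust_alpha(base: float = 0.05, k: int = 1) -> float:
    """Bonferroni-style threshold ``base / k``, rounded half-up to 3 decimals
    (the convention used for reported thresholds like 0.008 for six tests)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = Decimal(str(base)) / Decimal(k)
    return float(adj.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def percent_correct(n_correct: int, n_total: int) -> int:
    """Accuracy as a whole-number percentage, rounded half-up."""
    if n_total <= 0 or not 0 <= n_correct <= n_total:
        raise ValueError("invalid counts")
    pct = Decimal(n_correct) * 100 / Decimal(n_total)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ------------------------------------------------------------ noise ceilings

@dataclass
class NoiseCeiling:
    lower: float
    upper: float
    mask_name: str
    n_subjects: int


def noise_ceiling(subject_rdms: Sequence[RDM], mask: CellMask) -> NoiseCeiling:
    """Leave-one-out (lower) and grand-mean (upper) ceiling on the z scale.

    Lower: mean over subjects of z(tau_a(subject RDM, mean of the others));
    upper: the same against the mean including the subject.
    """
    if len(subject_rdms) < 3:
        raise ValueError("need at least 3 subjects for a noise ceiling")
    vals = np.stack([r.masked_values(mask) for r in subject_rdms])
    grand = vals.mean(axis=0)
    if np.all(grand == grand[0]):
        raise ValueError("group-mean RDM is constant over this mask")
    n = len(subject_rdms)
    lows, ups = [], []
    for s in range(n):
        others = (grand * n - vals[s]) / (n - 1)
        lows.append(tau_to_z(tau_a(vals[s], others))[1])
        ups.append(tau_to_z(tau_a(vals[s], grand))[1])
    return NoiseCeiling(
        lower=float(np.mean(lows)),
        upper=float(np.mean(ups)),
        mask_name=mask.name,
        n_subjects=n,
    )


# ------------------------------------------------------------- region fitting

@dataclass
class FitResult:
    subject: int
    region: str
    model: str
    mask: str
    tau_a: float
    r: float
    z: float
    n_cells: int


def fit_rdm(rdm: RDM, model: ModelRDM, subject: int = -1,
            region: str = "") -> FitResult:
    t = tau_a(rdm, model)
    r, z = tau_to_z(t)
    return FitResult(
        subject=subject, region=region, model=model.name,
        mask=model.mask.name, tau_a=t, r=r, z=z,
        n_cells=model.mask.n_cells,
    )


def standard_model_set(
    space: ConditionSpace,
    features: pd.DataFrame | np.ndarray,
    include_identity: bool = True,
    include_modality_specific: bool = True,
) -> dict[str, ModelRDM]:
    """The canonical battery fit in every region.

    Semantic-feature, item, and category models over the combined
    within-modality (across-producer) and across-modality masks; the same
    three models restricted to each single modality's across-producer cells
    (the form-region analyses); and the speaker and signer identity models
    over all within-modality cells.
    """
    within = cell_mask(space, "within_modality_combined")
    across = cell_mask(space, "across_modality")
    sem_w = semantic_feature_model(features, space, within)
    sem_a = semantic_feature_model(features, space, across)
    out = {
        "semantic_within": sem_w,
        "semantic_across": sem_a,
        "item_within": item_model(space, within),
        "item_across": item_model(space, across),
        "category_within": category_model(sem_w, space, within),
        "category_across": category_model(sem_a, space, across),
    }
    if include_modality_specific:
        for modality, sel in [("speech", "within_speech_across_speaker"),
                              ("sign", "within_sign_across_signer")]:
            m = cell_mask(space, sel)
            sem_m = semantic_feature_model(features, space, m)
            out[f"semantic_{modality}"] = sem_m
            out[f"item_{modality}"] = item_model(space, m)
            out[f"category_{modality}"] = category_model(sem_m, space, m)
    if include_identity:
        out["identity_speech"] = identity_model(space, "speech")
        out["identity_sign"] = identity_model(space, "sign")
    return out


_VERDICTS = ("shared-semantic", "modality-form", "none")


def classify_region(p_values: Mapping[str, float], alpha: float) -> str:
    """Label a region's fit pattern.

    ``shared-semantic``: the category model fits both within and across
    modality (categories cross-decode between speech and sign).
    ``modality-form``: item-level structure within a modality together with
    producer-identity sensitivity, and no across-modality category fit —
    the signature of perceptual word/sign form coding.
    ``none`` otherwise.
    """
    def sig(name):
        return p_values.get(name, 1.0) < alpha

    if sig("category_within") and sig("category_across"):
        return "shared-semantic"
    if (
        (sig("item_within") or sig("item_speech") or sig("item_sign"))
        and (sig("identity_speech") or sig("identity_sign"))
        and not sig("category_across")
    ):
        return "modality-form"
    return "none"


@dataclass
class RegionFit:
    region: str
    fits: pd.DataFrame        # one row per subject x model
    group: pd.DataFrame       # one row per model (one-sample tests)
    paired: pd.DataFrame      # model-comparison paired tests
    ceilings: dict[str, NoiseCeiling]
    alpha: float
    verdict: str


def fit_models_in_region(
    subject_rdms: Sequence[RDM],
    models: Mapping[str, ModelRDM],
    region: str = "roi",
    alpha: float = 0.05,
) -> RegionFit:
    """Fit a model battery to every subject's region RDM and test the group.

    Each model is fit per subject (tau-a over its mask, converted to Fisher
    z), tested against zero one-tailed across subjects at ``alpha``
    (callers adjust it for the number of regions tested, as reported
    thresholds are), and benchmarked against the noise ceiling of its mask.
    Item and category fits are additionally compared within vs across
    modality with paired two-tailed tests, and the overall pattern is
    labeled by :func:`classify_region`.
    """
    if not subject_rdms:
        raise ValueError("no subject RDMs")
    rows = []
    z_by_model: dict[str, np.ndarray] = {}
    for key, model in models.items():
        zs = []
        for s, rdm in enumerate(subject_rdms):
            fr = fit_rdm(rdm, model, subject=s, region=region)
            rows.append({**fr.__dict__, "model_key": key})
            zs.append(fr.z)
        z_by_model[key] = np.asarray(zs)
    fits = pd.DataFrame(rows)
    ceilings: dict[str, NoiseCeiling] = {}
    grows = []
    for key, model in models.items():
        gt = one_sample_t(z_by_model[key], tail="greater")
        mname = model.mask.name
        if mname not in ceilings and len(subject_rdms) >= 3:
            ceilings[mname] = noise_ceiling(subject_rdms, model.mask)
        ceil = ceilings.get(mname)
        grows.append({
            "region": region, "model_key": key, "model": model.name,
            "mask": mname, "t": gt.t, "df": gt.df, "p": gt.p,
            "d_z": gt.d_z, "n": gt.n,
            "significant": gt.p < alpha,
            "ceiling_lower": ceil.lower if ceil else np.nan,
            "ceiling_upper": ceil.upper if ceil else np.nan,
        })
    group = pd.DataFrame(grows)

    prows = []
    for a, b, label in [
        ("item_within", "item_across", "item within-vs-across"),
        ("category_within", "category_across", "category within-vs-across"),
        ("semantic_within", "semantic_across", "semantic within-vs-across"),
    ]:
        if a in z_by_model and b in z_by_model:
            try:
                pt = paired_t(z_by_model[a], z_by_model[b])
            except ValueError:
                continue
            prows.append({
                "region": region, "comparison": label, "t": pt.t,
                "df": pt.df, "p": pt.p, "d_z": pt.d_z, "n": pt.n,
            })
    paired = pd.DataFrame(prows)

    p_values = {row["model_key"]: row["p"] for row in grows}
    verdict = classify_region(p_values, alpha)
    return RegionFit(
        region=region, fits=fits, group=group, paired=paired,
        ceilings=ceilings, alpha=alpha, verdict=verdict,
    )
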