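"""Theoretical model RDMs and stimulus-side distance measures.

A model RDM predicts dissimilarities over a *tested-cell mask*, a subset of
the unordered condition pairs; only the rank order of its predictions matters
because fits use the tau-a rank correlation downstream.  The semantic feature
model predicts graded item-pair dissimilarity from concept-feature vectors
(cosine distance); it decomposes into an item model (same item vs different
item) and a category model (the feature predictions restricted to
different-item cells).  Producer-identity models test sensitivity to
low-level acoustic/visual features of the speaker or signer, and stimulus
measures (normalized phoneme edit distance, iconicity-rating differences)
support confound screening via plain Pearson correlation between candidate
models.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .conditions import CellMask, ConditionSpace, cell_mask, same_item_cells

try:  # fast edit-distance backend; a tiny DP fallback keeps the API total
    import edlib
except ImportError:  # pragma: no cover
    edlib = None


@dataclass
class ModelRDM:
    """Predicted dissimilarities over a tested-cell mask.

    ``values`` has one entry per condition pair, NaN outside the mask.
    """

    name: str
    values: np.ndarray
    mask: CellMask
    space: ConditionSpace = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.n_pairs,):
            raise ValueError("model length does not match the condition space")
        if np.isnan(self.values[self.mask.values]).any():
            raise ValueError("model has undefined predictions on masked cells")

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask.values]

    @property
    def is_constant(self) -> bool:
        """True when the model has no rank variation over its mask
        (unfittable with a rank correlation)."""
        v = self.masked_values
        return bool(v.size == 0 or np.all(v == v[0]))

    def to_square_frame(self) -> pd.DataFrame:
        n = self.space.n_conditions
        sq = np.full((n, n), np.nan)
        ii, jj = self.space.pair_indices()
        sq[ii, jj] = self.values
        sq[jj, ii] = self.values
        labels = self.space.condition_labels()
        return pd.DataFrame(sq, index=labels, columns=labels)


def _tile_item_matrix(
    item_dist: np.ndarray, space: ConditionSpace, mask: CellMask, name: str
) -> ModelRDM:
    """Spread an item x item dissimilarity matrix over every masked cell."""
    it = space.item_index()
    ii, jj = space.pair_indices()
    values = np.full(space.n_pairs, np.nan)
    sel = mask.values
    values[sel] = item_dist[it[ii[sel]], it[jj[sel]]]
    return ModelRDM(name=name, values=values, mask=mask, space=space)


def feature_distance_matrix(features: pd.DataFrame | np.ndarray,
                            space: ConditionSpace) -> np.ndarray:
    """Cosine distances between item feature vectors, ordered like the space."""
    if isinstance(features, pd.DataFrame):
        missing = [it for it in space.items if it not in features.index]
        if missing:
            raise ValueError(f"feature matrix missing items: {missing}")
        mat = features.loc[list(space.items)].to_numpy(dtype=float)
    else:
        mat = np.asarray(features, dtype=float)
        if mat.shape[0] != len(space.items):
            raise ValueError("one feature vector per item required")
    norms = np.linalg.norm(mat, axis=1)
    if np.any(norms == 0):
        bad = [space.items[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero feature vector (cosine undefined) for: {bad}")
    return squareform(pdist(mat, metric="cosine"))


def semantic_feature_model(
    features: pd.DataFrame | np.ndarray,
    space: ConditionSpace,
    mask: CellMask,
) -> ModelRDM:
    """Graded semantic dissimilarity from concept-feature vectors.

    Cell prediction = cosine distance between the two conditions' item
    feature vectors; same-item cells predict 0.
    """
    dist = feature_distance_matrix(features, space)
    return _tile_item_matrix(dist, space, mask, "semantic_feature")


def item_model(space: ConditionSpace, mask: CellMask) -> ModelRDM:
    """Each item uniquely represented: 0 for same-item cells, 1 otherwise."""
    n_item = len(space.items)
    dist_items = np.ones((n_item, n_item)) - np.eye(n_item)
    model = _tile_item_matrix(dist_items, space, mask, "item")
    if model.is_constant:
        warnings.warn(
            "item model is constant over this mask (no same-item cells); "
            "unusable for a rank correlation", stacklevel=2,
        )
    return model


def category_model(
    feature_model: ModelRDM, space: ConditionSpace, mask: CellMask
) -> ModelRDM:
    """Between-item semantic structure only: the feature model's predictions
    with every same-item cell dropped from the tested mask."""
    keep = mask.values & ~same_item_cells(space)
    if np.isnan(feature_model.values[keep]).any():
        raise ValueError("feature model lacks predictions on required cells")
    values = np.full(space.n_pairs, np.nan)
    values[keep] = feature_model.values[keep]
    cmask = CellMask(f"{mask.name}-different_item", keep, space)
    return ModelRDM(name="category", values=values, mask=cmask, space=space)


def identity_model(space: ConditionSpace, modality: str) -> ModelRDM:
    """Producer identity within one modality: same speaker/signer -> 0,
    different -> 1, over all within-modality cells (same-producer cells
    included — without them the model is constant)."""
    if modality not in space.modalities:
        raise ValueError(f"unknown modality {modality!r}")
    mask = cell_mask(space, "within_modality_all", modality)
    grp = space.model_index()
    ii, jj = space.pair_indices()
    values = np.full(space.n_pairs, np.nan)
    sel = mask.values
    values[sel] = (grp[ii[sel]] != grp[jj[sel]]).astype(float)
    return ModelRDM(name=f"identity_{modality}", values=values, mask=mask, space=space)


def iconicity_model(
    ratings: Mapping[str, float],
    space: ConditionSpace,
    mask: CellMask,
) -> ModelRDM:
    """Iconicity dissimilarity: |rating_i - rating_j| on a 1-7 scale."""
    vals = np.array([float(ratings[it]) for it in space.items])
    if np.any((vals < 1) | (vals > 7)):
        warnings.warn("iconicity ratings outside the 1-7 scale", stacklevel=2)
    dist = np.abs(vals[:, None] - vals[None, :])
    return _tile_item_matrix(dist, space, mask, "iconicity")


# ------------------------------------------------------------- phonology

def _levenshtein_dp(a: Sequence[str], b: Sequence[str]) -> int:
    """Plain dynamic-programming edit distance over token sequences."""
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, 1):
        cur = [i]
        for j, tb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ta != tb)))
        prev = cur
    return prev[-1]


def _edit_distance(a: Sequence[str], b: Sequence[str]) -> int:
    if edlib is None:
        return _levenshtein_dp(a, b)
    alphabet: dict[str, str] = {}
    for tok in [*a, *b]:
        if tok not in alphabet:
            alphabet[tok] = chr(0x100 + len(alphabet))
    sa = "".join(alphabet[t] for t in a)
    sb = "".join(alphabet[t] for t in b)
    return int(edlib.align(sa, sb, task="distance")["editDistance"])


def levenshtein_phon_distance(
    transcriptions: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Normalized phoneme edit distance between every pair of items.

    Distance = (insertions + deletions + substitutions) / length of the
    longer transcription; symmetric, in [0, 1], 0 iff identical.
    """
    items = list(transcriptions)
    seqs = {it: list(transcriptions[it]) for it in items}
    for it, s in seqs.items():
        if len(s) == 0:
            raise ValueError(f"empty phoneme sequence for {it!r}")
    n = len(items)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _edit_distance(seqs[items[i]], seqs[items[j]])
            norm = d / max(len(seqs[items[i]]), len(seqs[items[j]]))
            mat[i, j] = mat[j, i] = norm
    return pd.DataFrame(mat, index=items, columns=items)


def phonological_model(
    transcriptions: Mapping[str, Sequence[str]],
    space: ConditionSpace,
    mask: CellMask,
) -> ModelRDM:
    """Tile the normalized phoneme edit distances over a cell mask."""
    df = levenshtein_phon_distance(transcriptions)
    missing = [it for it in space.items if it not in df.index]
    if missing:
        raise ValueError(f"transcriptions missing items: {missing}")
    dist = df.loc[list(space.items), list(space.items)].to_numpy()
    return _tile_item_matrix(dist, space, mask, "phonological")


def model_correlation(a: ModelRDM, b: ModelRDM) -> float:
    """Pearson r between two models over the intersection of their masks.

    Used to screen candidate models for confounds (e.g. that phonological
    distance does not mimic semantic distance).
    """
    shared = a.mask.values & b.mask.values
    if shared.sum() < 3:
        raise ValueError("need at least 3 shared cells")
    return float(stats.pearsonr(a.values[shared], b.values[shared]).statistic)


def item_pair_correlation(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r (with p and n) between two item x item distance matrices
    over their off-diagonal unordered pairs."""
    items = [it for it in a.index if it in b.index]
    if len(items) < 3:
        raise ValueError("need at least 3 common items")
    ma = a.loc[items, items].to_numpy()
    mb = b.loc[items, items].to_numpy()
    iu = np.triu_indices(len(items), k=1)
    res = stats.pearsonr(ma[iu], mb[iu])
    return float(res.statistic), float(res.pvalue), len(iu[0])
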