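"""Non-metric multidimensional scaling of group-average RDMs.

Non-metric MDS is the natural visualization companion of rank-based model
fitting: only the rank order of the dissimilarities constrains the
configuration, and Kruskal stress-1 measures how well the monotone
regression fits.  Cross-validated distances may be negative; cells are
shifted by the minimum before embedding, which preserves ranks and is
harmless under a non-metric treatment.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

from .conditions import CellMask, ConditionSpace
from .distances import RDM


@dataclass
class Embedding:
    coords: np.ndarray            # (n_conditions_used, n_dims), mean-centered
    condition_indices: np.ndarray  # indices into space.conditions
    stress: float                 # Kruskal stress-1
    n_restarts: int
    seed: int
    space: ConditionSpace = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        labels = self.space.condition_labels()
        rows = []
        for row, ci in enumerate(self.condition_indices):
            it, mo, g = self.space.conditions[ci]
            rows.append({
                "condition": labels[ci], "item": it,
                "category": self.space.category_of[it],
                "modality": mo, "model_id": g,
                **{f"dim{d + 1}": self.coords[row, d]
                   for d in range(self.coords.shape[1])},
            })
        return pd.DataFrame(rows)


def _square_from_mask(rdm: RDM, mask: CellMask | None):
    space = rdm.space
    n = space.n_conditions
    sq = rdm.to_square()
    if mask is None:
        return sq, np.arange(n)
    ii, jj = space.pair_indices()
    used = np.zeros(n, dtype=bool)
    used[ii[mask.values]] = True
    used[jj[mask.values]] = True
    idx = np.flatnonzero(used)
    have = np.zeros((n, n), dtype=bool)
    have[ii[mask.values], jj[mask.values]] = True
    have[jj[mask.values], ii[mask.values]] = True
    sub = np.ix_(idx, idx)
    complete = have[sub] | np.eye(idx.size, dtype=bool)
    if not complete.all():
        raise ValueError(
            "mask does not give complete pairwise distances among the "
            "conditions it covers; cannot embed"
        )
    return sq[sub], idx


def nonmetric_mds(
    rdm: RDM,
    mask: CellMask | None = None,
    n_dims: int = 2,
    n_restarts: int = 10,
    seed: int = 0,
) -> Embedding:
    """Embed a (group-average) RDM by non-metric MDS, best of random restarts."""
    sq, idx = _square_from_mask(rdm, mask)
    if idx.size < n_dims + 1:
        raise ValueError("need more conditions than embedding dimensions")
    off = ~np.eye(idx.size, dtype=bool)
    lo = sq[off].min()
    if lo < 0:
        sq = sq - lo  # rank-preserving shift of the off-diagonal cells
        np.fill_diagonal(sq, 0.0)
    model = MDS(
        n_components=n_dims,
        metric="precomputed",
        metric_mds=False,
        n_init=n_restarts,
        random_state=seed,
        init="random",
        normalized_stress=True,
        max_iter=500,
    )
    coords = model.fit_transform(sq)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return Embedding(
        coords=coords, condition_indices=idx, stress=float(model.stress_),
        n_restarts=n_restarts, seed=seed, space=rdm.space,
    )


def category_centroids(embedding: Embedding, space: ConditionSpace | None = None
                       ) -> pd.DataFrame:
    """Mean embedded coordinate per (category, modality)."""
    space = space or embedding.space
    df = embedding.to_frame()
    dims = [c for c in df.columns if c.startswith("dim")]
    cent = df.groupby(["category", "modality"], sort=False)[dims].mean()
    return cent.reset_index()


def plot_embedding(embedding: Embedding, path=None):
    """Scatter of the embedding colored by category, markers by modality."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = embedding.to_frame()
    fig, ax = plt.subplots(figsize=(5, 5))
    colors = {"fruit": "tab:red", "animals": "tab:green",
              "transport": "tab:blue"}
    markers = {"speech": "o", "sign": "^"}
    for (cat, mo), grp in df.groupby(["category", "modality"]):
        ax.scatter(grp["dim1"], grp["dim2"],
                   c=colors.get(cat, "gray"), marker=markers.get(mo, "s"),
                   label=f"{cat}/{mo}", alpha=0.8)
    cent = category_centroids(embedding)
    ax.scatter(cent["dim1"], cent["dim2"], c="k", marker="x", s=60)
    ax.legend(fontsize=7)
    ax.set_title(f"non-metric MDS (stress-1 = {embedding.stress:.3f})")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
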