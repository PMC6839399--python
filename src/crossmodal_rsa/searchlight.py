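"""Spherical searchlight mapping and group-level cluster inference.

At every voxel, the crossnobis RDM over the voxels of a surrounding sphere is
computed (noise covariance estimated per sphere from the residual frames) and
the mean of a selected cell subset — e.g. the combined within-modality
distances — is written back to the sphere center.  Per-center RDMs can be
retained so clusters can later be summarized by their average RDM without a
second pass.

Group inference stacks the subject maps, forms a voxelwise t map, thresholds
it at an uncorrected cluster-forming p, extracts connected components
(18-connectivity: faces + edges), and assigns each cluster a p value from a
sign-flip permutation null of the maximum cluster extent, followed by
Benjamini-Hochberg FDR across clusters.  Permutation replaces parametric
random-field cluster inference: it is exact under the sign-symmetry of the
null and needs no smoothness estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .conditions import CellMask, ConditionSpace
from .distances import _diag_shrinkage_intensity
from .simulate import SubjectData


@dataclass
class SearchlightSpec:
    """Sphere geometry: integer voxel offsets within a physical radius."""

    radius_mm: float
    voxel_size_mm: tuple[float, float, float]
    offsets: np.ndarray  # (K, 3) int
    min_in_mask_fraction: float = 0.5

    @property
    def n_offsets(self) -> int:
        return self.offsets.shape[0]


def sphere_offsets(
    voxel_size_mm: Sequence[float],
    radius_mm: float,
    min_in_mask_fraction: float = 0.5,
) -> SearchlightSpec:
    """Enumerate all integer offsets whose physical center distance is within
    the radius (e.g. 65 voxels for an 8 mm sphere on a 3 x 3 x 4 mm grid)."""
    vs = tuple(float(v) for v in voxel_size_mm)
    if radius_mm < 0:
        raise ValueError("radius must be non-negative")
    if any(v <= 0 for v in vs):
        raise ValueError("voxel sizes must be positive")
    bounds = [int(radius_mm // v) for v in vs]
    offs = []
    for i in range(-bounds[0], bounds[0] + 1):
        for j in range(-bounds[1], bounds[1] + 1):
            for k in range(-bounds[2], bounds[2] + 1):
                if (i * vs[0]) ** 2 + (j * vs[1]) ** 2 + (k * vs[2]) ** 2 <= radius_mm ** 2:
                    offs.append((i, j, k))
    return SearchlightSpec(
        radius_mm=float(radius_mm),
        voxel_size_mm=vs,
        offsets=np.array(offs, dtype=int),
        min_in_mask_fraction=min_in_mask_fraction,
    )


@dataclass
class StatMap:
    """A per-voxel statistic on the subject grid; NaN outside the mask."""

    data: np.ndarray  # 3D
    name: str
    df: int | None = None

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RDMStore:
    """Per-searchlight-center RDMs retained for later ROI averaging."""

    centers: np.ndarray         # (N,) flat voxel indices
    values: np.ndarray          # (N, n_pairs) float32
    dims: tuple[int, int, int]
    space: ConditionSpace = field(repr=False)

    def centers_in(self, mask3d: np.ndarray) -> np.ndarray:
        """Positions (rows) of the stored centers inside a 3D boolean mask."""
        flat = mask3d.reshape(-1)
        return np.flatnonzero(flat[self.centers])


def _neighborhoods(dims, mask3d, offsets):
    """For each in-mask center: valid in-mask sphere member flat indices."""
    centers = np.argwhere(mask3d)  # (N, 3)
    pts = centers[:, None, :] + offsets[None, :, :]  # (N, K, 3)
    inb = np.all((pts >= 0) & (pts < np.array(dims)), axis=2)
    flat = np.zeros(pts.shape[:2], dtype=np.int64)
    clipped = np.clip(pts, 0, np.array(dims) - 1)
    flat = np.ravel_multi_index(
        (clipped[..., 0], clipped[..., 1], clipped[..., 2]), dims
    )
    valid = inb & mask3d.reshape(-1)[flat]
    return centers, flat, valid


def run_searchlight(
    subject: SubjectData,
    spec: SearchlightSpec,
    selectors: Sequence[CellMask],
    brain_mask: np.ndarray | None = None,
    lam: float | None = None,
    store_rdms: bool = False,
) -> tuple[dict[str, StatMap], RDMStore | None]:
    """Map mean masked crossnobis distances over the brain for one subject.

    All requested cell-mask statistics are computed in a single pass (the
    sphere RDM is shared).  The sphere noise covariance is estimated from
    the residual frames of the sphere's voxels with shrinkage toward the
    diagonal; when ``lam`` is None the analytic intensity is evaluated on a
    sample of spheres and its median reused everywhere (sphere-to-sphere
    variation of the intensity is negligible next to its sampling noise).
    """
    dims = subject.dims
    if brain_mask is None:
        brain_mask = np.ones(dims, dtype=bool)
    if brain_mask.shape != tuple(dims):
        raise ValueError("brain mask does not match the subject grid")
    if not brain_mask.any():
        raise ValueError("no in-mask searchlight centers")
    r = subject.n_runs
    f = subject.residuals.shape[1]
    res = subject.residuals - subject.residuals.mean(axis=1, keepdims=True)
    xall = res.reshape(r * f, -1)  # per-run demeaned frames, stacked
    betas = subject.betas
    space = subject.space
    n_pairs = space.n_pairs
    ii, jj = space.pair_indices()

    centers, flat, valid = _neighborhoods(dims, brain_mask, spec.offsets)
    frac = valid.mean(axis=1)
    keep = frac >= spec.min_in_mask_fraction

    if lam is None:
        probe = np.flatnonzero(keep)
        probe = probe[:: max(1, len(probe) // 20)][:20]
        lams = []
        for c in probe:
            vox = flat[c][valid[c]]
            lams.append(_diag_shrinkage_intensity(xall[:, vox]))
        lam = float(np.median(lams)) if lams else 1.0

    maps = {m.name: np.full(dims, np.nan) for m in selectors}
    sel_idx = {m.name: m.values for m in selectors}
    store_vals = np.zeros((int(keep.sum()), n_pairs), dtype=np.float32) if store_rdms else None
    store_centers = np.zeros(int(keep.sum()), dtype=np.int64)

    row = 0
    for c in np.flatnonzero(keep):
        vox = flat[c][valid[c]]
        p = vox.size
        x = xall[:, vox]
        s = x.T @ x / (r * f)
        sigma = (1.0 - lam) * s + lam * np.diag(np.diag(s))
        w, u = np.linalg.eigh(sigma)
        w = np.maximum(w, 1e-12 * w.max())
        whiten = (u / np.sqrt(w)) @ u.T
        wb = betas[:, :, vox] @ whiten  # (R, C, P)
        diffs = wb[:, ii, :] - wb[:, jj, :]
        total = diffs.sum(axis=0)
        d = (total * total).sum(-1) - (diffs * diffs).sum(-1).sum(0)
        d /= p * r * (r - 1)
        cidx = tuple(centers[c])
        for name, sel in sel_idx.items():
            maps[name][cidx] = d[sel].mean()
        if store_rdms:
            store_vals[row] = d
        store_centers[row] = np.ravel_multi_index(cidx, dims)
        row += 1

    stat_maps = {name: StatMap(data=m, name=name) for name, m in maps.items()}
    store = None
    if store_rdms:
        store = RDMStore(centers=store_centers, values=store_vals,
                         dims=tuple(dims), space=space)
    return stat_maps, store


# ------------------------------------------------------------- group level

def _stack(maps: Sequence[StatMap] | Sequence[np.ndarray]) -> np.ndarray:
    arrs = [m.data if isinstance(m, StatMap) else np.asarray(m) for m in maps]
    dims = arrs[0].shape
    if any(a.shape != dims for a in arrs):
        raise ValueError("subject maps are not on a common grid")
    return np.stack(arrs)


def _t_from_stack(data: np.ndarray) -> np.ndarray:
    """Voxelwise one-sample t; NaN where undefined (zero variance or NaN)."""
    n = data.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = data.mean(axis=0)
        sd = data.std(axis=0, ddof=1)
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t


def group_map(
    maps: Sequence[StatMap] | Sequence[np.ndarray],
    test: str = "one_sample",
    maps_b: Sequence[StatMap] | Sequence[np.ndarray] | None = None,
) -> StatMap:
    """Voxelwise group t map: one-sample (greater than zero) or paired
    difference between two map sets."""
    data = _stack(maps)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if test == "one_sample":
        name = "group_t"
    elif test == "paired":
        if maps_b is None:
            raise ValueError("paired test needs a second set of maps")
        data = data - _stack(maps_b)
        name = "group_t_paired"
    else:
        raise ValueError(f"unknown test {test!r}")
    return StatMap(data=_t_from_stack(data), name=name, df=data.shape[0] - 1)


_STRUCT_18 = ndimage.generate_binary_structure(3, 2)  # faces + edges


@dataclass
class ClusterResult:
    table: pd.DataFrame
    labels: np.ndarray          # 3D int, 0 = background
    threshold_t: float
    df: int

    @property
    def surviving_labels(self) -> list[int]:
        if self.table.empty:
            return []
        return self.table.loc[self.table["survives"], "cluster_id"].tolist()


def _label_clusters(binary: np.ndarray):
    labels, n = ndimage.label(binary, structure=_STRUCT_18)
    return labels, n


def cluster_inference(
    tmap: StatMap,
    subject_maps: Sequence[StatMap] | Sequence[np.ndarray],
    maps_b: Sequence[StatMap] | Sequence[np.ndarray] | None = None,
    cluster_forming_p: float = 0.005,
    q: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-level inference on a (positive-tail) group t map.

    Suprathreshold voxels at the uncorrected cluster-forming p are grouped
    into 18-connected components; each component's extent is referred to a
    sign-flip permutation null of the maximum cluster extent, and the
    resulting cluster p values are FDR-corrected (Benjamini-Hochberg) at
    level ``q``.  For a paired analysis pass the second map set, matching
    the map the t values came from.
    """
    data = _stack(subject_maps)
    if maps_b is not None:
        data = data - _stack(maps_b)
    n = data.shape[0]
    df = n - 1
    thr = float(sps.t.ppf(1.0 - cluster_forming_p, df))
    t_obs = tmap.data
    binary = np.where(np.isfinite(t_obs), t_obs, -np.inf) > thr
    labels, n_clu = _label_clusters(binary)
    if n_clu == 0:
        return ClusterResult(
            table=pd.DataFrame(
                columns=["cluster_id", "peak_x", "peak_y", "peak_z", "peak_t",
                         "extent", "p", "q_value", "survives"]
            ),
            labels=labels, threshold_t=thr, df=df,
        )

    extents = ndimage.sum_labels(np.ones_like(labels), labels,
                                 index=np.arange(1, n_clu + 1)).astype(int)
    # permutation null of the maximum cluster extent under sign flips
    rng = np.random.default_rng(seed)
    flat = data.reshape(n, -1)
    finite = np.isfinite(flat).all(axis=0)
    ssq = np.where(finite, (flat * flat).sum(axis=0), np.nan)
    max_ext = np.zeros(n_permutations, dtype=int)
    dims = t_obs.shape
    for b in range(n_permutations):
        signs = rng.choice((-1.0, 1.0), size=n)
        m = signs @ flat / n
        var = (ssq - n * m * m) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_perm = m / np.sqrt(var / n)
        binary_b = np.where(np.isfinite(t_perm), t_perm, -np.inf).reshape(dims) > thr
        lab_b, n_b = _label_clusters(binary_b)
        if n_b:
            ext_b = ndimage.sum_labels(np.ones_like(lab_b), lab_b,
                                       index=np.arange(1, n_b + 1))
            max_ext[b] = int(ext_b.max())
    p_vals = np.array([
        (1 + np.sum(max_ext >= e)) / (n_permutations + 1) for e in extents
    ])
    reject, q_vals, _, _ = multipletests(p_vals, alpha=q, method="fdr_bh")

    rows = []
    for k in range(1, n_clu + 1):
        in_k = labels == k
        tk = np.where(in_k, t_obs, -np.inf)
        peak = np.unravel_index(np.argmax(tk), dims)
        rows.append({
            "cluster_id": k,
            "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
            "peak_t": float(t_obs[peak]),
            "extent": int(extents[k - 1]),
            "p": float(p_vals[k - 1]),
            "q_value": float(q_vals[k - 1]),
            "survives": bool(reject[k - 1]),
        })
    table = pd.DataFrame(rows).sort_values("extent", ascending=False,
                                           ignore_index=True)
    return ClusterResult(table=table, labels=labels, threshold_t=thr, df=df)
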