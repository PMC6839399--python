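"""Regions of interest from searchlight clusters, including leave-one-out sets.

Surviving clusters become ROIs; each subject's representative RDM for an ROI
is the cellwise mean of all searchlight RDMs whose center falls inside it.
Because the ROIs are selected for reliably positive across-producer
distances, any model that predicts a mean shift on exactly those cells (the
producer-identity models do) would be tested circularly in the same data —
the orthogonality guard detects this and such models are only admitted in
leave-one-participant-out ROIs, whose defining group map excludes the tested
subject.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .conditions import CellMask
from .distances import RDM
from .models import ModelRDM
from .searchlight import ClusterResult, RDMStore, StatMap, _label_clusters, _stack


@dataclass
class ROI:
    name: str
    mask: np.ndarray  # 3D bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_leave_one_out(self) -> bool:
        return self.provenance.get("kind") == "leave_one_out"


@dataclass
class ROISet:
    rois: list[ROI]

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)


@dataclass
class LeaveOneOutROISet:
    """One ROI family per held-out subject; family s never saw subject s."""

    families: dict[int, list[ROI]]
    threshold_p: float

    @property
    def n_families(self) -> int:
        return len(self.families)


def clusters_to_rois(result: ClusterResult, prefix: str = "cluster",
                     provenance: dict | None = None) -> ROISet:
    """One ROI per surviving cluster (empty set, with a warning, if none)."""
    rois = []
    for k in result.surviving_labels:
        rois.append(ROI(
            name=f"{prefix}_{k}",
            mask=result.labels == k,
            provenance={"kind": "cluster", **(provenance or {})},
        ))
    if not rois:
        warnings.warn("no surviving clusters; returning an empty ROI set",
                      stacklevel=2)
    return ROISet(rois=rois)


def roi_mean_rdm(store: RDMStore, roi: ROI, **provenance) -> RDM:
    """Cellwise mean of the searchlight RDMs centered inside the ROI."""
    if roi.mask.shape != store.dims:
        raise ValueError("ROI grid does not match the RDM store")
    rows = store.centers_in(roi.mask)
    if rows.size == 0:
        raise ValueError(f"ROI {roi.name!r} contains no stored searchlight centers")
    vals = store.values[rows].astype(float).mean(axis=0)
    return RDM(values=vals, space=store.space,
               provenance={"roi": roi.name, "n_centers": int(rows.size),
                           **provenance})


def leave_one_out_rois(
    subject_maps: Sequence[StatMap] | Sequence[np.ndarray],
    threshold_p: float = 0.001,
    maps_b: Sequence[StatMap] | Sequence[np.ndarray] | None = None,
) -> LeaveOneOutROISet:
    """Leave-one-participant-out ROI families.

    For each subject s the group t map is re-estimated from all other
    subjects, thresholded at the uncorrected ``threshold_p``, and its
    18-connected components become the ROI family for s.  The family's
    provenance records the subjects used, so the independence of the
    held-out subject is checkable.
    """
    data = _stack(subject_maps)
    if maps_b is not None:
        data = data - _stack(maps_b)
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for leave-one-out ROIs")
    families: dict[int, list[ROI]] = {}
    for s in range(n):
        others = np.delete(data, s, axis=0)
        m = others.shape[0]
        if m < 2:
            warnings.warn(f"family {s}: fewer than 2 defining subjects; "
                          "empty family", stacklevel=2)
            families[s] = []
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            t = others.mean(0) / (others.std(0, ddof=1) / np.sqrt(m))
        thr = float(sps.t.ppf(1.0 - threshold_p, m - 1))
        binary = np.where(np.isfinite(t), t, -np.inf) > thr
        labels, n_clu = _label_clusters(binary)
        fam = [
            ROI(
                name=f"loo{s}_cluster_{k}",
                mask=labels == k,
                provenance={
                    "kind": "leave_one_out",
                    "held_out_subject": s,
                    "subjects_used": [i for i in range(n) if i != s],
                    "threshold_p": threshold_p,
                },
            )
            for k in range(1, n_clu + 1)
        ]
        if not fam:
            warnings.warn(f"family {s}: no suprathreshold voxels", stacklevel=2)
        families[s] = fam
    return LeaveOneOutROISet(families=families, threshold_p=threshold_p)


def orthogonality_guard(model: ModelRDM, selection: CellMask,
                        roi: ROI | None = None) -> str:
    """Check that fitting ``model`` in an ROI selected by the mean distance
    over ``selection`` cells is statistically unbiased.

    Rank (and Pearson) correlation with a model removes the mean of the
    cells the model is tested on, so a model whose predictions do not
    co-vary with membership in the selection set is orthogonal to selection.
    A model that predicts systematically larger values on the selecting
    cells than on its remaining cells (the producer-identity models, whose
    "different producer" cells are exactly the selecting cells) is not, and
    is only admitted in a leave-one-out ROI.

    Returns ``"pass"`` or ``"violation"``.
    """
    if model.space is not selection.space and \
            model.space.conditions != selection.space.conditions:
        raise ValueError("model and selection mask live on different spaces")
    if roi is not None and roi.is_leave_one_out:
        return "pass"
    indicator = selection.values[model.mask.values].astype(float)
    if indicator.size == 0:
        raise ValueError("model has an empty mask")
    if np.all(indicator == indicator[0]):
        return "pass"  # selection mean is removed by the correlation
    vals = model.masked_values
    if np.all(vals == vals[0]):
        return "pass"
    r = np.corrcoef(vals, indicator)[0, 1]
    return "violation" if abs(r) > 1e-8 else "pass"


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def match_rois_by_overlap(families: LeaveOneOutROISet,
                          reference: ROI) -> dict[int, ROI | None]:
    """For each family, the member ROI with maximal Dice overlap with a
    reference ROI (None when a family is empty or has no overlap)."""
    out: dict[int, ROI | None] = {}
    for s, fam in families.families.items():
        best, best_d = None, 0.0
        for roi in fam:
            d = dice(roi.mask, reference.mask)
            if d > best_d:
                best, best_d = roi, d
        out[s] = best
    return out
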