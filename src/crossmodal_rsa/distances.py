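"""Multivariate noise normalization and cross-validated Mahalanobis distances.

The spatial noise covariance across voxels is estimated from first-level GLM
residual frames, shrunk toward its diagonal with an analytic intensity, and
averaged across runs.  Condition patterns are prewhitened by the inverse
symmetric square root of this covariance, which down-weights correlated noisy
voxels, and pairwise pattern distances are then cross-validated over run
folds.  The cross-run form of the estimator makes run-specific noise cancel
in expectation, so a distance of zero is interpretable as "no pattern
difference" and individual cells may legitimately be negative.

For conditions i, j with run-m patterns ``b_i^m`` over P voxels:

    d(i, j) = 1 / (P * R * (R - 1)) *
              sum_{m != n} (b_i^m - b_j^m)' S^-1 (b_i^n - b_j^n)

with S the shrunk noise covariance and the sum over ordered run pairs.  The
1/P normalization keeps distances comparable between searchlight spheres of
different effective size at mask edges.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import CellMask, ConditionSpace

_EIG_TOL = 1e-10


@dataclass
class NoiseCovariance:
    """Run-averaged spatial noise covariance with recorded shrinkage."""

    matrix: np.ndarray  # (V, V)
    lam: float
    n_runs: int
    singular: bool = False

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]


def _diag_shrinkage_intensity(X: np.ndarray) -> float:
    """Analytic (Ledoit-Wolf-type) intensity for shrinkage toward diag(S).

    Ratio of the summed sampling variances of the off-diagonal covariance
    entries to their summed squares, clipped to [0, 1].  ``X`` holds demeaned
    residual frames (frames x voxels).
    """
    f = X.shape[0]
    if f < 2:
        return 1.0
    s = X.T @ X / f
    x2 = X * X
    sum_w2 = x2.T @ x2  # sum_t x_ti^2 x_tj^2
    var_s = (f / (f - 1) ** 3) * (sum_w2 - f * s * s)
    off = ~np.eye(s.shape[0], dtype=bool)
    denom = float((s[off] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_s[off].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def estimate_noise_cov(
    run_residuals: Sequence[np.ndarray],
    lam: float | None = None,
) -> NoiseCovariance:
    """Estimate the voxel noise covariance from per-run residual frames.

    Each run's sample covariance (population 1/N convention, frames demeaned
    per run) is shrunk toward its diagonal, ``(1 - lam) S + lam diag(S)``,
    and the shrunk covariances are averaged across runs.  When ``lam`` is not
    supplied an analytic intensity is computed per run and the recorded
    intensity is their mean.
    """
    if lam is not None and not (0.0 <= lam <= 1.0):
        raise ValueError(f"shrinkage weight must be in [0, 1], got {lam}")
    if not run_residuals:
        raise ValueError("no residual runs supplied")
    mats = []
    lams = []
    v = run_residuals[0].shape[1]
    for res in run_residuals:
        res = np.asarray(res, dtype=float)
        if res.ndim != 2 or res.shape[1] != v:
            raise ValueError("residual runs must share the voxel dimension")
        if res.shape[0] < 2:
            raise ValueError("need at least 2 residual frames per run")
        x = res - res.mean(axis=0, keepdims=True)
        s = x.T @ x / x.shape[0]
        li = _diag_shrinkage_intensity(x) if lam is None else lam
        mats.append((1.0 - li) * s + li * np.diag(np.diag(s)))
        lams.append(li)
    sigma = np.mean(mats, axis=0)
    eig = np.linalg.eigvalsh(sigma)
    singular = bool(eig.min() <= _EIG_TOL * max(eig.max(), 1.0))
    return NoiseCovariance(
        matrix=sigma, lam=float(np.mean(lams)), n_runs=len(run_residuals),
        singular=singular,
    )


def _inv_sqrt(cov: NoiseCovariance) -> np.ndarray:
    if cov.singular:
        raise np.linalg.LinAlgError(
            "noise covariance is singular; re-estimate with shrinkage "
            "(lam > 0 or the analytic default)"
        )
    w, u = np.linalg.eigh(cov.matrix)
    if w.min() <= _EIG_TOL * max(w.max(), 1.0):
        raise np.linalg.LinAlgError("noise covariance is not positive definite")
    return (u / np.sqrt(w)) @ u.T


def prewhiten(betas: np.ndarray, cov: NoiseCovariance) -> np.ndarray:
    """Multiply patterns by the inverse symmetric square root of the covariance.

    Crossnobis on whitened patterns with the identity covariance equals
    crossnobis on the raw patterns with ``cov``.
    """
    w = _inv_sqrt(cov)
    betas = np.asarray(betas, dtype=float)
    if betas.shape[-1] != cov.n_voxels:
        raise ValueError("voxel dimension does not match the covariance")
    return betas @ w


@dataclass
class RDM:
    """Dissimilarities over unordered condition pairs (upper triangle).

    ``values[k]`` is the distance for the k-th pair in canonical
    ``np.triu_indices`` order.  Cross-validated cells may be negative.
    """

    values: np.ndarray
    space: ConditionSpace = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.space.n_pairs,):
            raise ValueError("RDM length does not match the condition space")

    def to_square(self) -> np.ndarray:
        n = self.space.n_conditions
        sq = np.zeros((n, n))
        ii, jj = self.space.pair_indices()
        sq[ii, jj] = self.values
        sq[jj, ii] = self.values
        return sq

    def to_square_frame(self) -> pd.DataFrame:
        labels = self.space.condition_labels()
        return pd.DataFrame(self.to_square(), index=labels, columns=labels)

    def to_long_frame(self) -> pd.DataFrame:
        ii, jj = self.space.pair_indices()
        labels = self.space.condition_labels()
        return pd.DataFrame(
            {
                "condition_a": [labels[i] for i in ii],
                "condition_b": [labels[j] for j in jj],
                "distance": self.values,
            }
        )

    def mean_over(self, mask: CellMask) -> float:
        if mask.n_cells == 0:
            raise ValueError("empty cell mask")
        return float(self.values[mask.values].mean())

    def masked_values(self, mask: CellMask) -> np.ndarray:
        return self.values[mask.values]

    def save_csv(self, path) -> None:
        self.to_square_frame().to_csv(path)

    @classmethod
    def load_csv(cls, path, space: ConditionSpace) -> "RDM":
        df = pd.read_csv(path, index_col=0)
        labels = space.condition_labels()
        sq = df.loc[labels, labels].to_numpy(dtype=float)
        ii, jj = space.pair_indices()
        return cls(values=sq[ii, jj], space=space)


def mean_rdm(rdms: Sequence[RDM]) -> RDM:
    """Cellwise mean of RDMs defined on one condition space."""
    if not rdms:
        raise ValueError("no RDMs to average")
    space = rdms[0].space
    vals = np.mean([r.values for r in rdms], axis=0)
    return RDM(values=vals, space=space, provenance={"mean_of": len(rdms)})


def crossnobis_distances(
    betas: np.ndarray,
    cov: NoiseCovariance | None = None,
    *,
    normalize_voxels: bool = True,
) -> np.ndarray:
    """Cross-validated Mahalanobis distances for all condition pairs.

    Parameters
    ----------
    betas
        Array (runs, conditions, voxels) of per-run condition patterns.
    cov
        Noise covariance over the same voxels; ``None`` means identity
        (plain cross-validated Euclidean).
    normalize_voxels
        Divide by the voxel count P (the default), keeping distances on a
        per-voxel scale.

    Returns
    -------
    Pair vector of length ``C * (C - 1) / 2`` in ``np.triu_indices`` order.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.ndim != 3:
        raise ValueError("betas must be (runs, conditions, voxels)")
    r, c, p = betas.shape
    if r < 2:
        raise ValueError("crossnobis needs at least 2 runs")
    if cov is not None:
        if cov.n_voxels != p:
            raise ValueError("covariance voxel count does not match betas")
        white = prewhiten(betas, cov)
    else:
        white = betas
    ii, jj = np.triu_indices(c, k=1)
    diffs = white[:, ii, :] - white[:, jj, :]  # (R, n_pairs, P)
    total = diffs.sum(axis=0)
    # sum over ordered run pairs m != n of <d^m, d^n> = |sum_m d^m|^2 - sum_m |d^m|^2
    cross = (total * total).sum(axis=-1) - (diffs * diffs).sum(axis=-1).sum(axis=0)
    denom = r * (r - 1)
    if normalize_voxels:
        denom *= p
    return cross / denom


def crossnobis_rdm(
    subject,
    voxels: np.ndarray | None = None,
    cov: NoiseCovariance | None = None,
    **provenance,
) -> RDM:
    """Crossnobis RDM for a subject, optionally restricted to a voxel subset.

    ``subject`` is a :class:`~crossmodal_rsa.simulate.SubjectData`;
    ``voxels`` indexes its flat voxel axis.  All conditions enter the RDM —
    restriction to cell subsets happens at model-fit time, not here.
    """
    betas = subject.betas
    if voxels is not None:
        betas = betas[:, :, voxels]
    if cov is not None and cov.n_voxels != betas.shape[-1]:
        raise ValueError("covariance voxel count does not match the voxel subset")
    vals = crossnobis_distances(betas, cov)
    prov = {"subject": getattr(subject, "subject_id", None), **provenance}
    return RDM(values=vals, space=subject.space, provenance=prov)
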