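"""File formats: NIfTI volumes, CSV tables, YAML configs, JSON provenance.

Volumes are NIfTI-1 with an RAS+ diagonal affine in mm.  Beta volumes are
written one 4D file per run (last axis = conditions in canonical order, as
recorded in the accompanying condition table); residuals one 4D file per run
(last axis = frames).  Every artifact directory carries a JSON sidecar with
the seeds and package version that produced it.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .conditions import ConditionSpace, build_condition_space
from .searchlight import StatMap
from .simulate import SubjectData


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag([*voxel_size_mm, 1.0])


def save_volume(data3d_or_4d: np.ndarray, voxel_size_mm, path) -> None:
    img = nib.Nifti1Image(np.asarray(data3d_or_4d, dtype=np.float64),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), vs


def save_stat_map(stat_map: StatMap, voxel_size_mm, path) -> None:
    save_volume(stat_map.data, voxel_size_mm, path)


def write_subject(subject: SubjectData, outdir) -> dict:
    """Write one subject as per-run beta/residual NIfTI plus condition CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = subject.subject_id
    dims = subject.dims
    manifest = {"subject": sid, "beta": [], "residual": []}
    for r in range(subject.n_runs):
        bpath = outdir / f"sub-{sid:02d}_run-{r + 1}_beta.nii"
        rpath = outdir / f"sub-{sid:02d}_run-{r + 1}_residuals.nii"
        save_volume(subject.betas[r].T.reshape(*dims, -1),
                    subject.voxel_size_mm, bpath)
        save_volume(subject.residuals[r].T.reshape(*dims, -1),
                    subject.voxel_size_mm, rpath)
        manifest["beta"].append(str(bpath))
        manifest["residual"].append(str(rpath))
    cpath = outdir / f"sub-{sid:02d}_conditions.csv"
    subject.space.to_csv(cpath)
    manifest["conditions"] = str(cpath)
    return manifest


def read_subject_data(
    beta_paths,
    residual_paths,
    condition_csv,
    mask_path=None,
    space: ConditionSpace | None = None,
    subject_id: int = 0,
) -> SubjectData:
    """Assemble a :class:`SubjectData` from per-run volumes + condition table.

    The condition table's row order gives the order of the beta volumes; the
    betas are re-sorted to the canonical condition order on load, so a
    shuffled table yields identical downstream results.
    """
    df = pd.read_csv(condition_csv)
    needed = {"item", "modality", "model_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"condition table needs columns {sorted(needed)}")
    if space is None:
        space = build_condition_space() if "category" not in df.columns else \
            _space_from_table(df)
    listed = [(r["item"], r["modality"], int(r["model_id"]))
              for _, r in df.iterrows()]
    missing = [c for c in space.conditions if c not in listed]
    if missing:
        raise ValueError(f"condition table is missing conditions: {missing}")
    if len(listed) != space.n_conditions:
        raise ValueError(
            f"expected {space.n_conditions} condition rows, got {len(listed)}"
        )
    order = np.array([listed.index(c) for c in space.conditions])

    if len(beta_paths) != len(residual_paths):
        raise ValueError("need one residual file per beta file (per run)")
    betas, residuals = [], []
    dims = None
    voxel_size = None
    for bp, rp in zip(beta_paths, residual_paths):
        b4, vs = load_volume(bp)
        r4, vs2 = load_volume(rp)
        if dims is None:
            dims, voxel_size = b4.shape[:3], vs
        if b4.shape[:3] != dims or r4.shape[:3] != dims or vs2 != vs:
            raise ValueError("volume grids are inconsistent across runs")
        if b4.shape[3] != space.n_conditions:
            raise ValueError(
                f"{bp}: expected {space.n_conditions} beta volumes, "
                f"got {b4.shape[3]}"
            )
        b = b4.reshape(-1, b4.shape[3]).T  # (conditions, V)
        betas.append(b[order])
        residuals.append(r4.reshape(-1, r4.shape[3]).T)
    subj = SubjectData(
        subject_id=subject_id,
        betas=np.stack(betas),
        residuals=np.stack(residuals),
        dims=tuple(dims),
        voxel_size_mm=tuple(voxel_size),
        space=space,
    )
    if mask_path is not None:
        mask, _ = load_volume(mask_path)
        if mask.shape != tuple(dims):
            raise ValueError("mask grid does not match the data")
    return subj


def _space_from_table(df: pd.DataFrame) -> ConditionSpace:
    # the canonical item order comes from canonical_index when recorded, so
    # a row-shuffled table still reconstructs the same condition space
    if "canonical_index" in df.columns:
        df = df.sort_values("canonical_index")
    items, cat = [], {}
    for _, r in df.iterrows():
        if r["item"] not in items:
            items.append(r["item"])
            cat[r["item"]] = r["category"]
    return build_condition_space(items, cat, strict=len(items) == 9)


# ------------------------------------------------------------------ config

@dataclass
class RunConfig:
    """Pipeline configuration (YAML-serializable)."""

    out_dir: str = "out"
    seed: int = 0
    # scene
    n_subjects: int = 17
    n_runs: int = 6
    dims: tuple[int, int, int] = (12, 12, 8)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 6.0
    n_residual_frames: int = 60
    subject_jitter_sd: float = 0.2
    region_strength: float = 0.08
    region_size: tuple[int, int, int] = (3, 3, 3)
    # searchlight
    radius_mm: float = 8.0
    min_in_mask_fraction: float = 0.5
    shrinkage: float | None = None
    # inference
    cluster_forming_p: float = 0.005
    q: float = 0.05
    n_permutations: int = 500
    loo_threshold_p: float = 0.001
    base_alpha: float = 0.05

    def __post_init__(self):
        for name in ("cluster_forming_p", "q", "loo_threshold_p", "base_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dims", "voxel_size_mm", "region_size"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(self).items()},
                fh, sort_keys=False,
            )


def write_provenance(path, **fields) -> None:
    from . import __version__
    payload = {"package": "crossmodal-rsa", "version": __version__, **fields}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


# ------------------------------------------------------- packaged stimuli

def packaged_phonemes() -> dict[str, list[str]]:
    """Phoneme transcriptions of the nine spoken items (space-separated IPA)."""
    with resources.files("crossmodal_rsa.data").joinpath("phonemes.csv").open() as fh:
        df = pd.read_csv(fh)
    return {r["item"]: r["phonemes"].split() for _, r in df.iterrows()}


def packaged_iconicity() -> dict[str, float]:
    """Synthetic per-item iconicity ratings (1-7 scale).

    Item-level ratings for the stimulus set are not available; these
    synthetic values reproduce its category-mean ratings exactly
    (fruit 3.80, animals 3.92, transport 4.23).
    """
    name = "iconicity_synthetic.csv"
    with resources.files("crossmodal_rsa.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh)
    return {r["item"]: float(r["iconicity"]) for _, r in df.iterrows()}
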