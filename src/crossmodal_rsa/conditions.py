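"""Condition labels, canonical RDM ordering, and cell-mask algebra.

The experiment crosses a small set of conceptual items (grouped into semantic
categories) with two presentation modalities (speech, sign) and two producers
("language models": speaker 1/2, signer 1/2).  With the default nine items
this yields 36 conditions.  Representational dissimilarity matrices (RDMs) are
stored over unordered condition pairs (the upper triangle of the square
matrix); analyses never touch the diagonal.

Cell masks select the pair subsets the analyses are restricted to, e.g. the
within-modality cells that cross producers (speaker 1 vs speaker 2) so that
low-level perceptual similarity between identical tokens cannot drive a fit.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CATEGORY_OF: dict[str, str] = {
    "orange": "fruit",
    "grapes": "fruit",
    "apple": "fruit",
    "mouse": "animals",
    "lion": "animals",
    "monkey": "animals",
    "train": "transport",
    "bus": "transport",
    "bicycle": "transport",
}
DEFAULT_ITEMS: tuple[str, ...] = tuple(DEFAULT_CATEGORY_OF)

MODALITIES: tuple[str, str] = ("speech", "sign")
MODEL_IDS: tuple[int, int] = (1, 2)

#: selectors accepted by :func:`cell_mask`
SELECTORS = (
    "within_speech_across_speaker",
    "within_sign_across_signer",
    "within_modality_combined",
    "across_modality",
    "within_modality_all",
)


@dataclass(frozen=True)
class ConditionSpace:
    """The full condition labeling and its canonical order.

    The canonical order is modality-major (all speech conditions, then all
    sign conditions), producer id next, item last, which keeps the per-block
    item-by-item submatrices of the square RDM contiguous.
    """

    items: tuple[str, ...]
    category_of: Mapping[str, str]
    modalities: tuple[str, str] = MODALITIES
    model_ids: tuple[int, int] = MODEL_IDS
    conditions: tuple[tuple[str, str, int], ...] = ()

    # ------------------------------------------------------------------ sizes
    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_pairs(self) -> int:
        n = self.n_conditions
        return n * (n - 1) // 2

    @property
    def categories(self) -> tuple[str, ...]:
        seen: list[str] = []
        for it in self.items:
            c = self.category_of[it]
            if c not in seen:
                seen.append(c)
        return tuple(seen)

    # --------------------------------------------------------------- indexing
    def index_of(self, item: str, modality: str, model_id: int) -> int:
        return self.conditions.index((item, modality, model_id))

    def item_index(self) -> np.ndarray:
        lut = {it: i for i, it in enumerate(self.items)}
        return np.array([lut[c[0]] for c in self.conditions])

    def category_index(self) -> np.ndarray:
        cats = self.categories
        lut = {c: i for i, c in enumerate(cats)}
        return np.array([lut[self.category_of[c[0]]] for c in self.conditions])

    def modality_index(self) -> np.ndarray:
        lut = {m: i for i, m in enumerate(self.modalities)}
        return np.array([lut[c[1]] for c in self.conditions])

    def model_index(self) -> np.ndarray:
        lut = {m: i for i, m in enumerate(self.model_ids)}
        return np.array([lut[c[2]] for c in self.conditions])

    def pair_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/column condition indices of the upper-triangle pair vector."""
        return np.triu_indices(self.n_conditions, k=1)

    def condition_labels(self) -> list[str]:
        return [f"{m}.{g}.{it}" for it, m, g in self.conditions]

    # ------------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "canonical_index": i,
                "item": it,
                "category": self.category_of[it],
                "modality": mo,
                "model_id": g,
            }
            for i, (it, mo, g) in enumerate(self.conditions)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ConditionSpace":
        df = pd.read_csv(path).sort_values("canonical_index")
        items: list[str] = []
        cat: dict[str, str] = {}
        for _, row in df.iterrows():
            if row["item"] not in items:
                items.append(row["item"])
                cat[row["item"]] = row["category"]
        space = build_condition_space(items, cat, strict=len(items) == 9)
        got = [
            (r["item"], r["modality"], int(r["model_id"]))
            for _, r in df.iterrows()
        ]
        if tuple(got) != space.conditions:
            raise ValueError("condition table is not in canonical order")
        return space


def build_condition_space(
    items: Sequence[str] = DEFAULT_ITEMS,
    category_of: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> ConditionSpace:
    """Build a :class:`ConditionSpace` in canonical order.

    Parameters
    ----------
    items
        Ordered item labels.  The default design has nine, three per category.
    category_of
        Mapping item -> category label; defaults to the standard design.
    strict
        When True (the default), enforce the full design: nine distinct
        items, exactly three per category.  ``strict=False`` relaxes the
        count checks so tiny spaces can be built for unit exercises.
    """
    items = tuple(items)
    if category_of is None:
        category_of = DEFAULT_CATEGORY_OF
    if len(set(items)) != len(items):
        raise ValueError("duplicate item labels")
    missing = [it for it in items if it not in category_of]
    if missing:
        raise ValueError(f"items without a category: {missing}")
    if strict:
        if len(items) != 9:
            raise ValueError(f"expected 9 items, got {len(items)}")
        counts: dict[str, int] = {}
        for it in items:
            counts[category_of[it]] = counts.get(category_of[it], 0) + 1
        bad = {c: n for c, n in counts.items() if n != 3}
        if bad:
            raise ValueError(f"each category needs exactly 3 items, got {bad}")
    conditions = tuple(
        (it, mo, g)
        for mo in MODALITIES
        for g in MODEL_IDS
        for it in items
    )
    cat = {it: category_of[it] for it in items}
    return ConditionSpace(items=items, category_of=cat, conditions=conditions)


@dataclass(frozen=True)
class CellMask:
    """Boolean indicator over unordered condition pairs (i < j, canonical)."""

    name: str
    values: np.ndarray  # (n_pairs,) bool
    space: ConditionSpace = field(repr=False)

    def __post_init__(self):
        if self.values.shape != (self.space.n_pairs,):
            raise ValueError("mask length does not match the condition space")

    @property
    def n_cells(self) -> int:
        return int(self.values.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.values)

    def __and__(self, other: "CellMask") -> "CellMask":
        return CellMask(f"{self.name}&{other.name}", self.values & other.values, self.space)

    def __or__(self, other: "CellMask") -> "CellMask":
        return CellMask(f"{self.name}|{other.name}", self.values | other.values, self.space)

    def __invert__(self) -> "CellMask":
        return CellMask(f"~{self.name}", ~self.values, self.space)


def cell_mask(space: ConditionSpace, selector: str, modality: str | None = None) -> CellMask:
    """Build one of the named pair-subset masks.

    ``within_*_across_*`` masks pair the two producers of one modality and
    exclude same-producer pairs; ``across_modality`` pairs every speech
    condition with every sign condition; ``within_modality_all`` (which needs
    the ``modality`` argument, also accepted inline as e.g.
    ``"within_modality_all(speech)"``) additionally includes same-producer
    pairs — the identity models need those cells to have any rank variation.
    """
    if selector.startswith("within_modality_all(") and selector.endswith(")"):
        modality = selector[len("within_modality_all("):-1]
        selector = "within_modality_all"
    mod = space.modality_index()
    grp = space.model_index()
    ii, jj = space.pair_indices()
    same_mod = mod[ii] == mod[jj]
    same_grp = grp[ii] == grp[jj]

    def _is(mname: str) -> np.ndarray:
        k = space.modalities.index(mname)
        return (mod[ii] == k) & (mod[jj] == k)

    if selector == "within_speech_across_speaker":
        vals = _is("speech") & ~same_grp
    elif selector == "within_sign_across_signer":
        vals = _is("sign") & ~same_grp
    elif selector == "within_modality_combined":
        vals = same_mod & ~same_grp
    elif selector == "across_modality":
        vals = ~same_mod
    elif selector == "within_modality_all":
        if modality is None:
            raise ValueError("within_modality_all requires a modality")
        if modality not in space.modalities:
            raise ValueError(f"unknown modality {modality!r}")
        vals = _is(modality)
        selector = f"within_modality_all({modality})"
    else:
        raise ValueError(f"unknown selector {selector!r}")
    return CellMask(selector, vals, space)


def same_item_cells(space: ConditionSpace) -> np.ndarray:
    """Indicator over pairs whose two conditions present the same item."""
    it = space.item_index()
    ii, jj = space.pair_indices()
    return it[ii] == it[jj]


def same_category_cells(space: ConditionSpace) -> np.ndarray:
    cat = space.category_index()
    ii, jj = space.pair_indices()
    return cat[ii] == cat[jj]
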