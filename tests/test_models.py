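"""Model RDM construction and stimulus distance measures."""
import numpy as np
import pandas as pd
import pytest

from crossmodal_rsa.conditions import build_condition_space, cell_mask, same_item_cells
from crossmodal_rsa.models import (
    _levenshtein_dp,
    category_model,
    iconicity_model,
    identity_model,
    item_model,
    item_pair_correlation,
    levenshtein_phon_distance,
    model_correlation,
    semantic_feature_model,
)


@pytest.fixture(scope="module")
def within(space):
    return cell_mask(space, "within_speech_across_speaker")


@pytest.fixture(scope="module")
def across(space):
    return cell_mask(space, "across_modality")


def test_cosine_distance_hand_example(space, within):
    # vectors (1,1,0),(1,0,0),(0,0,1): d12 = 1-1/sqrt(2), d13 = d23 = 1
    feats = np.zeros((9, 3))
    feats[:, :] = [[0, 0, 1]] * 9
    feats[0] = [1, 1, 0]
    feats[1] = [1, 0, 0]
    model = semantic_feature_model(feats, space, within)
    i0 = space.index_of(space.items[0], "speech", 1)
    i1 = space.index_of(space.items[1], "speech", 2)
    sq = model.to_square_frame().to_numpy()
    assert sq[i0, i1] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-6)
    i2 = space.index_of(space.items[2], "speech", 2)
    assert sq[i0, i2] == pytest.approx(1.0)
    # same item, different producer -> identical vectors -> 0
    j0 = space.index_of(space.items[0], "speech", 2)
    assert sq[i0, j0] == pytest.approx(0.0)


def test_zero_feature_vector_rejected(space, within):
    feats = np.ones((9, 3))
    feats[4] = 0
    with pytest.raises(ValueError, match="zero feature vector"):
        semantic_feature_model(feats, space, within)


def test_item_model_counts(space, within, across):
    m = item_model(space, within)
    vals = m.masked_values
    assert m.mask.n_cells == 81
    assert (vals == 0).sum() == 9 and (vals == 1).sum() == 72
    ma = item_model(space, across)
    va = ma.masked_values
    assert (va == 0).sum() == 36 and (va == 1).sum() == 288


def test_item_model_constant_mask_warns(space):
    # a mask with no same-item cells leaves the model constant
    mask = cell_mask(space, "within_speech_across_speaker")
    keep = mask.values & ~same_item_cells(space)
    from crossmodal_rsa.conditions import CellMask

    diff_only = CellMask("diff_only", keep, space)
    with pytest.warns(UserWarning, match="constant"):
        m = item_model(space, diff_only)
    assert m.is_constant


def test_category_model_drops_same_item_cells(space, norms, within, across):
    sem = semantic_feature_model(norms, space, within)
    cat = category_model(sem, space, within)
    assert cat.mask.n_cells == 72
    sem_a = semantic_feature_model(norms, space, across)
    cat_a = category_model(sem_a, space, across)
    assert cat_a.mask.n_cells == 288
    # same-item cells absent from the category mask
    assert not (cat_a.mask.values & same_item_cells(space)).any()
    # predictions copied from the feature model on retained cells
    assert np.allclose(cat.masked_values, sem.values[cat.mask.values])


def test_identity_model_counts_and_symmetry(space):
    sp = identity_model(space, "speech")
    vals = sp.masked_values
    assert sp.mask.n_cells == 153
    assert (vals == 0).sum() == 72 and (vals == 1).sum() == 81
    sg = identity_model(space, "sign")
    assert (sg.masked_values == 0).sum() == 72
    with pytest.raises(ValueError, match="modality"):
        identity_model(space, "text")


def test_iconicity_model_absolute_differences(space, within):
    ratings = {it: 4.0 for it in space.items}
    ratings[space.items[0]] = 3.80
    ratings[space.items[1]] = 4.23
    m = iconicity_model(ratings, space, within)
    i0 = space.index_of(space.items[0], "speech", 1)
    i1 = space.index_of(space.items[1], "speech", 2)
    sq = m.to_square_frame().to_numpy()
    assert sq[i0, i1] == pytest.approx(0.43)
    ratings2 = dict.fromkeys(space.items, 1.0)
    ratings2[space.items[0]] = 7.0
    m2 = iconicity_model(ratings2, space, within)
    assert np.nanmax(m2.values) == pytest.approx(6.0)


def test_iconicity_out_of_scale_warns(space, within):
    with pytest.warns(UserWarning, match="1-7"):
        iconicity_model(dict.fromkeys(space.items, 8.0), space, within)


def test_levenshtein_examples_match_dp_oracle():
    trans = {
        "bus": ["b", "ʌ", "s"],
        "train": ["t", "r", "eɪ", "n"],
        "mouse": ["m", "aʊ", "s"],
        "monkey": ["m", "ʌ", "ŋ", "k", "i"],
    }
    d = levenshtein_phon_distance(trans)
    assert d.loc["bus", "train"] == pytest.approx(1.0)  # 4 edits / 4
    assert d.loc["mouse", "monkey"] == pytest.approx(0.8)  # 4 edits / 5
    assert d.loc["bus", "bus"] == 0.0
    assert np.allclose(d.to_numpy(), d.to_numpy().T)


def test_edlib_path_agrees_with_dp_oracle(rng):
    alphabet = [f"ph{k}" for k in range(12)]
    for _ in range(100):
        a = list(rng.choice(alphabet, size=rng.integers(1, 9)))
        b = list(rng.choice(alphabet, size=rng.integers(1, 9)))
        d = levenshtein_phon_distance({"a": a, "b": b}).loc["a", "b"]
        assert d == pytest.approx(_levenshtein_dp(a, b) / max(len(a), len(b)))


def test_empty_transcription_rejected():
    with pytest.raises(ValueError, match="empty"):
        levenshtein_phon_distance({"a": []})


def test_model_correlation_self_and_complement(space, within):
    m = item_model(space, within)
    assert model_correlation(m, m) == pytest.approx(1.0)
    comp = item_model(space, within)
    comp.values = 1.0 - comp.values
    assert model_correlation(m, comp) == pytest.approx(-1.0)


def test_independent_models_near_zero_correlation(space, within, rng):
    from crossmodal_rsa.models import ModelRDM

    rs = []
    for _ in range(200):
        a = ModelRDM("a", np.where(within.values, rng.normal(size=space.n_pairs), np.nan), within, space)
        b = ModelRDM("b", np.where(within.values, rng.normal(size=space.n_pairs), np.nan), within, space)
        rs.append(model_correlation(a, b))
    assert abs(np.mean(rs)) < 2 / np.sqrt(within.n_cells)


def test_item_pair_correlation_n36(space, norms):
    from crossmodal_rsa.io import packaged_phonemes
    from crossmodal_rsa.models import feature_distance_matrix

    phon = levenshtein_phon_distance(packaged_phonemes())
    sem = pd.DataFrame(feature_distance_matrix(norms, space),
                       index=list(space.items), columns=list(space.items))
    r, p, n = item_pair_correlation(phon, sem)
    assert n == 36  # 9 items -> 36 unordered pairs
    assert -1 <= r <= 1


def test_decomposition_rank_consistency(space, norms, within):
    """The feature model restricted to different-item cells has the category
    model's rank order; its same-vs-different-item contrast is the item
    model's."""
    sem = semantic_feature_model(norms, space, within)
    cat = category_model(sem, space, within)
    it = item_model(space, within)
    # category component: identical values on the category mask
    assert np.allclose(sem.values[cat.mask.values], cat.masked_values)
    # item component: same-item cells predicted strictly below any
    # different-item cell by the feature model
    same = same_item_cells(space) & within.values
    diff = ~same_item_cells(space) & within.values
    assert sem.values[same].max() < sem.values[diff].min()
    assert set(np.unique(it.masked_values)) == {0.0, 1.0}
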