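"""Tau-a fitting, Fisher conversion, group tests, ceilings, verdicts."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmodal_rsa.conditions import cell_mask
from crossmodal_rsa.distances import RDM
from crossmodal_rsa.stats import (
    adjust_alpha,
    classify_region,
    fit_models_in_region,
    noise_ceiling,
    one_sample_t,
    paired_t,
    percent_correct,
    standard_model_set,
    tau_a,
    tau_to_z,
)


# ------------------------------------------------------------------- tau-a

def test_tau_a_brute_force_examples():
    # 6 pairs, one discordant -> (5-1)/6
    assert tau_a([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(4 / 6)
    # tied model pair contributes neither way -> 2/3
    assert tau_a([1, 2, 3], [1, 1, 2]) == pytest.approx(2 / 3)
    assert tau_a([3.2, 1.5, 9.9, 0.1], [3.2, 1.5, 9.9, 0.1]) == 1.0


def test_tau_a_constant_model_rejected():
    with pytest.raises(ValueError, match="constant"):
        tau_a([1, 2, 3], [5, 5, 5])


def test_tau_a_constant_data_is_zero():
    # fully tied data: no concordant or discordant pairs
    assert tau_a([2, 2, 2, 2], [1, 2, 3, 4]) == 0.0


@given(st.integers(0, 10_000))
@settings(max_examples=200, deadline=None)
def test_tau_fast_path_equals_exact(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(3, 40))
    # heavy ties, like model RDMs
    x = rng.integers(0, 5, size=m).astype(float)
    y = rng.integers(0, 3, size=m).astype(float)
    if np.all(y == y[0]):
        y[0] += 1
    assert tau_a(x, y, method="fast") == tau_a(x, y, method="exact")


def test_tau_to_z_closed_form():
    assert tau_to_z(0.0) == (0.0, 0.0)
    r, z = tau_to_z(0.5)
    assert r == pytest.approx(0.70711, abs=1e-5)
    assert z == pytest.approx(0.88137, abs=1e-5)
    r1, z1 = tau_to_z(1.0)
    assert r1 == 1.0 and np.isfinite(z1)
    with pytest.raises(ValueError):
        tau_to_z(1.5)


def test_tau_to_z_odd_and_increasing():
    taus = np.linspace(-0.99, 0.99, 41)
    zs = np.array([tau_to_z(t)[1] for t in taus])
    assert np.all(np.diff(zs) > 0)
    assert np.allclose(zs, -zs[::-1], atol=1e-12)


# -------------------------------------------------------------- group tests

def test_one_sample_t_hand_example():
    gt = one_sample_t([1.0, 2.0, 3.0])
    assert gt.t == pytest.approx(3.4641, abs=1e-4)
    assert gt.df == 2
    assert gt.d_z == pytest.approx(2.0)


def test_one_sample_t_symmetric_values_p_half(rng):
    v = rng.normal(size=5000)
    gt = one_sample_t(v - v.mean() + 1e-18)
    assert gt.p == pytest.approx(0.5, abs=0.05)


def test_one_sample_t_zero_variance_errors():
    with pytest.raises(ValueError, match="variance"):
        one_sample_t([0.5, 0.5, 0.5])


def test_paired_t_difference_and_antisymmetry():
    z2 = np.array([0.0, 0.0, 0.0])
    z1 = np.array([1.0, 2.0, 3.0])
    pt = paired_t(z1, z2)
    assert abs(pt.t) == pytest.approx(3.4641, abs=1e-4)
    one_tailed = one_sample_t(z1).p
    assert pt.p == pytest.approx(2 * one_tailed, abs=1e-10)
    flipped = paired_t(z2, z1)
    assert flipped.t == pytest.approx(-pt.t)
    assert flipped.p == pytest.approx(pt.p)
    with pytest.raises(ValueError, match="variance"):
        paired_t(z1, z1)
    with pytest.raises(ValueError, match="length"):
        paired_t(z1, z1[:2])


def test_one_sample_type_I_error_calibrated(rng):
    """Nominal 5% one-tailed rejection rate on null normal draws."""
    reps, n = 2000, 17
    data = rng.normal(size=(reps, n))
    mean = data.mean(1)
    sd = data.std(1, ddof=1)
    t = mean / (sd / np.sqrt(n))
    from scipy import stats as sps

    crit = sps.t.ppf(0.95, n - 1)
    rate = (t > crit).mean()
    assert abs(rate - 0.05) < 0.015


def test_adjust_alpha_reported_thresholds():
    assert adjust_alpha(0.05, 6) == 0.008
    assert adjust_alpha(0.05, 3) == 0.017
    assert adjust_alpha(0.05, 4) == 0.013  # 0.0125 rounds half-up
    assert adjust_alpha(0.05, 5) == 0.010
    assert adjust_alpha(0.05, 1) == 0.050
    with pytest.raises(ValueError):
        adjust_alpha(0.05, 0)


def test_percent_correct_rounding():
    assert percent_correct(35, 36) == 97
    assert percent_correct(36, 36) == 100
    assert percent_correct(0, 36) == 0
    with pytest.raises(ValueError):
        percent_correct(5, 0)


# ------------------------------------------------------------ noise ceiling

def test_noise_ceiling_identical_subjects_clamped(space, rng):
    vals = rng.normal(size=space.n_pairs)
    rdms = [RDM(values=vals.copy(), space=space) for _ in range(4)]
    mask = cell_mask(space, "within_modality_combined")
    nc = noise_ceiling(rdms, mask)
    assert nc.lower == pytest.approx(nc.upper)
    assert np.isfinite(nc.lower)


def test_noise_ceiling_needs_three_subjects(space, rng):
    rdms = [RDM(values=rng.normal(size=space.n_pairs), space=space)
            for _ in range(2)]
    with pytest.raises(ValueError, match="3 subjects"):
        noise_ceiling(rdms, cell_mask(space, "across_modality"))


def test_noise_ceiling_pure_noise_near_zero(space, rng):
    mask = cell_mask(space, "within_modality_combined")
    lows = []
    for _ in range(50):
        rdms = [RDM(values=rng.normal(size=space.n_pairs), space=space)
                for _ in range(6)]
        lows.append(noise_ceiling(rdms, mask).lower)
    se = np.std(lows, ddof=1) / np.sqrt(len(lows))
    assert abs(np.mean(lows)) < 3 * se + 0.01


# ------------------------------------------------------------------ verdict

def test_classify_region_patterns():
    assert classify_region(
        {"category_within": 0.001, "category_across": 0.01}, 0.05
    ) == "shared-semantic"
    assert classify_region(
        {"item_speech": 0.001, "identity_speech": 0.01,
         "category_across": 0.4}, 0.05
    ) == "modality-form"
    assert classify_region({"category_within": 0.2}, 0.05) == "none"


def test_fit_models_in_region_table_shapes(space, norms, rng):
    models = standard_model_set(space, norms)
    # synthetic subject RDMs with planted category structure within+across
    from crossmodal_rsa.conditions import same_category_cells, same_item_cells

    base = np.where(same_category_cells(space), 0.2, 1.0)
    rdms = [RDM(values=base + 0.2 * rng.normal(size=space.n_pairs),
                space=space) for _ in range(8)]
    fit = fit_models_in_region(rdms, models, region="test", alpha=0.05)
    assert len(fit.fits) == 8 * len(models)
    assert set(fit.group["model_key"]) == set(models)
    assert fit.verdict == "shared-semantic"
    assert not fit.paired.empty
    for nc in fit.ceilings.values():
        assert nc.lower <= nc.upper + 1e-9
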