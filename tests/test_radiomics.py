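"""First-order statistics, GLCM construction, and Haralick features."""

import numpy as np
import pytest

from nigrascan.radiomics import (DIRECTIONS_3D, GLCM, TEXTURE_FEATURES,
                                 compute_glcm, discretize, extract_feature_vector,
                                 first_order, mri_feature_names, second_order)
from oracles import brute_force_glcm, brute_force_haralick


def test_discretize_binary_and_affine_invariance():
    levels, const = discretize(np.array([0.0, 1.0]), n_levels=2)
    assert not const and list(levels) == [0, 1]
    vals = np.random.default_rng(0).uniform(size=30)
    base, _ = discretize(vals, 8)
    shifted, _ = discretize(3.0 * vals + 11.0, 8)
    np.testing.assert_array_equal(base, shifted)


def test_discretize_constant_flagged():
    levels, const = discretize(np.full(5, 2.2), n_levels=4)
    assert const and (levels == 0).all()
    with pytest.raises(ValueError):
        discretize(np.array([0.0, 1.0]), n_levels=1)


def test_glcm_constant_patch_single_entry():
    vol = np.full((2, 2, 1), 7.0)
    glcm = compute_glcm(vol, np.ones((2, 2, 1), bool), n_levels=4)
    assert glcm.matrix[0, 0] == 1.0
    assert glcm.matrix.sum() == pytest.approx(1.0)


def test_glcm_alternating_strip():
    """{0,1,0,1} along one axis: mass only at (0,1) and (1,0), 0.5 each."""
    vol = np.array([0.0, 1.0, 0.0, 1.0]).reshape(4, 1, 1)
    mask = np.ones((4, 1, 1), dtype=bool)
    glcm = compute_glcm(vol, mask, n_levels=2, distance=1,
                        directions=[(1, 0, 0)])
    expected = np.array([[0.0, 0.5], [0.5, 0.0]])
    np.testing.assert_allclose(glcm.matrix, expected)


def test_glcm_respects_mask():
    vol = np.array([0.0, 1.0, 0.0, 1.0]).reshape(4, 1, 1)
    mask = np.zeros((4, 1, 1), dtype=bool)
    mask[:2] = True  # only the first pair
    glcm = compute_glcm(vol, mask, n_levels=2, distance=1,
                        directions=[(1, 0, 0)])
    oracle = brute_force_glcm(vol, mask, 2, 1, [(1, 0, 0)])
    np.testing.assert_allclose(glcm.matrix, oracle)
    np.testing.assert_allclose(glcm.matrix, [[0, 0.5], [0.5, 0]])


def test_glcm_no_pairs_is_an_error():
    vol = np.zeros((3, 3, 1))
    mask = np.zeros((3, 3, 1), dtype=bool)
    mask[0, 0, 0] = True
    mask[2, 2, 0] = True  # no neighbours at distance 1
    with pytest.raises(ValueError, match="pair"):
        compute_glcm(vol, mask, n_levels=2, distance=1, directions=[(1, 0, 0)])


@pytest.mark.parametrize("seed", range(6))
def test_glcm_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 6, size=2)) + (rng.integers(1, 4),)
    vol = rng.uniform(size=shape)
    mask = rng.uniform(size=shape) < 0.7
    mask.ravel()[:2] = True
    glcm = compute_glcm(vol, mask, n_levels=5, distance=1)
    oracle = brute_force_glcm(vol, mask, 5, 1, DIRECTIONS_3D)
    np.testing.assert_allclose(glcm.matrix, oracle, atol=1e-12)
    feats = second_order(glcm)[:4]
    np.testing.assert_allclose(feats, brute_force_haralick(glcm.matrix),
                               atol=1e-12)


def test_first_order_closed_forms():
    mean, skew, kurt = first_order(np.array([-1.0, -1.0, 1.0, 1.0]))
    assert (mean, skew, kurt) == (0.0, 0.0, 1.0)
    assert first_order(np.array([1.0, 2.0, 3.0]))[1] == pytest.approx(0.0)


def test_first_order_normal_kurtosis_near_three():
    draws = np.random.default_rng(10).standard_normal(1_000_000)
    assert first_order(draws)[2] == pytest.approx(3.0, abs=0.02)


def test_first_order_degenerate_and_small_inputs():
    mean, skew, kurt = first_order(np.full(5, 3.3))
    assert mean == pytest.approx(3.3) and np.isnan(skew) and np.isnan(kurt)
    with pytest.raises(ValueError):
        first_order(np.array([1.0, 2.0]))


def test_second_order_hand_computed_examples():
    contrast, corr, energy, homog, degen = second_order(
        GLCM(np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 0]]), 3, 1, ()))
    assert (contrast, corr, energy, homog, degen) == (0.0, 0.0, 1.0, 1.0, True)

    two = GLCM(np.array([[0.0, 0.5], [0.5, 0.0]]), 2, 1, ())
    contrast, corr, energy, homog, degen = second_order(two)
    assert contrast == pytest.approx(1.0)
    assert corr == pytest.approx(-1.0)
    assert energy == pytest.approx(0.5)
    assert homog == pytest.approx(0.5)
    assert not degen

    n = 4
    uniform = GLCM(np.full((n, n), 1.0 / n ** 2), n, 1, ())
    assert second_order(uniform)[2] == pytest.approx(1.0 / n ** 2)


def test_second_order_requires_normalized_input():
    with pytest.raises(ValueError, match="normalized"):
        second_order(GLCM(np.ones((2, 2)), 2, 1, ()))


@pytest.mark.parametrize("seed", range(8))
def test_feature_bounds_on_random_patches(seed):
    rng = np.random.default_rng(100 + seed)
    vol = rng.uniform(size=(5, 5, 3))
    mask = rng.uniform(size=(5, 5, 3)) < 0.8
    mask[:2, :2, 0] = True
    glcm = compute_glcm(vol, mask, n_levels=6)
    np.testing.assert_allclose(glcm.matrix, glcm.matrix.T)  # symmetry
    assert glcm.matrix.sum() == pytest.approx(1.0)
    contrast, corr, energy, homog, _ = second_order(glcm)
    assert contrast >= 0
    assert -1 <= corr <= 1
    assert 0 < energy <= 1
    assert 0 < homog <= 1
    _, _, kurt = first_order(vol[mask])
    assert kurt >= 1


def test_rotation_consistency_in_plane():
    """90-degree in-plane rotation leaves direction-pooled features unchanged."""
    rng = np.random.default_rng(11)
    vol = rng.uniform(size=(6, 6, 3))
    mask = rng.uniform(size=(6, 6, 3)) < 0.75
    mask[0, 0, :] = True
    base = compute_glcm(vol, mask, n_levels=5)
    rot = compute_glcm(np.rot90(vol, axes=(0, 1)), np.rot90(mask, axes=(0, 1)),
                       n_levels=5)
    np.testing.assert_allclose(second_order(base)[:4], second_order(rot)[:4],
                               atol=1e-12)


def test_extract_feature_vector_counts_and_names(mri_stage):
    subj = mri_stage["cohort"][0].subject_id
    feats = extract_feature_vector(mri_stage["nm_maps"][subj],
                                   mri_stage["t2_maps"][subj],
                                   mri_stage["vois"])
    assert list(feats) == mri_feature_names()
    n_texture = sum(1 for name in feats
                    if name.rsplit("-", 1)[1] in TEXTURE_FEATURES)
    assert n_texture == 48
    assert sum(1 for n in feats if n.endswith("-Vol")) == 2
    assert sum(1 for n in feats if n.endswith("-Mean")) == 8
    assert all(np.isfinite(v) for v in feats.values())


def test_extract_feature_vector_nm_mean_near_calibration(mri_stage):
    """Control subjects' normalized SN signal sits near the configured 1.45."""
    controls = mri_stage["controls"]
    means = [extract_feature_vector(mri_stage["nm_maps"][s],
                                    mri_stage["t2_maps"][s],
                                    mri_stage["vois"])["Neuromelanin-SN-L-Mean"]
             for s in controls]
    assert np.mean(means) == pytest.approx(1.45, abs=0.06)


def test_extract_feature_vector_symmetric_subject():
    """Noise-free phantom with mirror-symmetric anatomy gives equal L/R values."""
    from nigrascan import phantom
    from nigrascan.relaxometry import (extract_neuromelanin, fit_t2star,
                                       normalize_neuromelanin)
    from nigrascan.voi import VOISet
    spec = phantom.CohortSpec(n_per_group={"PD": 0, "NMC": 0, "NMNC": 1},
                              noise_sd=0.0, contrast_jitter=0.0,
                              size_jitter=0.0, t2_jitter=0.0, seed=0)
    subj = phantom.generate_cohort(spec)[0]
    vol, _, ref = phantom.generate_multiecho_phantom(spec, subj)
    nm = normalize_neuromelanin(extract_neuromelanin(vol), ref)
    t2 = fit_t2star(vol)
    gt = phantom.ground_truth_masks(spec)
    vois = VOISet(masks={"NM-SN-L": gt["SN-L"], "NM-SN-R": gt["SN-R"],
                         "T2*-SN-L": gt["SN-iron-L"], "T2*-SN-R": gt["SN-iron-R"],
                         "T2*-RN-L": gt["RN-L"], "T2*-RN-R": gt["RN-R"]},
                  voxel_size=spec.voxel_size)
    feats = extract_feature_vector(nm, t2, vois)
    for prefix_l, prefix_r in [("Neuromelanin-SN-L", "Neuromelanin-SN-R"),
                               ("T2*-SN-L", "T2*-SN-R"),
                               ("T2*-RN-L", "T2*-RN-R")]:
        for suffix in ("Mean",) + TEXTURE_FEATURES:
            l = feats.get(f"{prefix_l}-{suffix}")
            r = feats.get(f"{prefix_r}-{suffix}")
            # noise-free constant-T2* VOIs make shape statistics NaN on both sides
            assert l == pytest.approx(r, rel=1e-9, nan_ok=True), f"{prefix_l}-{suffix}"


def test_extract_feature_vector_missing_voi(mri_stage):
    from nigrascan.voi import VOISet
    subj = mri_stage["cohort"][0].subject_id
    partial = VOISet(masks={"NM-SN-L": mri_stage["vois"].masks["NM-SN-L"]},
                     voxel_size=(0.6, 0.6, 1.3))
    with pytest.raises(ValueError, match="NM-SN-R"):
        extract_feature_vector(mri_stage["nm_maps"][subj],
                               mri_stage["t2_maps"][subj], partial)
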