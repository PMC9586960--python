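"""The synthetic cohort generator: determinism, effect directions, calibration."""

import numpy as np
import pandas as pd
import pytest

from nigrascan import phantom
from nigrascan.cohort_defaults import (GROUP_DIFFERENTIATED_MRI_FEATURES,
                                       default_feature_stats)
from nigrascan.datspect import SBR_COLUMNS
from nigrascan.phantom import DAT_LABELS, CohortSpec, SubjectRecord
from nigrascan.radiomics import mri_feature_names


def _subject(group, index=0, lr=None):
    geno = {"PD": "iPD", "NMC": "LRRK2", "NMNC": "none"}[group]
    return SubjectRecord(subject_id=f"sub-{index:03d}", group=group,
                         genotype=geno, age=60.0, sex="M", lr_score=lr,
                         index=index)


@pytest.mark.parametrize("counts,total", [
    ({"PD": 46, "NMC": 47, "NMNC": 34}, 127),
    ({"PD": 1, "NMC": 0, "NMNC": 1}, 2),
])
def test_cohort_counts_propagate(counts, total):
    cohort = phantom.generate_cohort(CohortSpec(n_per_group=counts, seed=4))
    assert len(cohort) == total
    by_group = pd.Series([c.group for c in cohort]).value_counts().to_dict()
    assert {g: by_group.get(g, 0) for g in counts} == counts


def test_cohort_record_invariants():
    cohort = phantom.generate_cohort(
        CohortSpec(n_per_group={"PD": 10, "NMC": 10, "NMNC": 10}, seed=5))
    for r in cohort:
        if r.group == "PD":
            assert r.lr_score is None
        else:
            assert r.lr_score is not None and r.lr_score >= 0
        if r.genotype == "iPD":
            assert r.group == "PD"
        if r.genotype == "none":
            assert r.group == "NMNC"


def test_lr_scores_right_skewed_with_high_tail():
    spec = CohortSpec(n_per_group={"PD": 0, "NMC": 400, "NMNC": 0}, seed=6)
    lr = np.array([r.lr_score for r in phantom.generate_cohort(spec)])
    assert np.median(lr) < lr.mean()  # right skew
    frac_high = (lr > 50).mean()
    assert 0.05 < frac_high < 0.25  # configurable tail around 6/47


def test_cohort_determinism():
    spec = CohortSpec(n_per_group={"PD": 5, "NMC": 5, "NMNC": 5}, seed=9)
    assert phantom.generate_cohort(spec) == phantom.generate_cohort(spec)


def test_invalid_group_count_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_per_group={"PD": -1, "NMC": 0, "NMNC": 1})
    with pytest.raises(ValueError):
        CohortSpec(n_per_group={"XX": 1})


def test_effect_direction_is_a_spec_invariant():
    params = dict(phantom.DEFAULT_GROUP_PARAMS)
    params["PD"] = phantom.GroupTissueParams(sn_contrast=1.4, sn_t2star=40.0,
                                             rn_t2star=26.0)
    with pytest.raises(ValueError):
        CohortSpec(group_params=params)


def test_multiecho_signal_equation_noiseless():
    """WM voxel intensities follow S0*exp(-TE/T2*) exactly without noise."""
    spec = CohortSpec(n_per_group={"PD": 0, "NMC": 0, "NMNC": 1}, noise_sd=0.0,
                      contrast_jitter=0.0, size_jitter=0.0, t2_jitter=0.0, seed=0)
    subj = phantom.generate_cohort(spec)[0]
    vol, midbrain, reference = phantom.generate_multiecho_phantom(spec, subj)
    ref_vox = np.argwhere(reference)[0]
    for e, te in enumerate(spec.echo_times):
        expected = spec.wm.s0 * np.exp(-te / spec.wm.t2star)
        assert vol.data[(e, *ref_vox)] == pytest.approx(expected, rel=1e-12)


def test_pd_sn_first_echo_lower_than_control():
    spec = CohortSpec(n_per_group={"PD": 1, "NMC": 0, "NMNC": 1}, seed=21)
    pd_subj = _subject("PD", index=7)
    ctrl = _subject("NMNC", index=7, lr=5.0)  # same index -> same noise stream
    vol_pd, _, _ = phantom.generate_multiecho_phantom(spec, pd_subj)
    vol_ct, _, _ = phantom.generate_multiecho_phantom(spec, ctrl)
    gt = phantom.ground_truth_masks(spec, "PD")
    sn = gt["SN-L"] | gt["SN-R"]
    assert vol_pd.data[0][sn].mean() < vol_ct.data[0][sn].mean()


def test_midbrain_and_reference_masks_disjoint():
    spec = CohortSpec(n_per_group={"PD": 0, "NMC": 0, "NMNC": 1}, seed=3)
    subj = phantom.generate_cohort(spec)[0]
    _, midbrain, reference = phantom.generate_multiecho_phantom(spec, subj)
    assert not (midbrain & reference).any()
    assert midbrain.any() and reference.any()


def test_multiecho_determinism():
    spec = CohortSpec(n_per_group={"PD": 1, "NMC": 0, "NMNC": 0}, seed=13)
    subj = phantom.generate_cohort(spec)[0]
    a, _, _ = phantom.generate_multiecho_phantom(spec, subj)
    b, _, _ = phantom.generate_multiecho_phantom(spec, subj)
    np.testing.assert_array_equal(a.data, b.data)


# --- DAT-SPECT phantom ------------------------------------------------------


def test_datspect_ratio_exact_without_noise():
    """Configured L-putamen SBR 3.38 puts putamen voxels at 4.38x occipital."""
    stats = {col: {g: (mu, 0.0) for g, (mu, sd) in by_group.items()}
             for col, by_group in CohortSpec().sbr_stats.items()}
    spec = CohortSpec(n_per_group={"PD": 0, "NMC": 0, "NMNC": 1},
                      dat_noise_sd=0.0, sbr_stats=stats, seed=0)
    subj = phantom.generate_cohort(spec)[0]
    up = phantom.generate_datspect_phantom(spec, subj)
    occ_mean = up.values[up.label_map == DAT_LABELS["occipital"]].mean()
    putamen = up.values[up.label_map == DAT_LABELS["putamen-L"]]
    assert np.allclose(putamen / occ_mean, 1.0 + 3.38)


def test_datspect_pd_putamen_lower_and_background_cold():
    spec = CohortSpec(n_per_group={"PD": 1, "NMC": 0, "NMNC": 1}, seed=17)
    up_pd = phantom.generate_datspect_phantom(spec, _subject("PD", index=4))
    up_ct = phantom.generate_datspect_phantom(spec, _subject("NMNC", index=4, lr=2.0))
    put = up_pd.label_map == DAT_LABELS["putamen-L"]
    assert up_pd.values[put].mean() < up_ct.values[put].mean()
    occ = up_ct.values[up_ct.label_map == DAT_LABELS["occipital"]].mean()
    background = up_ct.values[up_ct.label_map == DAT_LABELS["background"]]
    assert (background / occ < 1.65).all()  # below every VOI threshold
    assert (up_ct.label_map == DAT_LABELS["occipital"]).any()


# --- feature-level fast path ------------------------------------------------


def test_feature_table_columns_match_extraction_names():
    spec = CohortSpec(n_per_group={"PD": 2, "NMC": 2, "NMNC": 2}, seed=1)
    table = phantom.generate_feature_table(spec)
    expected = list(phantom.METADATA_COLUMNS) + mri_feature_names() + list(SBR_COLUMNS)
    assert list(table.columns) == expected
    assert len(mri_feature_names()) == 58


def test_feature_table_group_means_calibrated():
    """Large-sample NMNC means match the configured values within 3 SE."""
    spec = CohortSpec(n_per_group={"PD": 0, "NMC": 0, "NMNC": 20000}, seed=2)
    table = phantom.generate_feature_table(spec)
    stats = default_feature_stats()
    for feat in ["Neuromelanin-SN-L-Mean", "L-PuSBR", "Brainstem-SBR"]:
        mu, sd = stats[feat]["NMNC"]
        se = sd / np.sqrt(len(table))
        assert abs(table[feat].mean() - mu) < 3 * se


def test_feature_table_effect_directions_preserved():
    spec = CohortSpec(n_per_group={"PD": 1000, "NMC": 0, "NMNC": 1000}, seed=8)
    table = phantom.generate_feature_table(spec)
    stats = default_feature_stats()
    grouped = table.groupby("group")
    for feat in list(GROUP_DIFFERENTIATED_MRI_FEATURES) + list(SBR_COLUMNS):
        configured = stats[feat]["PD"][0] - stats[feat]["NMNC"][0]
        observed = grouped[feat].mean()["PD"] - grouped[feat].mean()["NMNC"]
        assert np.sign(observed) == np.sign(configured)


def test_feature_table_zero_sd_gives_constant_column():
    stats = default_feature_stats()
    stats["L-PuSBR"] = {g: (2.5, 0.0) for g in ("PD", "NMC", "NMNC")}
    spec = CohortSpec(n_per_group={"PD": 3, "NMC": 0, "NMNC": 3}, seed=1)
    table = phantom.generate_feature_table(spec, feature_stats=stats)
    assert (table["L-PuSBR"] == 2.5).all()


def test_feature_table_negative_sd_rejected():
    stats = default_feature_stats()
    stats["L-PuSBR"]["PD"] = (2.5, -1.0)
    spec = CohortSpec(n_per_group={"PD": 3, "NMC": 0, "NMNC": 3}, seed=1)
    with pytest.raises(ValueError, match="negative SD"):
        phantom.generate_feature_table(spec, feature_stats=stats)


def test_feature_table_deterministic():
    spec = CohortSpec(n_per_group={"PD": 4, "NMC": 4, "NMNC": 4}, seed=31)
    a = phantom.generate_feature_table(spec)
    b = phantom.generate_feature_table(spec)
    pd.testing.assert_frame_equal(a, b)
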