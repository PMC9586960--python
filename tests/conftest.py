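import numpy as np
import pytest

from nigrascan import phantom, relaxometry, voi


@pytest.fixture(scope="session")
def small_spec():
    """A small but fully featured cohort: 3 PD + 6 controls."""
    return phantom.CohortSpec(n_per_group={"PD": 3, "NMC": 0, "NMNC": 6}, seed=11)


@pytest.fixture(scope="session")
def mri_stage(small_spec):
    """Cohort maps, control templates and the six MRI VOIs, computed once."""
    spec = small_spec
    cohort = phantom.generate_cohort(spec)
    nm_maps, t2_maps, midbrains = {}, {}, {}
    for subj in cohort:
        vol, midbrain, reference = phantom.generate_multiecho_phantom(spec, subj)
        nm = relaxometry.normalize_neuromelanin(
            relaxometry.extract_neuromelanin(vol), reference,
            voxel_size=spec.voxel_size)
        nm_maps[subj.subject_id] = nm
        t2_maps[subj.subject_id] = relaxometry.fit_t2star(vol)
        midbrains[subj.subject_id] = midbrain

    controls = [s.subject_id for s in cohort if s.group == "NMNC"]
    nm_template = voi.build_population_template(
        [nm_maps[s].values for s in controls], [midbrains[s] for s in controls])
    t2_template = voi.build_population_template(
        [np.where(t2_maps[s].valid_mask, t2_maps[s].values, np.nan)
         for s in controls],
        [midbrains[s] for s in controls])

    nm_labels = voi.kmeans_segment(nm_template, np.isfinite(nm_template),
                                   k=3, seed=0)
    t2_labels = voi.kmeans_segment(t2_template, np.isfinite(t2_template),
                                   k=3, seed=0)
    nm_vois = voi.define_nm_vois(nm_labels, nm_template,
                                 voxel_size=spec.voxel_size)
    t2_vois = voi.define_t2star_vois(t2_labels, t2_template,
                                     voxel_size=spec.voxel_size)
    merged = voi.VOISet(masks={**nm_vois.masks, **t2_vois.masks},
                        voxel_size=spec.voxel_size)
    return {
        "spec": spec, "cohort": cohort, "nm_maps": nm_maps, "t2_maps": t2_maps,
        "midbrains": midbrains, "controls": controls,
        "nm_template": nm_template, "t2_template": t2_template,
        "nm_labels": nm_labels, "t2_labels": t2_labels,
        "nm_vois": nm_vois, "t2_vois": t2_vois, "vois": merged,
        "ground_truth": phantom.ground_truth_masks(spec),
    }
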