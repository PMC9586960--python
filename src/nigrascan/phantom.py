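"""Synthetic midbrain and striatal phantoms for pipeline testing.

The generator emulates a pre-aligned study of three groups — symptomatic
Parkinson's disease (PD), non-manifesting mutation carriers (NMC) and
non-manifesting non-carriers (NMNC) — at three levels of realism:

* :func:`generate_cohort` — subject metadata (group, genotype, age, sex and a
  right-skewed prodromal likelihood-ratio score for the non-PD groups);
* :func:`generate_multiecho_phantom` / :func:`generate_datspect_phantom` —
  voxel data: a multi-echo gradient-echo midbrain with bilateral
  neuromelanin-hyperintense, short-T2* substantia nigra (SN) ellipsoids and
  short-T2* red nuclei (RN), plus a striatal uptake volume normalized
  against an occipital reference;
* :func:`generate_feature_table` — a fast path that draws the final 58 MRI +
  7 SBR feature columns directly as per-group Gaussians.

All randomness derives from ``spec.seed`` via independent per-subject
streams, so identical specs give bit-identical outputs.  Anatomy is
schematic (axis-aligned ellipsoids in a box): only the contrast
relationships between tissues matter for testing the downstream algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_defaults import GROUPS, SBR_GROUP_STATS, default_feature_stats
from .datspect import SBR_COLUMNS
from .radiomics import mri_feature_names
from .relaxometry import (DEFAULT_ECHO_TIMES, DEFAULT_VOXEL_SIZE,
                          MultiEchoVolume)

__all__ = [
    "SubjectRecord",
    "TissueSignal",
    "GroupTissueParams",
    "CohortSpec",
    "UptakeVolume",
    "DAT_LABELS",
    "generate_cohort",
    "generate_multiecho_phantom",
    "generate_datspect_phantom",
    "generate_feature_table",
    "ground_truth_masks",
    "cohort_to_frame",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("subject_id", "group", "genotype", "age", "sex", "lr_score")

#: anatomical labels of the DAT-SPECT phantom label map
DAT_LABELS = {
    "background": 0,
    "caudate-L": 1, "caudate-R": 2,
    "putamen-L": 3, "putamen-R": 4,
    "pallidum-L": 5, "pallidum-R": 6,
    "brainstem": 7,
    "occipital": 8,
}


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic participant."""

    subject_id: str
    group: str  # PD | NMC | NMNC
    genotype: str  # LRRK2 | GBA | iPD | none
    age: float  # years
    sex: str  # M | F
    lr_score: float | None  # prodromal likelihood ratio; None for PD
    index: int = 0  # stable cohort position, seeds the subject's RNG stream

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.genotype == "iPD" and self.group != "PD":
            raise ValueError("genotype iPD is only valid for the PD group")
        if self.genotype == "none" and self.group != "NMNC":
            raise ValueError("genotype 'none' is only valid for the NMNC group")
        has_lr = self.lr_score is not None
        if has_lr != (self.group in ("NMC", "NMNC")):
            raise ValueError("lr_score must be present iff group is NMC or NMNC")


@dataclass(frozen=True)
class TissueSignal:
    """Mono-exponential signal parameters of one tissue class."""

    s0: float  # first proton-density-weighted intensity, a.u.
    t2star: float  # ms


@dataclass(frozen=True)
class GroupTissueParams:
    """Group-dependent midbrain parameters.

    ``sn_contrast`` multiplies the white-matter S0 inside the SN (the
    neuromelanin hyperintensity, and — after white-matter normalization —
    the expected normalized SN signal); ``sn_size_scale`` scales the SN
    ellipsoid semi-axes (neuromelanin extent loss in PD).
    """

    sn_contrast: float
    sn_t2star: float  # ms
    rn_t2star: float  # ms
    sn_size_scale: float = 1.0


DEFAULT_GROUP_PARAMS = {
    # PD: reduced NM contrast and extent, shortened T2* inside the SN
    "PD": GroupTissueParams(sn_contrast=1.37, sn_t2star=28.04, rn_t2star=26.0,
                            sn_size_scale=0.88),
    "NMC": GroupTissueParams(sn_contrast=1.43, sn_t2star=30.0, rn_t2star=26.0,
                             sn_size_scale=0.97),
    "NMNC": GroupTissueParams(sn_contrast=1.45, sn_t2star=30.67, rn_t2star=26.0,
                              sn_size_scale=1.0),
}

_AGE_STATS = {"PD": (62.3, 10.0), "NMC": (51.5, 8.3), "NMNC": (53.5, 10.6)}
_MALE_FRACTION = {"PD": 31 / 46, "NMC": 25 / 47, "NMNC": 14 / 34}


@dataclass(frozen=True)
class CohortSpec:
    """Everything the generator needs to produce one synthetic study."""

    n_per_group: dict = field(default_factory=lambda: {"PD": 46, "NMC": 47, "NMNC": 34})
    grid_shape: tuple = (54, 44, 16)
    voxel_size: tuple = DEFAULT_VOXEL_SIZE  # mm
    echo_times: tuple = DEFAULT_ECHO_TIMES  # ms
    group_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    wm: TissueSignal = TissueSignal(s0=100.0, t2star=45.0)
    csf: TissueSignal = TissueSignal(s0=60.0, t2star=80.0)
    background: TissueSignal = TissueSignal(s0=15.0, t2star=20.0)
    noise_sd: float = 1.0  # additive Gaussian, intensity units
    contrast_jitter: float = 0.03  # per-subject fractional SD of SN contrast
    size_jitter: float = 0.03  # per-subject fractional SD of SN size scale
    t2_jitter: float = 0.8  # per-subject SD of SN/RN T2*, ms
    frac_high_lr: dict = field(default_factory=lambda: {"NMC": 6 / 47, "NMNC": 1 / 34})
    # DAT-SPECT phantom
    dat_grid_shape: tuple = (40, 48, 20)
    dat_voxel_size: tuple = (2.0, 2.0, 2.0)  # mm
    occipital_uptake: float = 10.0
    dat_noise_sd: float = 0.02  # in occipital-ratio units
    sbr_stats: dict = field(default_factory=lambda: {
        col: {"PD": SBR_GROUP_STATS[col]["PD"],
              "NMC": SBR_GROUP_STATS[col]["NMNC"],
              "NMNC": SBR_GROUP_STATS[col]["NMNC"]}
        for col in SBR_COLUMNS})
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r} in n_per_group")
            if int(n) != n or n < 0:
                raise ValueError("group counts must be nonnegative integers")
        tes = np.asarray(self.echo_times, dtype=float)
        if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        if self.noise_sd < 0 or self.dat_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        pd_t2 = self.group_params["PD"].sn_t2star
        ctrl_t2 = self.group_params["NMNC"].sn_t2star
        if pd_t2 > ctrl_t2:
            raise ValueError("PD SN T2* must not exceed the NMNC SN T2* "
                             "(simulated effect direction)")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_group.values()))


@dataclass(frozen=True)
class UptakeVolume:
    """DAT-SPECT phantom: nonnegative uptake plus an anatomical label map."""

    values: np.ndarray
    voxel_size: tuple
    label_map: np.ndarray  # integers per DAT_LABELS


# ---------------------------------------------------------------------------
# cohort metadata


def _rng(spec: CohortSpec, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF,
                                                         *stream]))


def _draw_lr(rng: np.random.Generator, frac_high: float) -> float:
    """Right-skewed LR score: lognormal bulk with a configurable tail > 50."""
    if rng.uniform() < frac_high:
        return float(rng.uniform(51.0, 110.0))
    return float(min(rng.lognormal(mean=1.6, sigma=1.0), 49.0))


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw the subject metadata table. Deterministic for a fixed seed."""
    rng = _rng(spec, 0)
    records: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        n = int(spec.n_per_group.get(group, 0))
        if group == "PD":
            genos = ["LRRK2", "GBA", "iPD"]
        elif group == "NMC":
            genos = ["LRRK2", "GBA"]
        else:
            genos = ["none"]
        mu, sd = _AGE_STATS[group]
        for i in range(n):
            age = float(np.clip(rng.normal(mu, sd), 40.0, 80.0))
            sex = "M" if rng.uniform() < _MALE_FRACTION[group] else "F"
            lr = None
            if group in ("NMC", "NMNC"):
                lr = _draw_lr(rng, spec.frac_high_lr.get(group, 0.0))
            records.append(SubjectRecord(
                subject_id=f"sub-{idx + 1:03d}", group=group,
                genotype=genos[i % len(genos)], age=age, sex=sex,
                lr_score=lr, index=idx))
            idx += 1
    return records


def cohort_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Metadata records as a DataFrame with the standard columns."""
    return pd.DataFrame([{c: getattr(r, c) for c in METADATA_COLUMNS}
                         for r in records])


# ---------------------------------------------------------------------------
# midbrain MRI phantom geometry (voxel units)

_SN_CENTER_OFFSET = (8.0, 20.0, 6.5)  # (|x - midline|, y, z)
_SN_SEMI_AXES = (5.0, 7.0, 3.1)
# iron-rich SN compartment: medially shifted and slightly smaller than the
# neuromelanin extent, so NM-defined and T2*-defined SN VOIs overlap only
# partially (as they do in vivo)
_SN_IRON_CENTER_OFFSET = (6.5, 20.0, 6.5)
_SN_IRON_SCALE = 0.92
_RN_CENTER_OFFSET = (3.5, 29.5, 10.0)
_RN_SEMI_AXES = (2.5, 3.2, 2.2)
_AQUEDUCT_CENTER = (0.0, 33.0, 8.0)
_AQUEDUCT_SEMI_AXES = (1.5, 2.5, 5.5)
_MIDBRAIN_BOX = ((6, 48), (8, 38), (2, 14))
_HEAD_BOX = ((2, 52), (2, 42), (1, 15))


def _ellipsoid(shape: tuple, center: tuple, semi_axes: tuple) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _box(shape: tuple, bounds: tuple) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(slice(lo, hi) for lo, hi in bounds)] = True
    return mask


def _bilateral(shape, center_offset, semi_axes):
    mid = (shape[0] - 1) / 2.0
    dx, y, z = center_offset
    left = _ellipsoid(shape, (mid - dx, y, z), semi_axes)
    right = _ellipsoid(shape, (mid + dx, y, z), semi_axes)
    return left, right


def ground_truth_masks(spec: CohortSpec, group: str = "NMNC",
                       size_scale: float | None = None) -> dict[str, np.ndarray]:
    """Nominal SN/RN ellipsoid masks for a group (segmentation ground truth)."""
    shape = spec.grid_shape
    scale = spec.group_params[group].sn_size_scale if size_scale is None else size_scale
    sn_axes = tuple(a * scale for a in _SN_SEMI_AXES)
    # the iron-rich compartment does not shrink with the neuromelanin extent:
    # disease shortens its T2* but iron accumulates rather than recedes
    iron_axes = tuple(a * _SN_IRON_SCALE for a in _SN_SEMI_AXES)
    sn_l, sn_r = _bilateral(shape, _SN_CENTER_OFFSET, sn_axes)
    fe_l, fe_r = _bilateral(shape, _SN_IRON_CENTER_OFFSET, iron_axes)
    rn_l, rn_r = _bilateral(shape, _RN_CENTER_OFFSET, _RN_SEMI_AXES)
    return {"SN-L": sn_l, "SN-R": sn_r, "RN-L": rn_l, "RN-R": rn_r,
            "SN-iron-L": fe_l, "SN-iron-R": fe_r}


def generate_multiecho_phantom(spec: CohortSpec, subject: SubjectRecord):
    """Simulate one subject's multi-echo midbrain acquisition.

    Voxel signal is ``S0(tissue) * exp(-TE / T2*(tissue))`` plus additive
    Gaussian noise.  SN voxels carry elevated first-echo signal (neuromelanin
    hyperintensity) and shortened T2*; RN voxels carry shortened T2* only.
    Per-subject jitter perturbs SN contrast, extent and T2* around the group
    values.

    Returns
    -------
    (MultiEchoVolume, midbrain_mask, reference_wm_mask)
        The rostral-midbrain working mask and a disjoint normal-appearing
        white-matter reference mask.
    """
    shape = spec.grid_shape
    gp = spec.group_params[subject.group]
    rng = _rng(spec, 1, subject.index)
    contrast = gp.sn_contrast * (1.0 + spec.contrast_jitter * rng.standard_normal())
    scale = gp.sn_size_scale * (1.0 + spec.size_jitter * rng.standard_normal())
    sn_t2 = max(gp.sn_t2star + spec.t2_jitter * rng.standard_normal(), 5.0)
    rn_t2 = max(gp.rn_t2star + spec.t2_jitter * rng.standard_normal(), 5.0)

    gt = ground_truth_masks(spec, subject.group, size_scale=scale)
    sn = gt["SN-L"] | gt["SN-R"]
    sn_iron = gt["SN-iron-L"] | gt["SN-iron-R"]
    rn = gt["RN-L"] | gt["RN-R"]
    if ((sn | sn_iron) & rn).any():
        raise ValueError("phantom geometry error: SN and RN ellipsoids overlap")
    aqueduct = _ellipsoid(shape, ((shape[0] - 1) / 2.0 + _AQUEDUCT_CENTER[0],
                                  _AQUEDUCT_CENTER[1], _AQUEDUCT_CENTER[2]),
                          _AQUEDUCT_SEMI_AXES)
    midbrain = _box(shape, _MIDBRAIN_BOX)
    head = _box(shape, _HEAD_BOX)
    reference = head & ~midbrain
    if (midbrain & reference).any():
        raise ValueError("reference mask must exclude the rostral midbrain area")

    s0 = np.full(shape, spec.background.s0)
    t2 = np.full(shape, spec.background.t2star)
    s0[head] = spec.wm.s0
    t2[head] = spec.wm.t2star
    s0[aqueduct & midbrain] = spec.csf.s0
    t2[aqueduct & midbrain] = spec.csf.t2star
    te1 = float(spec.echo_times[0])
    s0[rn] = spec.wm.s0
    t2[rn] = rn_t2
    t2[sn_iron] = sn_t2
    # sn_contrast is defined as the observed first-echo SN/WM ratio; S0 is
    # compensated for the differential T2* decay accumulated by TE1
    s0[sn] = spec.wm.s0 * contrast * np.exp(te1 / t2[sn] - te1 / spec.wm.t2star)

    tes = np.asarray(spec.echo_times)
    data = s0[None] * np.exp(-tes[:, None, None, None] / t2[None])
    if spec.noise_sd > 0:
        data = data + spec.noise_sd * rng.standard_normal(data.shape)
    vol = MultiEchoVolume(echo_times=tuple(tes), data=data,
                          voxel_size=spec.voxel_size)
    return vol, midbrain, reference


# ---------------------------------------------------------------------------
# DAT-SPECT phantom geometry (voxel units, coarser grid)

_DAT_REGIONS = {
    # name -> (|x offset| or None for midline, y, z, semi-axes)
    "caudate": (6.0, 14.0, 11.0, (2.5, 4.0, 3.0)),
    "putamen": (10.0, 21.0, 10.0, (3.0, 5.0, 3.5)),
    "pallidum": (5.0, 21.0, 10.0, (2.0, 3.0, 2.5)),
}
_BRAINSTEM = (26.0, 4.0, (4.0, 5.0, 3.5))  # (y, z, semi-axes), midline
_OCCIPITAL_BOX = ((8, 32), (40, 47), (4, 16))

_SBR_REGION = {"L-CaSBR": "caudate-L", "R-CaSBR": "caudate-R",
               "L-PuSBR": "putamen-L", "R-PuSBR": "putamen-R",
               "L-GPaSBR": "pallidum-L", "R-GPaSBR": "pallidum-R",
               "Brainstem-SBR": "brainstem"}


def _dat_label_map(shape: tuple) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int16)
    mid = (shape[0] - 1) / 2.0
    for name, (dx, y, z, axes) in _DAT_REGIONS.items():
        left = _ellipsoid(shape, (mid - dx, y, z), axes)
        right = _ellipsoid(shape, (mid + dx, y, z), axes)
        for side, mask in (("L", left), ("R", right)):
            sel = mask & (labels == 0)
            labels[sel] = DAT_LABELS[f"{name}-{side}"]
    y, z, axes = _BRAINSTEM
    bs = _ellipsoid(shape, (mid, y, z), axes)
    labels[bs & (labels == 0)] = DAT_LABELS["brainstem"]
    occ = _box(shape, _OCCIPITAL_BOX)
    labels[occ & (labels == 0)] = DAT_LABELS["occipital"]
    return labels


def generate_datspect_phantom(spec: CohortSpec, subject: SubjectRecord) -> UptakeVolume:
    """Simulate one subject's reconstructed-equivalent DAT uptake volume.

    Each anatomical region's uptake-to-occipital ratio is ``1 + SBR`` with
    the SBR drawn from the subject's group distribution, so the downstream
    occipital normalization and ratio-minus-one SBR computation recover the
    configured group means.  Background uptake is ~0 (below every VOI
    threshold); occipital uptake is strictly positive.
    """
    shape = spec.dat_grid_shape
    rng = _rng(spec, 2, subject.index)
    labels = _dat_label_map(shape)
    if not (labels == DAT_LABELS["occipital"]).any():
        raise ValueError("occipital reference region is empty")

    if spec.occipital_uptake <= 0:
        raise ValueError("occipital uptake must be strictly positive")
    occ = spec.occipital_uptake
    values = np.zeros(shape)
    values[labels == DAT_LABELS["occipital"]] = occ
    for col in SBR_COLUMNS:
        mu, sd = spec.sbr_stats[col][subject.group]
        sbr = rng.normal(mu, sd)
        sbr = max(sbr, -0.9)  # keep the region ratio positive
        values[labels == DAT_LABELS[_SBR_REGION[col]]] = occ * (1.0 + sbr)
    if spec.dat_noise_sd > 0:
        noise = spec.dat_noise_sd * occ * rng.standard_normal(shape)
        # keep noise out of the occipital reference so its mean stays exact,
        # mimicking a large, low-variance reference region
        noise[labels == DAT_LABELS["occipital"]] = 0.0
        values = np.clip(values + noise, 0.0, None)
    return UptakeVolume(values=values, voxel_size=tuple(spec.dat_voxel_size),
                        label_map=labels)


# ---------------------------------------------------------------------------
# fast path: feature-level table


def generate_feature_table(spec: CohortSpec,
                           feature_stats: dict | None = None) -> pd.DataFrame:
    """Draw the 58 MRI + 7 SBR feature columns directly as per-group Gaussians.

    Column names are identical to those emitted by the image pipeline
    (:func:`nigrascan.radiomics.mri_feature_names` plus the SBR columns), so
    the statistical downstream stages can run without voxel data.

    Parameters
    ----------
    feature_stats : dict, optional
        ``{feature: {group: (mean, sd)}}``; defaults to
        :func:`nigrascan.cohort_defaults.default_feature_stats`.  A zero SD
        yields constant draws; a negative SD is a configuration error.
    """
    stats = feature_stats if feature_stats is not None else default_feature_stats()
    records = generate_cohort(spec)
    frame = cohort_to_frame(records)
    groups = frame["group"].to_numpy()
    rng = _rng(spec, 3)

    columns = list(mri_feature_names()) + list(SBR_COLUMNS)
    for name in columns:
        if name not in stats:
            raise ValueError(f"no distribution parameters for feature {name!r}")
        mu = np.empty(len(records))
        sd = np.empty(len(records))
        for g in GROUPS:
            try:
                m, s = stats[name][g]
            except KeyError:
                raise ValueError(f"feature {name!r} lacks parameters for group {g!r}")
            if s < 0:
                raise ValueError(f"negative SD for feature {name!r}, group {g!r}")
            mu[groups == g] = m
            sd[groups == g] = s
        frame[name] = mu + sd * rng.standard_normal(len(records))
    return frame
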