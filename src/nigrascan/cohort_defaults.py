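"""Default group-level feature distributions for the synthetic cohort generator.

Thirteen MRI features and all seven DAT-SPECT specific-binding-ratio (SBR)
features carry group-specific means and SDs, reflecting the published
contrast between symptomatic Parkinson's disease (PD) and non-manifesting
non-carrier controls (NMNC): lower neuromelanin signal and volume, shorter
T2*, more positive T2* skewness/kurtosis, and markedly lower striatal SBR in
PD.  Non-manifesting carriers (NMC) are modelled at control level for these
features — the at-risk group's deviations are subtle and feature-dependent,
and the classification tasks this generator serves contrast PD with NMNC.

The remaining 45 MRI columns get group-independent (null-effect) parameters
chosen per feature family to sit in the plausible range for midbrain
radiomics at ~32 gray levels.
"""

from __future__ import annotations

from .datspect import SBR_COLUMNS
from .radiomics import mri_feature_names

__all__ = [
    "MRI_GROUP_STATS",
    "SBR_GROUP_STATS",
    "GROUP_DIFFERENTIATED_MRI_FEATURES",
    "default_feature_stats",
    "GROUPS",
]

GROUPS = ("PD", "NMC", "NMNC")

# feature -> {group: (mean, sd)}; the 13 MRI features that separate PD from NMNC
MRI_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Neuromelanin-SN-L-Mean": {"PD": (1.37, 0.13), "NMNC": (1.45, 0.12)},
    "Neuromelanin-SN-R-Mean": {"PD": (1.35, 0.13), "NMNC": (1.42, 0.11)},
    "Neuromelanin-SN-L-Vol": {"PD": (146.00, 64.38), "NMNC": (213.87, 54.31)},
    "Neuromelanin-SN-R-Vol": {"PD": (122.80, 65.03), "NMNC": (184.77, 52.87)},
    "T2*-neuromelanin-SN-R-Mean": {"PD": (28.04, 3.86), "NMNC": (30.67, 4.27)},
    "T2*-RN-L-Skewness": {"PD": (0.91, 0.61), "NMNC": (0.58, 0.50)},
    "T2*-RN-R-Contrast": {"PD": (14.99, 2.30), "NMNC": (16.65, 2.39)},
    "T2*-RN-R-Skewness": {"PD": (0.83, 0.40), "NMNC": (0.57, 0.32)},
    "T2*-neuromelanin-SN-L-Correlation": {"PD": (0.37, 0.04), "NMNC": (0.39, 0.03)},
    "T2*-neuromelanin-SN-L-Kurtosis": {"PD": (4.78, 1.81), "NMNC": (3.75, 0.92)},
    "T2*-neuromelanin-SN-R-Kurtosis": {"PD": (5.10, 2.49), "NMNC": (4.14, 1.26)},
    "Neuromelanin-SN-L-Kurtosis": {"PD": (3.13, 0.55), "NMNC": (2.83, 0.38)},
    "Neuromelanin-SN-L-Skewness": {"PD": (0.40, 0.31), "NMNC": (0.23, 0.23)},
}

GROUP_DIFFERENTIATED_MRI_FEATURES = tuple(MRI_GROUP_STATS)

SBR_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "L-CaSBR": {"PD": (1.58, 0.66), "NMNC": (3.03, 0.66)},
    "R-CaSBR": {"PD": (1.62, 0.56), "NMNC": (3.00, 0.67)},
    "L-PuSBR": {"PD": (1.39, 0.40), "NMNC": (3.38, 0.67)},
    "R-PuSBR": {"PD": (1.29, 0.46), "NMNC": (3.24, 0.67)},
    "L-GPaSBR": {"PD": (1.90, 0.64), "NMNC": (3.83, 1.00)},
    "R-GPaSBR": {"PD": (1.79, 0.56), "NMNC": (3.88, 1.06)},
    "Brainstem-SBR": {"PD": (0.64, 0.16), "NMNC": (0.79, 0.15)},
}

# group-independent fallbacks by (contrast, feature suffix); plausible midbrain
# radiomics magnitudes at 32 gray levels / 13-direction GLCM
_NULL_DEFAULTS = {
    ("NM", "Mean"): (1.43, 0.12),
    ("NM", "Vol"): (190.0, 55.0),
    ("NM", "Skewness"): (0.30, 0.25),
    ("NM", "Kurtosis"): (2.90, 0.40),
    ("NM", "Contrast"): (12.0, 2.2),
    ("NM", "Correlation"): (0.38, 0.04),
    ("NM", "Energy"): (0.020, 0.005),
    ("NM", "Homogeneity"): (0.52, 0.05),
    ("T2", "Mean"): (29.0, 4.0),
    ("T2", "Skewness"): (0.60, 0.45),
    ("T2", "Kurtosis"): (3.80, 1.00),
    ("T2", "Contrast"): (15.5, 2.4),
    ("T2", "Correlation"): (0.38, 0.04),
    ("T2", "Energy"): (0.020, 0.005),
    ("T2", "Homogeneity"): (0.52, 0.05),
}


def default_feature_stats() -> dict[str, dict[str, tuple[float, float]]]:
    """Per-feature ``{group: (mean, sd)}`` for all 58 MRI + 7 SBR columns.

    Group-differentiated features take their published PD/NMNC parameters
    (NMC at the NMNC value); all other features are drawn from the same
    distribution in every group.
    """
    stats: dict[str, dict[str, tuple[float, float]]] = {}
    for name in mri_feature_names():
        contrast = "NM" if name.startswith("Neuromelanin") else "T2"
        suffix = name.rsplit("-", 1)[1]
        mean, sd = _NULL_DEFAULTS[(contrast, suffix)]
        stats[name] = {g: (mean, sd) for g in GROUPS}
        if name in MRI_GROUP_STATS:
            row = MRI_GROUP_STATS[name]
            stats[name] = {"PD": row["PD"], "NMC": row["NMNC"], "NMNC": row["NMNC"]}
    for name in SBR_COLUMNS:
        row = SBR_GROUP_STATS[name]
        stats[name] = {"PD": row["PD"], "NMC": row["NMNC"], "NMNC": row["NMNC"]}
    return stats
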