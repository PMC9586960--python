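"""DAT-SPECT occipital normalization and specific binding ratios (SBR).

Striatal dopamine-transporter uptake is expressed relative to a nonspecific
reference region (the occipital lobe): each voxel is divided by the mean
occipital uptake, and the SBR of a VOI is the mean ratio minus 1 — the
specific binding in excess of the nonspecific background, so a region with
no specific uptake scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RatioMap", "normalize_uptake", "compute_sbr", "compute_sbr_record",
           "SBR_COLUMNS"]

#: the seven SBR columns, in emission order
SBR_COLUMNS = ("L-CaSBR", "R-CaSBR", "L-PuSBR", "R-PuSBR",
               "L-GPaSBR", "R-GPaSBR", "Brainstem-SBR")

#: SBR column -> VOI mask name used by the VOI stage
SBR_VOI_MAP = {
    "L-CaSBR": "caudate-L", "R-CaSBR": "caudate-R",
    "L-PuSBR": "putamen-L", "R-PuSBR": "putamen-R",
    "L-GPaSBR": "pallidum-L", "R-GPaSBR": "pallidum-R",
    "Brainstem-SBR": "brainstem",
}


@dataclass(frozen=True)
class RatioMap:
    """Uptake divided by the mean occipital uptake; occipital mean kept for provenance."""

    values: np.ndarray
    occipital_mean: float
    voxel_size: tuple = (2.0, 2.0, 2.0)


def normalize_uptake(uptake: np.ndarray, occipital_mask: np.ndarray,
                     voxel_size: tuple = (2.0, 2.0, 2.0)) -> RatioMap:
    """Divide an uptake volume by its mean over the occipital reference.

    The resulting ratio map has mean 1 over the occipital mask by
    construction, and is invariant to a global rescaling of the uptake.
    """
    uptake = np.asarray(uptake, dtype=float)
    occipital_mask = np.asarray(occipital_mask, dtype=bool)
    if occipital_mask.shape != uptake.shape:
        raise ValueError("occipital mask shape does not match uptake shape")
    if not occipital_mask.any():
        raise ValueError("occipital mask is empty")
    occ_mean = float(uptake[occipital_mask].mean())
    if occ_mean <= 0:
        raise ValueError(f"nonpositive occipital mean uptake ({occ_mean})")
    return RatioMap(values=uptake / occ_mean, occipital_mean=occ_mean,
                    voxel_size=tuple(voxel_size))


def compute_sbr(ratio: RatioMap, voi: np.ndarray) -> float:
    """Specific binding ratio of one VOI: mean in-VOI ratio minus 1."""
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("VOI mask is empty")
    return float(ratio.values[voi].mean() - 1.0)


def compute_sbr_record(ratio: RatioMap, vois) -> dict[str, float]:
    """SBR for all seven VOIs of a :class:`~nigrascan.voi.VOISet`."""
    record = {}
    for column, voi_name in SBR_VOI_MAP.items():
        if voi_name not in vois.masks:
            raise ValueError(f"missing VOI: {voi_name}")
        record[column] = compute_sbr(ratio, vois.masks[voi_name])
    return record
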