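"""First-order and gray-level co-occurrence (GLCM) texture features per VOI.

Six texture features are computed for each volume-of-interest/contrast pair:
two first-order (skewness, kurtosis) and four Haralick second-order features
derived from a symmetric, normalized 3-D GLCM (contrast, correlation, energy,
homogeneity).  Together with the neuromelanin means and volumes and the T2*
means, each subject yields a 58-column MRI feature vector:

* 8 values for each neuromelanin SN VOI (mean, volume, 6 texture) -> 16
* 7 values for each of the six T2*-bearing VOIs (mean, 6 texture) -> 42

giving 48 texture features (12 neuromelanin + 36 T2*) in total.

Conventions: skewness = m3 / m2^1.5 and kurtosis = m4 / m2^2 with plain 1/n
central moments (Pearson, non-excess: a normal sample gives kurtosis ~= 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GLCM",
    "discretize",
    "compute_glcm",
    "first_order",
    "second_order",
    "extract_feature_vector",
    "mri_feature_names",
    "TEXTURE_FEATURES",
    "GLCM_DEFAULTS",
    "DIRECTIONS_3D",
]

TEXTURE_FEATURES = ("Skewness", "Kurtosis", "Contrast", "Correlation",
                    "Energy", "Homogeneity")

#: the six VOI/contrast pairs carrying texture features, in emission order
NM_VOI_PREFIXES = ("Neuromelanin-SN-L", "Neuromelanin-SN-R")
T2S_VOI_PREFIXES = ("T2*-SN-L", "T2*-SN-R", "T2*-RN-L", "T2*-RN-R",
                    "T2*-neuromelanin-SN-L", "T2*-neuromelanin-SN-R")

GLCM_DEFAULTS = {"n_levels": 32, "distance": 1}

# the 13 unique nearest-neighbour direction offsets of a 3-D lattice
# (26-neighbourhood modulo inversion; both directions are counted symmetrically)
DIRECTIONS_3D = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)


def mri_feature_names() -> list[str]:
    """The 58 MRI feature-column names, in extraction order."""
    names = []
    for prefix in NM_VOI_PREFIXES:
        names.append(f"{prefix}-Mean")
        names.append(f"{prefix}-Vol")
        names.extend(f"{prefix}-{f}" for f in TEXTURE_FEATURES)
    for prefix in T2S_VOI_PREFIXES:
        names.append(f"{prefix}-Mean")
        names.extend(f"{prefix}-{f}" for f in TEXTURE_FEATURES)
    return names


@dataclass(frozen=True)
class GLCM:
    """Symmetric, sum-normalized gray-level co-occurrence matrix."""

    matrix: np.ndarray  # (n_levels, n_levels), entries sum to 1
    n_levels: int
    distance: int
    directions: tuple


def discretize(values: np.ndarray, n_levels: int = 32) -> tuple[np.ndarray, bool]:
    """Uniform min-max binning of intensities into ``n_levels`` gray levels.

    Returns ``(levels, constant)`` where ``levels`` are integer bin indices in
    ``[0, n_levels)`` and ``constant`` flags degenerate (all-equal) input,
    which maps to a single level 0.  Level assignment is invariant under
    positive affine transforms of the input.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros(values.shape, dtype=np.intp), True
    levels = np.floor((values - vmin) / (vmax - vmin) * n_levels).astype(np.intp)
    return np.minimum(levels, n_levels - 1), False


def compute_glcm(volume: np.ndarray, mask: np.ndarray, n_levels: int = 32,
                 distance: int = 1, directions: tuple | None = None) -> GLCM:
    """Compute a masked 3-D GLCM pooled over direction offsets.

    Gray levels are assigned by min-max discretization of the *in-mask*
    intensities.  For every offset ``d * distance`` each ordered voxel pair
    with both ends inside the mask contributes to ``(i, j)`` and ``(j, i)``,
    so the matrix is symmetric by construction; counts from all offsets are
    pooled before normalization to sum 1.

    Raises
    ------
    ValueError
        If no in-mask voxel pair exists at any offset.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume shape")
    if directions is None:
        directions = DIRECTIONS_3D
    levels_flat, _ = discretize(volume[mask], n_levels)
    levels = np.zeros(volume.shape, dtype=np.intp)
    levels[mask] = levels_flat

    counts = np.zeros((n_levels, n_levels))
    for d in directions:
        off = tuple(int(c) * distance for c in d)
        src = tuple(slice(max(0, -o), min(s, s - o)) for s, o in zip(volume.shape, off))
        dst = tuple(slice(max(0, o), min(s, s + o)) for s, o in zip(volume.shape, off))
        pair_ok = mask[src] & mask[dst]
        li = levels[src][pair_ok]
        lj = levels[dst][pair_ok]
        np.add.at(counts, (li, lj), 1)
        np.add.at(counts, (lj, li), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask voxel pairs at the requested offsets")
    return GLCM(matrix=counts / total, n_levels=n_levels, distance=distance,
                directions=tuple(directions))


def first_order(values: np.ndarray) -> tuple[float, float, float]:
    """Mean, skewness and kurtosis of an intensity sample.

    Skewness and kurtosis use 1/n central moments (Pearson kurtosis, so a
    normal sample is near 3).  Zero-variance input yields NaN for both shape
    statistics; the mean is always defined.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("first-order statistics require at least 3 values")
    mean = float(values.mean())
    if np.ptp(values) == 0:
        return mean, float("nan"), float("nan")
    skew = float(sps.skew(values, bias=True))
    kurt = float(sps.kurtosis(values, bias=True, fisher=False))
    return mean, skew, kurt


def second_order(glcm: GLCM) -> tuple[float, float, float, float, bool]:
    """Haralick features of a normalized GLCM.

    Returns ``(contrast, correlation, energy, homogeneity, degenerate)``:

    * contrast     = sum p(i,j) (i-j)^2
    * correlation  = sum p(i,j) (i-mu_i)(j-mu_j) / (sigma_i sigma_j)
    * energy       = sum p(i,j)^2
    * homogeneity  = sum p(i,j) / (1 + |i-j|)

    A zero marginal variance makes correlation undefined; it is reported as
    0.0 with ``degenerate=True`` so feature tables stay numeric.
    """
    p = np.asarray(glcm.matrix, dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float((p * (i - j) ** 2).sum())
    energy = float((p ** 2).sum())
    homogeneity = float((p / (1.0 + np.abs(i - j))).sum())

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float((np.arange(n) * pi).sum())
    mu_j = float((np.arange(n) * pj).sum())
    var_i = float(((np.arange(n) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(n) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        return contrast, 0.0, energy, homogeneity, True
    corr = float((p * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j))
    return contrast, corr, energy, homogeneity, False


def _texture_block(volume: np.ndarray, mask: np.ndarray, prefix: str,
                   n_levels: int, distance: int) -> dict[str, float]:
    vals = volume[mask]
    _, skew, kurt = first_order(vals)
    glcm = compute_glcm(volume, mask, n_levels=n_levels, distance=distance)
    contrast, corr, energy, homog, _ = second_order(glcm)
    return {
        f"{prefix}-Skewness": skew,
        f"{prefix}-Kurtosis": kurt,
        f"{prefix}-Contrast": contrast,
        f"{prefix}-Correlation": corr,
        f"{prefix}-Energy": energy,
        f"{prefix}-Homogeneity": homog,
    }


def extract_feature_vector(nm, t2, vois, n_levels: int = 32, distance: int = 1,
                           nm_volume_threshold: float = 1.0) -> dict[str, float]:
    """Assemble one subject's 58-entry MRI feature vector.

    Parameters
    ----------
    nm : NormalizedNMMap
        White-matter-normalized neuromelanin map.
    t2 : T2StarMap
        Fitted T2* map; invalid-fit voxels are excluded from every statistic.
    vois : VOISet
        Must contain the six MRI masks NM-SN-L/R, T2*-SN-L/R, T2*-RN-L/R.
    nm_volume_threshold : float
        Normalized-signal cutoff defining the neuromelanin volume (voxels
        with value strictly above it count).

    Returns
    -------
    dict
        Feature name -> value, in the order of :func:`mri_feature_names`:
        48 texture features, 2 NM means, 2 NM volumes (mm^3), 6 T2* means (ms).
    """
    from .voi import nm_volume as _nm_volume  # local import avoids cycle

    required = ["NM-SN-L", "NM-SN-R", "T2*-SN-L", "T2*-SN-R", "T2*-RN-L", "T2*-RN-R"]
    for name in required:
        if name not in vois.masks:
            raise ValueError(f"missing VOI: {name}")

    t2_valid = np.where(t2.valid_mask, t2.values, np.nan)
    features: dict[str, float] = {}

    for side in ("L", "R"):
        voi = vois.masks[f"NM-SN-{side}"]
        prefix = f"Neuromelanin-SN-{side}"
        features[f"{prefix}-Mean"] = float(nm.values[voi].mean())
        features[f"{prefix}-Vol"] = _nm_volume(nm, voi, threshold=nm_volume_threshold)
        features.update(_texture_block(nm.values, voi, prefix, n_levels, distance))

    t2_voi_map = [("T2*-SN-L", "T2*-SN-L"), ("T2*-SN-R", "T2*-SN-R"),
                  ("T2*-RN-L", "T2*-RN-L"), ("T2*-RN-R", "T2*-RN-R"),
                  ("T2*-neuromelanin-SN-L", "NM-SN-L"),
                  ("T2*-neuromelanin-SN-R", "NM-SN-R")]
    for prefix, voi_name in t2_voi_map:
        voi = vois.masks[voi_name] & t2.valid_mask
        if not voi.any():
            raise ValueError(f"no valid T2* voxels inside VOI {voi_name}")
        features[f"{prefix}-Mean"] = float(t2_valid[voi].mean())
        features.update(_texture_block(t2_valid, voi, prefix, n_levels, distance))

    order = mri_feature_names()
    return {name: features[name] for name in order}
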