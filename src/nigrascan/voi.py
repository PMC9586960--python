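"""Population templates, k-means segmentation, and VOI definition.

MRI VOIs are derived from control-group population templates: the
intensity-normalized neuromelanin (or T2*) images are averaged over the
rostral midbrain, a 1-D k-means (k = 3) partitions template voxels by
intensity, and the cluster of interest is split at the sagittal midline into
left/right masks — six MRI VOIs in total (NM-SN-L/R from the neuromelanin
template; T2*-SN-L/R and T2*-RN-L/R from the T2* template).  DAT-SPECT VOIs
are the anatomically labeled voxels of the control ratio template above
fixed uptake-ratio thresholds (> 3 striatal, > 1.65 brainstem) — seven
masks.

Laterality convention: the first array axis is left-right; voxels with
``x < nx/2`` are "L".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

__all__ = [
    "VOISet",
    "SegmentationError",
    "build_population_template",
    "kmeans_segment",
    "define_nm_vois",
    "define_t2star_vois",
    "nm_volume",
    "define_dat_vois",
    "dice",
    "MRI_VOI_NAMES",
    "DAT_VOI_NAMES",
]

MRI_VOI_NAMES = ("NM-SN-L", "NM-SN-R", "T2*-SN-L", "T2*-SN-R", "T2*-RN-L", "T2*-RN-R")
DAT_VOI_NAMES = ("caudate-L", "caudate-R", "putamen-L", "putamen-R",
                 "pallidum-L", "pallidum-R", "brainstem")

_CONNECTIVITY = np.ones((3, 3, 3), dtype=bool)  # 26-connected components


class SegmentationError(RuntimeError):
    """Raised when template segmentation cannot produce the expected VOIs."""


@dataclass(frozen=True)
class VOISet:
    """Named binary masks sharing one voxel grid."""

    masks: dict
    voxel_size: tuple

    def __post_init__(self):
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("all VOI masks must share one grid shape")

    def counts(self) -> dict:
        return {name: int(mask.sum()) for name, mask in self.masks.items()}


def build_population_template(images: list, masks: list,
                              background: float = np.nan) -> np.ndarray:
    """Voxelwise mean of control images restricted to the union working mask.

    Voxels outside the union of the per-subject masks are set to
    ``background`` (NaN by default).
    """
    if len(images) == 0:
        raise ValueError("at least one control image is required")
    if len(masks) != len(images):
        raise ValueError("one mask per image is required")
    shape = np.asarray(images[0]).shape
    for arr in list(images) + list(masks):
        if np.asarray(arr).shape != shape:
            raise ValueError("all images and masks must share one grid shape")
    union = np.zeros(shape, dtype=bool)
    for m in masks:
        union |= np.asarray(m, dtype=bool)
    mean = np.mean([np.asarray(img, dtype=float) for img in images], axis=0)
    template = np.full(shape, background, dtype=float)
    template[union] = mean[union]
    return template


def kmeans_segment(template: np.ndarray, mask: np.ndarray, k: int = 3,
                   seed: int = 0) -> np.ndarray:
    """1-D k-means on voxel intensity within a mask.

    Cluster labels are re-ordered by ascending centroid intensity, so label
    0 is always the darkest cluster and label ``k-1`` the brightest,
    independent of initialization.  Returns an integer grid with -1 outside
    the mask.

    Raises
    ------
    SegmentationError
        If the masked image is degenerate (< k distinct intensities).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < k:
        raise ValueError(f"mask has fewer than k={k} voxels")
    values = np.asarray(template, dtype=float)[mask]
    if np.unique(values).size < k:
        raise SegmentationError(
            f"degenerate template: fewer than {k} distinct intensities in mask")
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) & 0x7FFFFFFF)
    raw = km.fit_predict(values.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty(k, dtype=np.intp)
    remap[order] = np.arange(k)
    labels = np.full(template.shape, -1, dtype=np.intp)
    labels[mask] = remap[raw]
    return labels


def _remove_small(mask: np.ndarray, min_component: int) -> np.ndarray:
    comps, n = ndimage.label(mask, structure=_CONNECTIVITY)
    keep = np.zeros_like(mask)
    for i in range(1, n + 1):
        comp = comps == i
        if comp.sum() >= min_component:
            keep |= comp
    return keep


def _split_lr(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mid = mask.shape[0] / 2.0
    x = np.arange(mask.shape[0])[:, None, None]
    left = mask & (x < mid)
    right = mask & (x >= mid)
    return left, right


def define_nm_vois(labels: np.ndarray, template: np.ndarray | None = None,
                   min_component: int = 5,
                   voxel_size: tuple = (0.6, 0.6, 1.3)) -> VOISet:
    """Neuromelanin SN VOIs: the brightest k-means cluster, split at midline.

    Small connected components (< ``min_component`` voxels, 26-connectivity)
    are removed as noise speckles.
    """
    k = int(labels.max()) + 1
    if k < 1:
        raise SegmentationError("no cluster labels inside the mask")
    sn = _remove_small(labels == (k - 1), min_component)
    if not sn.any():
        raise SegmentationError("highest-intensity cluster empty after cleanup")
    left, right = _split_lr(sn)
    if not left.any() or not right.any():
        raise SegmentationError("neuromelanin SN cluster is not bilateral")
    return VOISet(masks={"NM-SN-L": left, "NM-SN-R": right},
                  voxel_size=tuple(voxel_size))


def define_t2star_vois(labels: np.ndarray, template: np.ndarray | None = None,
                       min_component: int = 5,
                       voxel_size: tuple = (0.6, 0.6, 1.3)) -> VOISet:
    """T2* SN and RN VOIs from the darkest (shortest-T2*, iron-rich) cluster.

    Connected components of the lowest-T2* cluster are assigned per
    hemisphere: of the two largest components on each side, the more lateral
    one (larger midline distance of its centroid) is the SN, the more medial
    one the RN.

    Raises
    ------
    SegmentationError
        If any hemisphere yields fewer than two surviving components.
    """
    iron = _remove_small(labels == 0, min_component)
    comps, n = ndimage.label(iron, structure=_CONNECTIVITY)
    mid = labels.shape[0] / 2.0
    per_side: dict[str, list] = {"L": [], "R": []}
    for i in range(1, n + 1):
        comp = comps == i
        cx = float(ndimage.center_of_mass(comp)[0])
        side = "L" if cx < mid else "R"
        per_side[side].append((comp.sum(), abs(cx - mid), comp))
    masks = {}
    for side, comp_list in per_side.items():
        if len(comp_list) < 2:
            raise SegmentationError(
                f"hemisphere {side}: found {len(comp_list)} iron-rich component(s), "
                "need 2 (SN and RN); total surviving components: "
                f"{sum(len(v) for v in per_side.values())}")
        comp_list.sort(key=lambda t: t[0], reverse=True)
        two = comp_list[:2]
        two.sort(key=lambda t: t[1], reverse=True)  # by midline distance
        masks[f"T2*-SN-{side}"] = two[0][2]
        masks[f"T2*-RN-{side}"] = two[1][2]
    return VOISet(masks=masks, voxel_size=tuple(voxel_size))


def nm_volume(nm, voi: np.ndarray, threshold: float = 1.0) -> float:
    """Neuromelanin volume in mm^3: supra-threshold voxels times voxel volume.

    Counts voxels inside ``voi`` whose normalized neuromelanin signal is
    strictly greater than ``threshold`` (default 1, the white-matter level).
    """
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise ValueError("VOI mask is empty")
    count = int((np.asarray(nm.values)[voi] > threshold).sum())
    return count * float(np.prod(nm.voxel_size))


def define_dat_vois(ratio_template: np.ndarray, label_map: np.ndarray,
                    labels: dict, striatal_threshold: float = 3.0,
                    brainstem_threshold: float = 1.65,
                    voxel_size: tuple = (2.0, 2.0, 2.0)) -> VOISet:
    """Threshold the control ratio template inside each anatomical label.

    Striatal VOIs (caudate, putamen, pallidum, both sides) keep labeled
    voxels with occipital-normalized ratio > ``striatal_threshold``; the
    brainstem uses ``brainstem_threshold``.  Exactly seven masks are
    emitted; an empty mask is an error naming the VOI.
    """
    ratio = np.asarray(ratio_template, dtype=float)
    label_map = np.asarray(label_map)
    masks = {}
    for name in DAT_VOI_NAMES:
        thr = brainstem_threshold if name == "brainstem" else striatal_threshold
        mask = (label_map == labels[name]) & (ratio > thr)
        if not mask.any():
            raise SegmentationError(f"DAT VOI {name!r} is empty at threshold {thr}")
        masks[name] = mask
    return VOISet(masks=masks, voxel_size=tuple(voxel_size))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
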