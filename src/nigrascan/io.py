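"""NIfTI-1 readers/writers and table serialization helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import MultiEchoVolume

__all__ = ["read_volume", "write_volume", "read_multiecho", "write_multiecho"]


def write_volume(values: np.ndarray, path, voxel_size=(1.0, 1.0, 1.0)) -> Path:
    """Write a 3-D (or 4-D) array as NIfTI-1 with a diagonal affine."""
    path = Path(path)
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms(tuple(voxel_size[:3]) + (1.0,) * (values.ndim - 3))
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, tuple]:
    """Read a NIfTI-1 file; returns (array, voxel_size_mm)."""
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return values, voxel_size


def write_multiecho(vol: MultiEchoVolume, prefix) -> list[Path]:
    """One NIfTI file per echo: ``<prefix>_echo-1.nii`` etc., in TE order."""
    paths = []
    for i in range(vol.n_echoes):
        p = Path(f"{prefix}_echo-{i + 1}.nii")
        write_volume(vol.data[i], p, vol.voxel_size)
        paths.append(p)
    return paths


def read_multiecho(paths, echo_times) -> MultiEchoVolume:
    """Assemble echo files (given in TE order) into a MultiEchoVolume.

    A single 4-D file is split along its last axis into echoes.
    """
    paths = list(paths)
    arrays = []
    voxel_size = None
    for p in paths:
        values, vs = read_volume(p)
        voxel_size = voxel_size or vs
        if values.ndim == 4:
            arrays.extend(np.moveaxis(values, -1, 0))
        else:
            arrays.append(values)
    if len(arrays) != len(echo_times):
        raise ValueError(f"found {len(arrays)} echo volumes for "
                         f"{len(echo_times)} echo times")
    return MultiEchoVolume(echo_times=tuple(echo_times),
                           data=np.stack(arrays), voxel_size=voxel_size)
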