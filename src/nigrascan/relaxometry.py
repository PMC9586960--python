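"""T2* relaxometry and neuromelanin image preparation.

A multi-echo gradient-echo acquisition samples the mono-exponential decay
``S(TE) = S0 * exp(-TE / T2*)`` at a handful of echo times.  Taking logs turns
the decay into a straight line, so T2* is recovered per voxel by ordinary
least squares of ``ln S`` on TE; the neuromelanin-sensitive image is simply
the first (shortest-TE) echo, which is subsequently normalized against a
normal-appearing white-matter reference region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiEchoVolume",
    "T2StarMap",
    "NormalizedNMMap",
    "fit_t2star",
    "extract_neuromelanin",
    "normalize_neuromelanin",
]

DEFAULT_ECHO_TIMES = (7.91, 15.96, 24.0)  # ms
DEFAULT_VOXEL_SIZE = (0.6, 0.6, 1.3)  # mm
DEFAULT_T2STAR_CAP = 150.0  # ms; uncapped fits on near-flat decays explode


@dataclass(frozen=True)
class MultiEchoVolume:
    """Co-registered 3-D echo images sharing one voxel grid.

    Parameters
    ----------
    echo_times : sequence of float
        Echo times in ms, strictly increasing, all positive.
    data : ndarray, shape (n_echoes, nx, ny, nz)
        One intensity volume per echo.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    """

    echo_times: tuple
    data: np.ndarray
    voxel_size: tuple = DEFAULT_VOXEL_SIZE

    def __post_init__(self):
        tes = np.asarray(self.echo_times, dtype=float)
        if tes.ndim != 1 or tes.size < 1:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(tes <= 0) or np.any(np.diff(tes) <= 0):
            raise ValueError("echo times must be positive and strictly increasing")
        data = np.asarray(self.data)
        if data.ndim != 4 or data.shape[0] != tes.size:
            raise ValueError(
                f"data must have shape (n_echoes={tes.size}, nx, ny, nz); got {data.shape}"
            )
        object.__setattr__(self, "echo_times", tuple(tes))
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def shape(self) -> tuple:
        return self.data.shape[1:]


@dataclass(frozen=True)
class T2StarMap:
    """Per-voxel T2* estimates in ms.

    ``values`` is NaN wherever ``valid_mask`` is False (nonpositive signal or a
    non-decaying fit); valid values lie in ``(0, cap]``.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    cap: float = DEFAULT_T2STAR_CAP
    voxel_size: tuple = DEFAULT_VOXEL_SIZE


@dataclass(frozen=True)
class NormalizedNMMap:
    """Dimensionless neuromelanin map; mean over the reference mask is 1."""

    values: np.ndarray
    reference_mean: float
    voxel_size: tuple = DEFAULT_VOXEL_SIZE


def fit_t2star(vol: MultiEchoVolume, mask: np.ndarray | None = None,
               t2star_cap: float = DEFAULT_T2STAR_CAP) -> T2StarMap:
    """Fit a mono-exponential T2* decay per voxel by log-linear least squares.

    Per voxel, ordinary least squares of ``ln S`` on TE gives slope ``-1/T2*``.
    Voxels with any nonpositive echo intensity, or with a non-negative slope
    (no decay), are flagged invalid; valid estimates are clamped to
    ``(0, t2star_cap]``.

    Parameters
    ----------
    vol : MultiEchoVolume
        At least two echoes.
    mask : ndarray of bool, optional
        Restrict the fit to these voxels; outside voxels are invalid.
    t2star_cap : float
        Upper clamp in ms.

    Returns
    -------
    T2StarMap
    """
    if vol.n_echoes < 2:
        raise ValueError("T2* fitting requires at least two echoes")
    if t2star_cap <= 0:
        raise ValueError("t2star_cap must be positive")

    tes = np.asarray(vol.echo_times)
    data = vol.data
    shape = vol.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask shape does not match volume shape")

    positive = np.all(data > 0, axis=0)
    fit_mask = mask & positive

    values = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    if fit_mask.any():
        logs = np.log(data[:, fit_mask])  # (n_echoes, n_vox)
        te_c = tes - tes.mean()
        # closed-form OLS slope: cov(TE, ln S) / var(TE)
        slope = te_c @ logs / (te_c @ te_c)
        decaying = slope < -1e-12  # tolerance: an exactly flat decay is invalid
        t2 = np.where(decaying, -1.0 / np.where(decaying, slope, -1.0), np.nan)
        t2 = np.minimum(t2, t2star_cap)
        out = np.full(fit_mask.sum(), np.nan)
        out[decaying] = t2[decaying]
        values[fit_mask] = out
        vstate = np.zeros(fit_mask.sum(), dtype=bool)
        vstate[decaying] = True
        valid[fit_mask] = vstate

    return T2StarMap(values=values, valid_mask=valid, cap=float(t2star_cap),
                     voxel_size=vol.voxel_size)


def extract_neuromelanin(vol: MultiEchoVolume) -> np.ndarray:
    """Return the neuromelanin-sensitive image: the first-echo grid, unchanged."""
    return vol.data[0].copy()


def normalize_neuromelanin(nm: np.ndarray, reference_mask: np.ndarray,
                           voxel_size: tuple = DEFAULT_VOXEL_SIZE) -> NormalizedNMMap:
    """Normalize a neuromelanin image by its mean over a white-matter reference.

    Parameters
    ----------
    nm : ndarray
        Raw first-echo intensities.
    reference_mask : ndarray of bool
        Normal-appearing white-matter voxels, disjoint from the midbrain
        region of interest.

    Returns
    -------
    NormalizedNMMap
        ``values = nm / mean(nm[reference_mask])``; by construction the mean of
        the output over the reference mask is 1.
    """
    nm = np.asarray(nm, dtype=float)
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if reference_mask.shape != nm.shape:
        raise ValueError("reference mask shape does not match image shape")
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    ref_mean = float(nm[reference_mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"nonpositive reference mean ({ref_mean}); cannot normalize")
    return NormalizedNMMap(values=nm / ref_mean, reference_mean=ref_mean,
                           voxel_size=tuple(voxel_size))
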