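"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit


def brute_force_glcm(volume, mask, n_levels, distance, directions):
    """GLCM by explicit voxel-pair enumeration (no vectorized tricks)."""
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = volume[mask]
    vmin, vmax = vals.min(), vals.max()
    levels = np.zeros(volume.shape, dtype=int)
    if vmax > vmin:
        lv = np.floor((volume - vmin) / (vmax - vmin) * n_levels).astype(int)
        levels = np.minimum(lv, n_levels - 1)
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = volume.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                for dx, dy, dz in directions:
                    u, v, w = x + dx * distance, y + dy * distance, z + dz * distance
                    if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                        i, j = levels[x, y, z], levels[u, v, w]
                        counts[i, j] += 1
                        counts[j, i] += 1
    total = counts.sum()
    return counts / total if total else counts


def brute_force_haralick(p):
    """Contrast, correlation, energy, homogeneity by explicit double loops."""
    p = np.asarray(p, dtype=float)
    n = p.shape[0]
    contrast = energy = homog = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            contrast += p[i, j] * (i - j) ** 2
            energy += p[i, j] ** 2
            homog += p[i, j] / (1 + abs(i - j))
            mu_i += i * p[i, j]
            mu_j += j * p[i, j]
    var_i = var_j = cov = 0.0
    for i in range(n):
        for j in range(n):
            var_i += (i - mu_i) ** 2 * p[i, j]
            var_j += (j - mu_j) ** 2 * p[i, j]
            cov += (i - mu_i) * (j - mu_j) * p[i, j]
    corr = cov / np.sqrt(var_i * var_j) if var_i > 0 and var_j > 0 else 0.0
    return contrast, corr, energy, homog


def nonlinear_t2star_fit(tes, signal):
    """Mono-exponential fit by nonlinear least squares (reference for the
    log-linear closed form)."""
    tes = np.asarray(tes, dtype=float)
    signal = np.asarray(signal, dtype=float)

    def model(te, s0, t2):
        return s0 * np.exp(-te / t2)

    popt, _ = curve_fit(model, tes, signal, p0=[signal[0], 20.0], maxfev=10000)
    return popt[1]


def stepup_bh(p_values, q):
    """Benjamini-Hochberg step-up written out literally."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject
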