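"""Independent naive reference implementations used as test oracles.

Everything here is deliberately written the slow, obvious way — explicit
per-voxel Python loops, direct DFT sums, textbook formulas — and shares no
code with the package under test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def dft_amplitude(x: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum by direct DFT summation."""
    n = len(x)
    n_bins = n // 2 + 1
    amps = np.empty(n_bins)
    t = np.arange(n)
    for k in range(n_bins):
        re = np.sum(x * np.cos(2 * np.pi * k * t / n))
        im = -np.sum(x * np.sin(2 * np.pi * k * t / n))
        mag = np.sqrt(re**2 + im**2)
        scale = 1.0 / n if (k == 0 or (n % 2 == 0 and k == n_bins - 1)) else 2.0 / n
        amps[k] = mag * scale
    return amps


def naive_alff(vol: np.ndarray, mask: np.ndarray, tr: float,
               low: float, high: float) -> np.ndarray:
    out = np.zeros(vol.shape[:3])
    n = vol.shape[-1]
    freqs = np.arange(n // 2 + 1) / (n * tr)
    band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    for idx in np.ndindex(vol.shape[:3]):
        if mask[idx]:
            out[idx] = dft_amplitude(vol[idx]).take(np.where(band)[0]).mean()
    return out


def naive_falff(vol: np.ndarray, mask: np.ndarray, tr: float,
                low: float, high: float) -> np.ndarray:
    out = np.zeros(vol.shape[:3])
    n = vol.shape[-1]
    freqs = np.arange(n // 2 + 1) / (n * tr)
    band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    for idx in np.ndindex(vol.shape[:3]):
        if mask[idx]:
            amps = dft_amplitude(vol[idx])
            den = amps[1:].sum()
            out[idx] = amps[band].sum() / den if den > 0 else 0.0
    return out


def naive_peraf(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.zeros(vol.shape[:3])
    for idx in np.ndindex(vol.shape[:3]):
        if mask[idx]:
            x = vol[idx]
            mu = x.mean()
            out[idx] = 100.0 * np.mean(np.abs(x - mu)) / mu if mu > 0 else 0.0
    return out


def naive_kcc(series_set: np.ndarray) -> float:
    """Kendall's W of (K, n) series: textbook formula on time ranks."""
    k, n = series_set.shape
    ranks = np.array([stats.rankdata(s) for s in series_set])
    r_i = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2.0
    s = np.sum((r_i - rbar) ** 2)  # equivalent numerator: sum R_i^2 - n rbar^2
    return s / (k**2 * (n**3 - n) / 12.0)


def naive_reho(vol: np.ndarray, mask: np.ndarray, k: int = 27) -> np.ndarray:
    offsets = {
        7: [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
            if abs(a) + abs(b) + abs(c) <= 1],
        19: [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
             if abs(a) + abs(b) + abs(c) <= 2],
        27: [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)],
    }[k]
    out = np.zeros(vol.shape[:3])
    shape = vol.shape[:3]
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        members = []
        for d in offsets:
            j = tuple(np.add(idx, d))
            if all(0 <= j[a] < shape[a] for a in range(3)) and mask[j]:
                members.append(vol[j])
        if len(members) < 2:
            continue
        out[idx] = min(max(naive_kcc(np.array(members)), 0.0), 1.0)
    return out


def naive_dc(vol: np.ndarray, mask: np.ndarray, r0: float = 0.25,
             weighted: bool = False) -> np.ndarray:
    coords = list(zip(*np.where(mask)))
    out = np.zeros(vol.shape[:3])
    for i, ci in enumerate(coords):
        acc = 0.0
        for j, cj in enumerate(coords):
            if i == j:
                continue
            xi, xj = vol[ci], vol[cj]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if r > r0:
                acc += r if weighted else 1.0
        out[ci] = acc
    return out


def pooled_t_textbook(x, y):
    """Hand formula: pooled variance, df = n1 + n2 - 2."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2


def partial_r_recursion(r_xy, r_xz, r_yz):
    """First-order partial correlation closed form."""
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def bh_reject_bruteforce(p, q):
    """BH rejection set by exhaustive maximal-k search."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    best_k = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            best_k = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:best_k]] = True
    return reject


def normal_equations_residual(design, y):
    """OLS residual via explicit normal equations (X'X)^-1 X'y."""
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    return y - design @ beta
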