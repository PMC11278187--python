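"""Independent brute-force reference implementations.

Everything here is written as plain double loops / explicit arithmetic, on
purpose: these oracles share no code path with the package and exist only
to check it.
"""

import math

import numpy as np


def erode_loops(image, radius):
    """Sliding-window minimum with explicit loops, edge replication."""
    m, n = image.shape
    out = np.empty_like(image, dtype=float)
    for i in range(m):
        for j in range(n):
            lo_i, hi_i = max(0, i - radius), min(m - 1, i + radius)
            lo_j, hi_j = max(0, j - radius), min(n - 1, j + radius)
            best = math.inf
            for a in range(lo_i, hi_i + 1):
                for b in range(lo_j, hi_j + 1):
                    best = min(best, image[a, b])
            out[i, j] = best
    return out


def block_ranges(extent, k):
    step = extent // k
    return [(i * step, (i + 1) * step if i < k - 1 else extent) for i in range(k)]


def eme_loops(image, k1, k2, eps):
    total = 0.0
    for r0, r1 in block_ranges(image.shape[0], k1):
        for c0, c1 in block_ranges(image.shape[1], k2):
            mx = -math.inf
            mn = math.inf
            for i in range(r0, r1):
                for j in range(c0, c1):
                    mx = max(mx, image[i, j])
                    mn = min(mn, image[i, j])
            total += 20.0 * math.log10((mx + eps) / (mn + eps))
    return total / (k1 * k2)


def mse_loops(f, g):
    m, n = f.shape
    total = 0.0
    for i in range(m):
        for j in range(n):
            total += (f[i, j] - g[i, j]) ** 2
    return total / (m * n)


def psnr_from_mse(err):
    if err == 0:
        return math.inf
    return 10.0 * math.log10(255.0**2 / err)


def dsc_counts(a, b):
    """Dice by explicit pixel-set enumeration."""
    set_a = {(i, j) for i, j in zip(*np.nonzero(a))}
    set_b = {(i, j) for i, j in zip(*np.nonzero(b))}
    if not set_a and not set_b:
        return 1.0
    return 2.0 * len(set_a & set_b) / (len(set_a) + len(set_b))


def ridge_normal_equations(D, Y, lam):
    """(DᵀD + lam·I)⁻¹ DᵀY via an explicit inverse."""
    return np.linalg.inv(D.T @ D + lam * np.eye(D.shape[1])) @ (D.T @ Y)


def log_edges_direct(image, sigma):
    """Gaussian blur (scipy) then an explicit 5-point stencil with edge
    replication, applied by loops."""
    from scipy.ndimage import gaussian_filter

    blurred = gaussian_filter(image, sigma=sigma, mode="nearest")
    m, n = image.shape
    out = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            up = blurred[max(i - 1, 0), j]
            down = blurred[min(i + 1, m - 1), j]
            left = blurred[i, max(j - 1, 0)]
            right = blurred[i, min(j + 1, n - 1)]
            out[i, j] = up + down + left + right - 4.0 * blurred[i, j]
    return out
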