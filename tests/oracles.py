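"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with dense Python loops and clamped indexing,
sharing no code with the package, so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import math

import numpy as np


def naive_curvature(pixels: np.ndarray) -> np.ndarray:
    """Loop-based mean curvature of a binary height field, unit grid.

    Central differences with edge-clamped indices (equivalent to replicate
    padding); mixed derivative as the central difference of the
    first-derivative field.
    """
    s = pixels.astype(float)
    nx, ny = s.shape

    def at(i: int, j: int) -> float:
        return s[min(max(i, 0), nx - 1), min(max(j, 0), ny - 1)]

    def gx(i: int, j: int) -> float:
        return (at(i + 1, j) - at(i - 1, j)) / 2.0

    H = np.zeros((nx, ny))
    for i in range(nx):
        for j in range(ny):
            sx = gx(i, j)
            sy = (at(i, j + 1) - at(i, j - 1)) / 2.0
            sxx = at(i + 1, j) - 2.0 * at(i, j) + at(i - 1, j)
            syy = at(i, j + 1) - 2.0 * at(i, j) + at(i, j - 1)
            jp = min(j + 1, ny - 1)
            jm = max(j - 1, 0)
            sxy = (gx(i, jp) - gx(i, jm)) / 2.0
            num = (sx**2 + 1.0) * syy - 2.0 * sx * sy * sxy + (sy**2 + 1.0) * sxx
            den = 2.0 * (sx**2 + sy**2 + 1.0) ** 1.5
            H[i, j] = -num / den
    return H


def naive_edge_roughness(voxels: np.ndarray) -> float:
    """Loop-based edge roughness of a binary (x, y, z) voxel grid at 1 mm."""
    nx, ny, nz = voxels.shape
    cor = np.zeros((nx, nz), dtype=np.uint8)
    sag = np.zeros((ny, nz), dtype=np.uint8)
    for k in range(nz):
        for i in range(nx):
            for j in range(ny):
                if voxels[i, j, k]:
                    cor[i, k] = 1
                    sag[j, k] = 1
    total_abs = float(np.abs(naive_curvature(cor)).sum() + np.abs(naive_curvature(sag)).sum())
    area = int(cor.sum()) + int(sag.sum())
    return total_abs / area


def exact_fisher_two_sided(table) -> float:
    """Exhaustive two-sided Fisher p by integer hypergeometric enumeration.

    Sums P(tables with the observed margins whose probability <= observed);
    the comparison is done on exact integer numerators, the final ratio in
    floating point.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            total += w
    return total / denom
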