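"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: Gaussian
derivative kernels are sampled analytically and applied by direct 2D
correlation, eigenproblems go through ``numpy.linalg.eigh`` one pixel at a
time, and lengths are counted by exhaustive pair enumeration.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import convolve2d

SQRT2 = math.sqrt(2.0)


def _gauss_kernel_1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian (derivative) kernel, radius 4 sigma, 0th order normalized."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / sigma**2 * phi
    if order == 2:
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        return k - k.sum() * phi  # derivative kernels must annihilate constants
    raise ValueError(order)


def hessian_reference(image: np.ndarray, sigma: float):
    """Scale-normalized Hessian by direct 2D convolution with sampled kernels."""
    img = np.asarray(image, dtype=np.float64)

    def conv(oy, ox):
        k = np.outer(_gauss_kernel_1d(sigma, oy), _gauss_kernel_1d(sigma, ox))
        return convolve2d(img, k, mode="same", boundary="symm")

    return conv(2, 0) * sigma**2, conv(1, 1) * sigma**2, conv(0, 2) * sigma**2


def frangi_reference(image: np.ndarray, scales, beta=0.5, bright=True):
    """Per-pixel multiscale vesselness + orientation via explicit eigen-solves.

    Returns (vesselness, orientation_deg, ok) where ``ok`` marks pixels with
    a well-conditioned eigen gap (orientation comparable there).
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    best_v = np.zeros((h, w))
    best_theta = np.full((h, w), np.nan)
    ok = np.zeros((h, w), dtype=bool)

    for sigma in scales:
        hrr, hrc, hcc = hessian_reference(img, sigma)
        lam1 = np.empty((h, w))
        lam2 = np.empty((h, w))
        theta = np.empty((h, w))
        gap = np.empty((h, w))
        for r in range(h):
            for c in range(w):
                H = np.array([[hrr[r, c], hrc[r, c]], [hrc[r, c], hcc[r, c]]])
                vals, vecs = np.linalg.eigh(H)
                i1 = int(np.argmin(np.abs(vals)))  # smaller |lambda|
                lam1[r, c] = vals[i1]
                lam2[r, c] = vals[1 - i1]
                v = vecs[:, i1]  # (row, col) components
                theta[r, c] = math.degrees(math.atan2(v[0], v[1])) % 180.0
                gap[r, c] = abs(abs(vals[0]) - abs(vals[1]))
        s = np.sqrt(lam1**2 + lam2**2)
        c_auto = 0.5 * s.max()
        v = np.zeros((h, w))
        if c_auto > 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
            v = np.exp(-rb2 / (2 * beta**2)) * (1.0 - np.exp(-(s**2) / (2 * c_auto**2)))
        bad = (lam2 > 0) if bright else (lam2 < 0)
        v[bad | (lam2 == 0)] = 0.0
        better = v > best_v
        best_v[better] = v[better]
        best_theta[better] = theta[better]
        ok[better] = gap[better] > 1e-9 * (np.abs(hrr) + np.abs(hcc) + np.abs(hrc) + 1e-300)[better]
    return best_v, best_theta, ok


def edge_length_reference(skel: np.ndarray) -> float:
    """Exhaustive pair enumeration of the 8-neighbour edge rule.

    Axial edges count 1, diagonal edges sqrt(2); a diagonal edge is skipped
    when the pair shares an axial skeleton neighbour (corner shortcut).
    """
    coords = [tuple(p) for p in np.argwhere(np.asarray(skel, dtype=bool))]
    cset = set(coords)
    total = 0.0
    for r, c in coords:
        if (r, c + 1) in cset:
            total += 1.0
        if (r + 1, c) in cset:
            total += 1.0
        for dc in (-1, 1):
            q = (r + 1, c + dc)
            if q in cset and (r, c + dc) not in cset and (r + 1, c) not in cset:
                total += SQRT2
    return total


def vonmises_window_mass(kappa: float, half_width_deg: float = 60.0) -> float:
    """Probability mass of a centred von Mises within +/- half_width (quadrature).

    For the axial model theta = groove + phi/2, alignment within 30 deg of the
    groove corresponds to |phi| < 60 deg on the doubled circle.
    """
    from scipy.integrate import quad
    from scipy.special import i0

    a = math.radians(half_width_deg)
    if kappa == 0:
        return a / math.pi
    val, _ = quad(lambda p: math.exp(kappa * math.cos(p)) / (2 * math.pi * i0(kappa)), -a, a)
    return val
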