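"""Multiscale Frangi vesselness with per-pixel axial ridge orientation.

Neurites are thin bright curvilinear structures.  At each Gaussian scale σ
the scale-normalized Hessian (second Gaussian derivatives × σ²) is
eigen-decomposed per pixel with |λ1| ≤ |λ2|; a bright ridge has λ2 strongly
negative and λ1 ≈ 0, and runs along the eigenvector of λ1.  The Frangi
response combines a blobness ratio R_B = λ1/λ2 (low on lines, ~1 on blobs)
with a structureness energy S = sqrt(λ1² + λ2²) (low in flat noise):

    V = exp(-R_B² / 2β²) · (1 - exp(-S² / 2c²)),   V = 0 where λ2 > 0

for bright ridges.  The final per-pixel vesselness is the maximum over
scales, and the orientation is the ridge direction at that argmax scale,
stored as an axial angle in [0, 180) degrees (θ and θ+180° are the same
orientation).

Alignment with the nanogroove axis is then a circular-window statistic:
the percentage of neurite-skeleton pixels whose axial distance to the
groove angle is strictly below 30°.  Under isotropy this window covers
60°/180° of the axial range, i.e. an expected 33% baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# relative scale below which the two Hessian eigenvalues are considered
# tied; tied pixels have no defined ridge direction
_EIGEN_TIE_RTOL = 1e-12


@dataclass
class FrangiParams:
    """Knobs of the multiscale vesselness filter.

    ``scales_px`` should span the expected neurite half-widths in pixels;
    ``beta`` is the blobness sensitivity (0.5 is the common choice);
    ``c_mode='auto'`` sets the structureness scale c to half the maximum
    S at each scale, ``'fixed'`` uses ``c_value``.
    """

    scales_px: tuple[float, ...] = (1.0, 2.0, 3.0)
    beta: float = 0.5
    c_mode: str = "auto"
    c_value: float = 1.0
    bright_ridges: bool = True

    def __post_init__(self) -> None:
        self.scales_px = tuple(float(s) for s in self.scales_px)
        if not self.scales_px:
            raise ValueError("scales_px must be non-empty")
        if any(s <= 0 for s in self.scales_px):
            raise ValueError(f"scales must be strictly positive, got {self.scales_px}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.c_mode not in ("auto", "fixed"):
            raise ValueError(f"c_mode must be 'auto' or 'fixed', got {self.c_mode!r}")
        if self.c_mode == "fixed" and not (self.c_value > 0):
            raise ValueError(f"c_value must be > 0, got {self.c_value}")


@dataclass
class OrientationField:
    """Per-pixel vesselness in [0, 1], axial orientation and argmax scale.

    ``orientation_deg`` is NaN where no ridge direction is defined (zero
    vesselness or tied eigenvalues); such pixels never contribute to the
    alignment statistic.
    """

    vesselness: np.ndarray
    orientation_deg: np.ndarray
    best_scale_px: np.ndarray


@dataclass
class AlignmentResult:
    """Percentage of outgrowth aligned with the groove axis.

    ``aligned_pct`` is None (reported as missing) when there is no skeleton
    support at all — an empty slice has no outgrowth to be aligned.
    """

    aligned_pct: float | None
    threshold_deg: float = 30.0
    support_px: int = 0


def _gauss_deriv_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel (radius 4σ) that annihilates constants.

    The truncated second-derivative kernel does not sum exactly to zero, so
    a raw application gives a constant image a spurious nonzero Hessian; the
    residual sum is redistributed along the Gaussian envelope to restore the
    defining property of a derivative filter.
    """
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / sigma**2 * phi  # antisymmetric: sums to zero exactly
    k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
    return k - k.sum() * phi


def scale_normalized_hessian(image: np.ndarray, sigma: float):
    """Second Gaussian derivatives × σ², as (Hrr, Hrc, Hcc) with r=y, c=x."""
    img = np.asarray(image, dtype=np.float64)
    k0 = _gauss_deriv_kernel(sigma, 0)
    k1 = _gauss_deriv_kernel(sigma, 1)
    k2 = _gauss_deriv_kernel(sigma, 2)

    def sep(krow, kcol):
        out = ndimage.correlate1d(img, krow, axis=0, mode="reflect")
        return ndimage.correlate1d(out, kcol, axis=1, mode="reflect")

    hrr = sep(k2, k0) * sigma**2
    hrc = sep(k1, k1) * sigma**2
    hcc = sep(k0, k2) * sigma**2
    return hrr, hrc, hcc


def _eigen_ridge(hrr, hrc, hcc):
    """Closed-form 2×2 symmetric eigen-solve, vectorized.

    Returns (lam1, lam2, theta_deg) with |lam1| <= |lam2|; theta is the
    direction of the lam1-eigenvector (the along-ridge direction), axial in
    [0, 180), NaN where the eigenvalues tie.
    """
    mean = 0.5 * (hrr + hcc)
    half = 0.5 * (hrr - hcc)
    disc = np.sqrt(half**2 + hrc**2)
    la = mean + disc
    lb = mean - disc
    a_small = np.abs(la) <= np.abs(lb)
    lam1 = np.where(a_small, la, lb)
    lam2 = np.where(a_small, lb, la)

    # eigenvector of lam1: both (hrc, lam1-hrr) and (lam1-hcc, hrc) solve
    # (H - lam1 I) v = 0; pick the better-conditioned one per pixel
    v1r, v1c = hrc, lam1 - hrr
    v2r, v2c = lam1 - hcc, hrc
    use_1 = (v1r**2 + v1c**2) >= (v2r**2 + v2c**2)
    vr = np.where(use_1, v1r, v2r)
    vc = np.where(use_1, v1c, v2c)
    theta = np.degrees(np.arctan2(vr, vc)) % 180.0

    scale = np.abs(hrr) + np.abs(hcc) + np.abs(hrc)
    tied = disc <= _EIGEN_TIE_RTOL * np.maximum(scale, np.finfo(np.float64).tiny)
    theta = np.where(tied, np.nan, theta)
    return lam1, lam2, theta


def frangi_orientation(image: np.ndarray, params: FrangiParams | None = None) -> OrientationField:
    """Compute the multiscale vesselness and ridge-orientation maps.

    A constant image yields all-zero vesselness and undefined orientation
    everywhere (not an error).
    """
    if params is None:
        params = FrangiParams()
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")

    best_v = np.zeros(img.shape, dtype=np.float64)
    best_theta = np.full(img.shape, np.nan)
    best_scale = np.full(img.shape, np.nan)

    for sigma in params.scales_px:
        hrr, hrc, hcc = scale_normalized_hessian(img, sigma)
        lam1, lam2, theta = _eigen_ridge(hrr, hrc, hcc)
        s2 = lam1**2 + lam2**2

        if params.c_mode == "auto":
            c = 0.5 * np.sqrt(s2.max())
            # numerically flat at this scale: max S is floating-point dust
            if c <= 1e-10 * max(1.0, float(np.abs(img).max())):
                c = 0.0
        else:
            c = params.c_value

        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(lam2 != 0, (lam1 / lam2) ** 2, 0.0)
        if c > 0:
            v = np.exp(-rb2 / (2.0 * params.beta**2)) * (1.0 - np.exp(-s2 / (2.0 * c**2)))
        else:  # flat image at this scale: no structure anywhere
            v = np.zeros_like(img)

        wrong_sign = lam2 > 0 if params.bright_ridges else lam2 < 0
        v = np.where(wrong_sign | (lam2 == 0), 0.0, v)

        better = v > best_v
        best_v = np.where(better, v, best_v)
        best_theta = np.where(better, theta, best_theta)
        best_scale = np.where(better, sigma, best_scale)

    # pixels that never scored keep NaN orientation
    best_theta = np.where(best_v > 0, best_theta, np.nan)
    best_scale = np.where(best_v > 0, best_scale, np.nan)
    return OrientationField(best_v, best_theta, best_scale)


def axial_delta(theta_deg, groove_angle_deg):
    """Axial angular distance in [0, 90] degrees (180°-periodic).

    Works elementwise on arrays; NaN propagates.
    """
    d = np.abs(np.asarray(theta_deg, dtype=np.float64) - groove_angle_deg) % 180.0
    out = np.minimum(d, 180.0 - d)
    if np.ndim(theta_deg) == 0:
        return float(out)
    return out


#: minimum pixels a skeleton segment needs before its orientations are pooled
_MIN_SEGMENT_SMOOTH_PX = 3
#: junction-to-junction stubs shorter than this (edge-rule px) are crossing
#: artifacts, not outgrowth, and are removed from the alignment support
_BRIDGE_MAX_PX = 6.0


def _segment_smoothed_orientation(field: OrientationField, skeleton):
    """Orientation regularized along skeleton segments, plus refined support.

    Each sufficiently long segment's pixels are assigned the segment's
    axial circular mean (computed on doubled angles).  This keeps the
    Hessian orientations but removes the pixel-level jitter that rasterized
    filaments induce.  Pixels where crossing filaments make the ridge
    direction meaningless — junction pixels and short junction-to-junction
    bridge stubs — are dropped from the support.

    Returns ``(theta, keep)``: the smoothed orientation map and a boolean
    mask of skeleton pixels retained in the support.
    """
    theta = field.orientation_deg.copy()
    skel = np.asarray(skeleton.skeleton, dtype=bool)
    keep = skel.copy()
    # 8-neighbour count; skeleton pixels with >= 3 neighbours are junctions
    nb = ndimage.convolve(skel.astype(np.int8), np.ones((3, 3), np.int8), mode="constant")
    junction = skel & (nb - 1 >= 3)
    for seg in skeleton.segments:
        path = seg.path
        if junction[tuple(path[0])] and junction[tuple(path[-1])]:
            steps = np.abs(np.diff(path, axis=0))
            length_px = float(np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0).sum())
            if length_px < _BRIDGE_MAX_PX:
                keep[path[:, 0], path[:, 1]] = False
                continue
        vals = field.orientation_deg[path[:, 0], path[:, 1]]
        ok = np.isfinite(vals)
        if ok.sum() < _MIN_SEGMENT_SMOOTH_PX:
            continue
        doubled = np.radians(2.0 * vals[ok])
        mean = 0.5 * np.degrees(
            np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
        ) % 180.0
        theta[path[:, 0], path[:, 1]] = mean
    keep &= ~junction
    return theta, keep


def alignment_fraction(
    field: OrientationField,
    skeleton,
    groove_angle_deg: float,
    threshold_deg: float = 30.0,
    smooth_segments: bool = True,
) -> AlignmentResult:
    """Percentage of skeleton pixels aligned within ``threshold_deg`` of the groove.

    Support is the set of skeleton pixels with a defined orientation, so the
    statistic is length-weighted in effect (each centreline pixel votes once,
    thick filaments do not vote with their area).  The inequality is strict:
    a pixel exactly at the threshold counts as NOT aligned.

    When ``skeleton`` carries segment paths (a
    :class:`~groovescreen.neurites.NeuriteSkeleton`) and ``smooth_segments``
    is true, per-pixel orientations are first pooled along each segment
    (axial circular mean); a bare boolean mask is used as-is.
    """
    mask = np.asarray(getattr(skeleton, "skeleton", skeleton), dtype=bool)
    if mask.shape != field.orientation_deg.shape:
        raise ValueError(
            f"skeleton shape {mask.shape} != orientation field shape "
            f"{field.orientation_deg.shape}"
        )
    if smooth_segments and getattr(skeleton, "segments", None):
        theta, keep = _segment_smoothed_orientation(field, skeleton)
        support = keep & np.isfinite(theta)
        if not support.any():  # all support was junction furniture; fall back
            support = mask & np.isfinite(theta)
    else:
        theta = field.orientation_deg
        support = mask & np.isfinite(theta)
    n = int(support.sum())
    if n == 0:
        return AlignmentResult(None, threshold_deg, 0)
    delta = axial_delta(theta[support], groove_angle_deg)
    pct = 100.0 * float(np.count_nonzero(delta < threshold_deg)) / n
    return AlignmentResult(pct, threshold_deg, n)


def aligned_percentage(
    orientations_deg, groove_angle_deg: float, threshold_deg: float = 30.0
) -> float:
    """Alignment percentage of a bare orientation sample (strict inequality)."""
    theta = np.asarray(orientations_deg, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("empty orientation sample")
    delta = axial_delta(theta, groove_angle_deg)
    return 100.0 * float(np.count_nonzero(delta < threshold_deg)) / theta.size
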