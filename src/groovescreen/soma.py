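"""Per-slice cell-body (soma) detection, counting and subtraction masks.

The pipeline needs somas for two things: the per-slice cell count, and a
mask to subtract from the image so only outgrowths feed the orientation
statistics.  The detector is deliberately classical: Gaussian smooth →
threshold (Otsu by default) → morphological opening to detach thin
neurites → connected components → area band → optional watershed split of
touching somas.  Components larger than the area band (dense cell
clusters) are excluded from the count but kept in the subtraction mask,
since unsubtracted cluster texture would corrupt orientation estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

logger = logging.getLogger(__name__)


@dataclass
class SomaParams:
    smoothing_sigma_px: float = 2.0
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.0
    min_soma_area_px: int = 60
    max_soma_area_px: int = 5000
    split_touching: bool = True
    # Otsu always splits a histogram, even of pure background noise; require
    # the threshold to clear the sub-threshold mean by this many of its SDs
    min_contrast_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.smoothing_sigma_px < 0 or not math.isfinite(self.smoothing_sigma_px):
            raise ValueError(f"smoothing_sigma_px must be finite and >= 0, got {self.smoothing_sigma_px}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"threshold_method must be 'otsu' or 'fixed', got {self.threshold_method!r}")
        if self.min_soma_area_px < 1:
            raise ValueError(f"min_soma_area_px must be >= 1, got {self.min_soma_area_px}")
        if self.max_soma_area_px <= self.min_soma_area_px:
            raise ValueError("max_soma_area_px must exceed min_soma_area_px")


@dataclass
class SomaLabelMap:
    """Labelled somas plus the (larger) subtraction mask.

    ``labels`` has 0 for background and 1..count for in-band somas.
    ``mask`` additionally includes over-sized components (clusters) that are
    not counted but must still be subtracted before orientation analysis.
    """

    labels: np.ndarray
    count: int
    centroids: list[tuple[float, float]] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.labels > 0


def _opening_radius(min_area: int) -> int:
    # disk radius ~ half the minimum soma radius: detaches 1-2 px neurites
    # while leaving in-band somas intact
    return max(1, math.ceil(math.sqrt(min_area / math.pi) / 2.0))


def detect_cell_bodies(image: np.ndarray, params: SomaParams | None = None) -> SomaLabelMap:
    """Detect and label cell bodies in one slice.

    A constant slice under Otsu thresholding returns count 0 with a logged
    notice (there is nothing to threshold) rather than failing.
    """
    if params is None:
        params = SomaParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D slice, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)):
        raise ValueError("slice must be finite")
    if img.min() < 0:
        raise ValueError("slice must be non-negative")

    empty = SomaLabelMap(np.zeros(img.shape, dtype=np.int32), 0, [], np.zeros(img.shape, bool))

    smoothed = ndimage.gaussian_filter(img, params.smoothing_sigma_px) if params.smoothing_sigma_px > 0 else img
    if params.threshold_method == "otsu":
        if smoothed.max() == smoothed.min():
            logger.info("constant slice: Otsu undefined, reporting 0 somas")
            return empty
        thr = threshold_otsu(smoothed)
        # robust background width: the low side is mostly background, so the
        # MAD ignores the smoothed halo tail around true objects
        low = smoothed[smoothed <= thr]
        med = float(np.median(low))
        mad_sigma = 1.4826 * float(np.median(np.abs(low - med)))
        if (thr - med) < params.min_contrast_sigma * mad_sigma:
            logger.info("no foreground contrast above background noise: 0 somas")
            return empty
    else:
        thr = params.fixed_threshold
    fg = smoothed > thr
    if not fg.any():
        return empty

    opened = ndimage.binary_opening(fg, structure=disk(_opening_radius(params.min_soma_area_px)))
    if not opened.any():
        return empty

    lab = label(opened, connectivity=2)
    areas = np.bincount(lab.ravel())
    small = areas < params.min_soma_area_px
    big = areas > params.max_soma_area_px
    small[0] = big[0] = False

    # subtraction mask keeps the big clusters, drops speck components
    mask = opened & ~small[lab]
    in_band = opened & ~small[lab] & ~big[lab]

    if not in_band.any():
        return SomaLabelMap(np.zeros(img.shape, dtype=np.int32), 0, [], mask)

    if params.split_touching:
        seg = _split_touching(in_band, params)
    else:
        seg = label(in_band, connectivity=2)

    # re-apply the lower area bound (watershed fragments can dip below it)
    final = np.zeros(img.shape, dtype=np.int32)
    centroids: list[tuple[float, float]] = []
    n = 0
    for region in regionprops(seg):
        if region.area < params.min_soma_area_px:
            continue
        n += 1
        final[seg == region.label] = n
        centroids.append(tuple(region.centroid))
    return SomaLabelMap(final, n, centroids, mask)


def _split_touching(in_band: np.ndarray, params: SomaParams) -> np.ndarray:
    """Watershed on the distance transform, seeded at its local maxima."""
    dist = ndimage.distance_transform_edt(in_band)
    min_dist = max(1, int(round(math.sqrt(params.min_soma_area_px / math.pi))))
    comp = label(in_band, connectivity=2)
    # light smoothing kills spurious plateau maxima on lumpy masks
    peaks = peak_local_max(
        ndimage.gaussian_filter(dist, 1.0), min_distance=min_dist,
        labels=comp, exclude_border=False,
    )
    if len(peaks) == 0:
        return comp
    # deterministic marker ids: lexicographic (y, x) order
    order = np.lexsort((peaks[:, 1], peaks[:, 0]))
    peaks = peaks[order]
    markers = np.zeros(in_band.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=in_band)
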