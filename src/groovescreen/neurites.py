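"""Outgrowth-only image, neurite skeletons and physical length.

After soma subtraction the slice contains only outgrowths.  The neurite
mask is the thresholded vesselness map restricted to unsubtracted pixels;
it is skeletonized to one-pixel centrelines, short terminal branches and
speck components are pruned, and length is measured in physical units by
the 8-neighbour edge rule: an axial step between skeleton pixels counts
1 pixel, a diagonal step sqrt(2) pixels.  Diagonal edges that merely
shortcut an axially connected corner (the two pixels already share an
axial skeleton neighbour) are not counted, so an L-shaped path of 35 axial
edges measures exactly 35 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label
from scipy import ndimage
from skimage.morphology import skeletonize

from .orientation import OrientationField
from .soma import SomaLabelMap

_SQRT2 = math.sqrt(2.0)
_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class NeuriteParams:
    body_dilation_px: int = 2
    vesselness_threshold: float = 0.15
    min_branch_length_px: float = 4.0
    min_component_length_px: float = 10.0
    # vesselness is contrast-normalized per slice, so a structureless slice
    # would still score its noise; skeleton components whose mean intensity
    # is not this many robust SDs above the background median are discarded
    # (0 disables)
    min_intensity_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.body_dilation_px < 0:
            raise ValueError(f"body_dilation_px must be >= 0, got {self.body_dilation_px}")
        if not (0 < self.vesselness_threshold <= 1):
            raise ValueError(
                f"vesselness_threshold must be in (0, 1], got {self.vesselness_threshold}"
            )
        if self.min_branch_length_px < 0 or self.min_component_length_px < 0:
            raise ValueError("pruning lengths must be >= 0")


@dataclass
class SkeletonSegment:
    """One skeleton path between branch/end points."""

    path: np.ndarray  # (n, 2) array of (row, col)
    length_um: float
    chord_orientation_deg: float | None  # None for degenerate (closed) chords


@dataclass
class NeuriteSkeleton:
    skeleton: np.ndarray  # bool image of 1-px centrelines
    total_length_um: float
    segments: list[SkeletonSegment] = field(default_factory=list)


def dilated_body_mask(bodies: SomaLabelMap, dilation_px: int) -> np.ndarray:
    """The subtraction footprint: body mask grown by ``dilation_px``.

    Growth is Chebyshev (square footprint): a 5x5 body grown by 1 zeroes
    exactly its 7x7 neighbourhood.
    """
    mask = np.asarray(bodies.mask, dtype=bool)
    if dilation_px > 0 and mask.any():
        size = 2 * dilation_px + 1
        mask = ndimage.binary_dilation(mask, structure=np.ones((size, size), bool))
    return mask


def subtract_cell_bodies(
    image: np.ndarray, bodies: SomaLabelMap, params: NeuriteParams | None = None
) -> np.ndarray:
    """Zero out the (dilated) cell-body mask, leaving outgrowths only."""
    if params is None:
        params = NeuriteParams()
    img = np.asarray(image)
    mask = np.asarray(bodies.mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != body mask shape {mask.shape}")
    out = img.copy()
    out[dilated_body_mask(bodies, params.body_dilation_px)] = 0
    return out


def fill_cell_bodies(
    image: np.ndarray, bodies: SomaLabelMap, params: NeuriteParams | None = None
) -> np.ndarray:
    """Replace the (dilated) cell-body mask with the background estimate.

    The vesselness pass runs on this image rather than the zeroed one: a
    zero-filled disk leaves a step edge whose bright side scores as a
    circular ridge, and bright soma rims would otherwise dominate the
    automatic structureness scale and suppress dim neurites.  The
    background estimate is the median intensity outside the mask.
    """
    if params is None:
        params = NeuriteParams()
    img = np.asarray(image, dtype=np.float64)
    mask = dilated_body_mask(bodies, params.body_dilation_px)
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != body mask shape {mask.shape}")
    if not mask.any():
        return img.copy()
    bg = float(np.median(img[~mask])) if (~mask).any() else 0.0
    out = img.copy()
    out[mask] = bg
    return out


def skeleton_edge_length_px(skel: np.ndarray) -> float:
    """Total edge-rule length of a skeleton mask, in pixels."""
    s = np.asarray(skel, dtype=bool)
    axial = int((s[:, 1:] & s[:, :-1]).sum()) + int((s[1:, :] & s[:-1, :]).sum())
    # diagonal "\": pair (r,c)-(r+1,c+1); shared axial neighbours (r,c+1),(r+1,c)
    d1 = s[:-1, :-1] & s[1:, 1:] & ~(s[:-1, 1:] | s[1:, :-1])
    # diagonal "/": pair (r,c+1)-(r+1,c); shared axial neighbours (r,c),(r+1,c+1)
    d2 = s[:-1, 1:] & s[1:, :-1] & ~(s[:-1, :-1] | s[1:, 1:])
    return axial + _SQRT2 * (int(d1.sum()) + int(d2.sum()))


def _adjacency(skel: np.ndarray) -> dict:
    coords = set(map(tuple, np.argwhere(skel)))
    adj = {}
    for p in coords:
        nbrs = []
        for dr, dc in _OFFSETS:
            q = (p[0] + dr, p[1] + dc)
            if q in coords:
                nbrs.append(q)
        adj[p] = sorted(nbrs)
    return adj


def _path_length_px(path) -> float:
    total = 0.0
    for (r0, c0), (r1, c1) in zip(path, path[1:]):
        total += _SQRT2 if (r0 != r1 and c0 != c1) else 1.0
    return total


def decompose_segments(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Split a skeleton into pixel paths between branch points and endpoints.

    Isolated cycles come back as closed paths.  Traversal order is
    deterministic (lexicographic in (row, col)).
    """
    adj = _adjacency(skel)
    deg = {p: len(n) for p, n in adj.items()}
    visited: set[frozenset] = set()
    paths: list[list[tuple[int, int]]] = []

    def walk(start, first):
        path = [start, first]
        visited.add(frozenset((start, first)))
        prev, cur = start, first
        while deg[cur] == 2:
            nxt = next((q for q in adj[cur] if q != prev), None)
            if nxt is None or frozenset((cur, nxt)) in visited:
                break
            visited.add(frozenset((cur, nxt)))
            path.append(nxt)
            prev, cur = cur, nxt
        return path

    nodes = sorted(p for p, d in deg.items() if d != 2)
    for p in nodes:
        for q in adj[p]:
            if frozenset((p, q)) not in visited:
                paths.append(walk(p, q))
    # leftover degree-2 pixels belong to closed cycles
    for p in sorted(adj):
        if deg[p] != 2:
            continue
        for q in adj[p]:
            if frozenset((p, q)) not in visited:
                paths.append(walk(p, q))
    for p in sorted(adj):  # isolated single pixels
        if deg[p] == 0:
            paths.append([p])
    return paths


def _chord_orientation(path) -> float | None:
    (r0, c0), (r1, c1) = path[0], path[-1]
    dr, dc = r1 - r0, c1 - c0
    if dr == 0 and dc == 0:
        return None
    return math.degrees(math.atan2(dr, dc)) % 180.0


def _remove_nubs(skel: np.ndarray) -> np.ndarray:
    """Drop redundant pixels whose neighbours stay connected without them.

    These "nubs" are one-pixel remnants that branch pruning leaves at
    junctions.  True line pixels are never nubs (their two sides are only
    connected through them), so digital straight lines are untouched.
    """
    out = skel.copy()
    adj = _adjacency(out)
    changed = True
    while changed:
        changed = False
        for p in sorted(adj):
            if not out[p]:
                continue
            nbrs = [q for q in adj[p] if out[q]]
            if len(nbrs) < 2:
                continue
            # connectivity of the neighbour set without p
            comp = {nbrs[0]}
            frontier = [nbrs[0]]
            while frontier:
                q = frontier.pop()
                for s in nbrs:
                    if s not in comp and max(abs(s[0] - q[0]), abs(s[1] - q[1])) <= 1:
                        comp.add(s)
                        frontier.append(s)
            if len(comp) == len(nbrs):
                out[p] = False
                changed = True
    return out


def prune_skeleton(skel: np.ndarray, min_branch_length_px: float) -> np.ndarray:
    """Remove terminal branches shorter than the given edge-rule length."""
    if min_branch_length_px <= 0 or not skel.any():
        return skel
    adj = _adjacency(skel)
    deg = {p: len(n) for p, n in adj.items()}
    out = skel.copy()
    for path in decompose_segments(skel):
        if len(path) < 2:
            continue
        d0, d1 = deg[path[0]], deg[path[-1]]
        terminal = (d0 == 1 and d1 >= 3) or (d1 == 1 and d0 >= 3)
        if terminal and _path_length_px(path) < min_branch_length_px:
            keep = path[-1] if d1 >= 3 else path[0]
            for p in path:
                if p != keep:
                    out[p] = False
    return _remove_nubs(out)


def _drop_short_components(skel: np.ndarray, min_length_px: float) -> np.ndarray:
    if min_length_px <= 0 or not skel.any():
        return skel
    lab = label(skel, connectivity=2)
    out = skel.copy()
    for i in range(1, lab.max() + 1):
        comp = lab == i
        if skeleton_edge_length_px(comp) < min_length_px:
            out[comp] = False
    return out


def measure_skeleton(skel: np.ndarray, pixel_size_xy: float) -> NeuriteSkeleton:
    """Measure a binary skeleton: total edge-rule length and chord segments."""
    s = np.asarray(skel, dtype=bool)
    total_um = skeleton_edge_length_px(s) * pixel_size_xy
    segments = [
        SkeletonSegment(
            path=np.asarray(path, dtype=np.int64).reshape(-1, 2),
            length_um=_path_length_px(path) * pixel_size_xy,
            chord_orientation_deg=_chord_orientation(path),
        )
        for path in decompose_segments(s)
        if len(path) >= 2
    ]
    return NeuriteSkeleton(s, total_um, segments)


def extract_skeleton(
    outgrowth_image: np.ndarray,
    field: OrientationField,
    params: NeuriteParams | None = None,
    pixel_size_xy: float = 1.0,
) -> NeuriteSkeleton:
    """Threshold vesselness on the outgrowth-only image and skeletonize.

    The vesselness field is computed on the original slice (soma rims then
    fall inside the subtracted region); restricting to nonzero pixels of the
    subtracted image applies the body mask at thresholding time.  An empty
    mask yields an empty skeleton with length 0.
    """
    if params is None:
        params = NeuriteParams()
    img = np.asarray(outgrowth_image)
    if img.shape != field.vesselness.shape:
        raise ValueError(
            f"outgrowth image shape {img.shape} != vesselness shape {field.vesselness.shape}"
        )
    mask = (field.vesselness >= params.vesselness_threshold) & (img > 0)
    skel = skeletonize(mask)
    skel = prune_skeleton(skel, params.min_branch_length_px)
    skel = _drop_short_components(skel, params.min_component_length_px)
    skel = _drop_dim_components(skel, img, params.min_intensity_sigma)
    return measure_skeleton(skel, pixel_size_xy)


def _drop_dim_components(skel: np.ndarray, img: np.ndarray, k_sigma: float) -> np.ndarray:
    """Discard skeleton components not clearly brighter than the background."""
    if k_sigma <= 0 or not skel.any():
        return skel
    flat = np.asarray(img, dtype=np.float64)
    bg = float(np.median(flat))
    cut = bg + k_sigma * 1.4826 * float(np.median(np.abs(flat - bg)))
    lab = label(skel, connectivity=2)
    out = skel.copy()
    for i in range(1, lab.max() + 1):
        comp = lab == i
        if flat[comp].mean() <= cut:
            out[comp] = False
    return out
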