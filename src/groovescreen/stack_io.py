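"""Calibrated confocal z-stack I/O and depth-interval slice selection.

A z-stack is a series of optical sections at a fixed z increment above the
nanogrooved substrate.  The screening pipeline does not analyze every
section: it samples slices at a fixed physical interval (1.8 µm by default)
starting at the substrate plane, which for a 300 nm z-step means every 6th
slice.  Stacks travel as plain multi-page grayscale TIFF; calibration
(pixel size, z-step) is supplied by the caller because TIFF metadata
dialects are unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: intensity dtypes accepted on read; everything else is rejected loudly
SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


class StackFormatError(ValueError):
    """Raised for TIFFs the pipeline does not support (RGB, exotic dtypes...)."""


@dataclass
class ImageStack:
    """A 3D intensity grid with physical calibration.

    Axis order is (z, y, x); slice 0 is the substrate surface by default
    (the stacks are acquired bottom-up from the nanogrooved substrate).

    Parameters
    ----------
    voxels
        Non-negative intensity grid, shape (n_slices, height, width).
    pixel_size_xy
        In-plane calibration, µm per pixel (> 0).
    z_step_um
        Axial calibration, µm per slice (> 0).
    substrate_index
        Index of the slice at the substrate surface; depth profiles are
        reported as distances from this plane.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step_um: float
    substrate_index: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={self.voxels.ndim}")
        if any(s < 1 for s in self.voxels.shape):
            raise ValueError(f"all stack dimensions must be >= 1, got {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels.astype(np.float64, copy=False))):
            raise ValueError("stack intensities must be finite")
        if self.voxels.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        if not (self.pixel_size_xy > 0):
            raise ValueError(f"pixel_size_xy must be > 0, got {self.pixel_size_xy}")
        if not (self.z_step_um > 0):
            raise ValueError(f"z_step_um must be > 0, got {self.z_step_um}")
        if not (0 <= self.substrate_index < self.n_slices):
            raise ValueError(
                f"substrate_index {self.substrate_index} outside [0, {self.n_slices})"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_float(self, index: int) -> np.ndarray:
        """One slice promoted to float64 for filtering (raw dtype untouched)."""
        return self.voxels[index].astype(np.float64)


@dataclass
class SlicePlan:
    """Slices selected for analysis at a fixed physical interval.

    ``z_um[i] = (indices[i] - substrate_index) * z_step_um``.
    """

    interval_um: float
    indices: list[int] = field(default_factory=list)
    z_um: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.interval_um > 0):
            raise ValueError(f"interval_um must be > 0, got {self.interval_um}")
        if len(self.indices) != len(self.z_um):
            raise ValueError("indices and z_um must have equal length")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("indices must be strictly increasing")


def read_stack(
    path,
    pixel_size_xy: float,
    z_step_um: float,
    substrate_index: int = 0,
    name: str = "",
) -> ImageStack:
    """Read a single-channel multi-page TIFF as an :class:`ImageStack`.

    The page count becomes the slice count; intensities are kept in their
    on-disk dtype (8/16-bit unsigned or 32-bit float) with no resampling.
    """
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        spp = page.samplesperpixel
        if spp != 1:
            raise StackFormatError(
                f"{path}: multi-sample pages not supported (samplesperpixel={spp}); "
                "supply one channel per file"
            )
        arr = tf.asarray()
    if arr.ndim == 2:  # single page -> degenerate 1-slice stack
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise StackFormatError(f"{path}: expected 2D/3D grayscale data, got shape {arr.shape}")
    if arr.dtype not in [np.dtype(d) for d in SUPPORTED_DTYPES]:
        raise StackFormatError(
            f"{path}: unsupported dtype {arr.dtype}; expected one of "
            + ", ".join(np.dtype(d).name for d in SUPPORTED_DTYPES)
        )
    if not name:
        name = str(path)
    return ImageStack(arr, pixel_size_xy, z_step_um, substrate_index, name)


def write_stack(stack: ImageStack, path) -> None:
    """Write the stack as a multi-page grayscale TIFF, one page per slice."""
    tifffile.imwrite(path, stack.voxels, photometric="minisblack")


def slice_stride(interval_um: float, z_step_um: float) -> int:
    """Nearest-integer slice stride for a physical interval, clamped at 1."""
    k = int(round(interval_um / z_step_um))
    if k < 1:
        logger.info(
            "interval %.3g um below z-step %.3g um; analyzing every slice", interval_um, z_step_um
        )
        k = 1
    return k


def select_slices(stack: ImageStack, interval_um: float) -> SlicePlan:
    """Select every k-th slice from the substrate upward.

    k = max(1, round(interval_um / z_step_um)); the substrate slice is always
    included and distances are reported from it in µm.
    """
    if not (interval_um > 0):
        raise ValueError(f"interval_um must be > 0, got {interval_um}")
    k = slice_stride(interval_um, stack.z_step_um)
    indices = list(range(stack.substrate_index, stack.n_slices, k))
    z_um = [(i - stack.substrate_index) * stack.z_step_um for i in indices]
    return SlicePlan(interval_um=interval_um, indices=indices, z_um=z_um)
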