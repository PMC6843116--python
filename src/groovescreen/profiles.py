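"""Depth profiles: the per-slice pipeline assembled into tabular output.

For each slice selected at the analysis interval the pipeline runs
soma detection → vesselness/orientation → body subtraction → skeleton
extraction → alignment, producing one :class:`SliceMetrics` row:
(n_cells, total_outgrowth_um, alignment_pct) versus distance from the
substrate.  This is the screening method's product — cell count, outgrowth
length and alignment profiles over depth.

Alignment on a slice with no skeleton support is reported missing (empty
CSV field), not 0 or 33: a slice without outgrowth has no alignment.  By
default profiling stops after two consecutive zero-outgrowth slices,
mirroring the practice of not analyzing beyond the depth where outgrowths
vanish.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .neurites import NeuriteParams, extract_skeleton, fill_cell_bodies, subtract_cell_bodies
from .orientation import FrangiParams, alignment_fraction, frangi_orientation
from .soma import SomaParams, detect_cell_bodies
from .stack_io import ImageStack, select_slices

logger = logging.getLogger(__name__)


@dataclass
class SliceMetrics:
    slice_index: int
    z_um: float
    n_cells: int
    total_outgrowth_um: float
    alignment_pct: float | None
    support_px: int


@dataclass
class RunConfig:
    """Everything one analysis run needs besides the stack itself."""

    groove_angle_deg: float
    pixel_size_xy: float = 0.5
    z_step_um: float = 0.3
    substrate_index: int = 0
    interval_um: float = 1.8
    threshold_deg: float = 30.0
    stop_after_empty: int | None = 2
    soma: SomaParams = field(default_factory=SomaParams)
    neurite: NeuriteParams = field(default_factory=NeuriteParams)
    frangi: FrangiParams = field(default_factory=FrangiParams)

    def __post_init__(self) -> None:
        if isinstance(self.soma, dict):
            self.soma = SomaParams(**self.soma)
        if isinstance(self.neurite, dict):
            self.neurite = NeuriteParams(**self.neurite)
        if isinstance(self.frangi, dict):
            self.frangi = FrangiParams(**self.frangi)
        if not (self.interval_um > 0):
            raise ValueError(f"interval_um must be > 0, got {self.interval_um}")
        if not (0 < self.threshold_deg <= 90):
            raise ValueError(f"threshold_deg must be in (0, 90], got {self.threshold_deg}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def profile_stack(stack: ImageStack, config: RunConfig) -> list[SliceMetrics]:
    """Run the full per-slice pipeline over the selected slices.

    Deterministic for fixed inputs.  A failing stage aborts with the slice
    index named; an empty slice produces a zero/missing row instead.
    """
    plan = select_slices(stack, config.interval_um)
    logger.info(
        "profiling %s: %d slices at %.2f um interval, groove angle %.1f deg",
        stack.name or "stack", len(plan.indices), config.interval_um, config.groove_angle_deg,
    )
    rows: list[SliceMetrics] = []
    consecutive_empty = 0
    for idx, z in zip(plan.indices, plan.z_um):
        try:
            sl = stack.slice_float(idx)
            bodies = detect_cell_bodies(sl, config.soma)
            # vesselness on the body-neutralized slice: soma rims would
            # otherwise dominate the auto structureness scale
            fieldmap = frangi_orientation(fill_cell_bodies(sl, bodies, config.neurite), config.frangi)
            outgrowth = subtract_cell_bodies(sl, bodies, config.neurite)
            skel = extract_skeleton(outgrowth, fieldmap, config.neurite, stack.pixel_size_xy)
            result = alignment_fraction(
                fieldmap, skel, config.groove_angle_deg, config.threshold_deg
            )
        except ValueError as exc:
            raise ValueError(f"slice {idx} (z={z:.2f} um): {exc}") from exc
        rows.append(
            SliceMetrics(
                slice_index=idx,
                z_um=z,
                n_cells=bodies.count,
                total_outgrowth_um=skel.total_length_um,
                alignment_pct=result.aligned_pct,
                support_px=result.support_px,
            )
        )
        logger.info(
            "  slice %d (z=%.2f um): %d cells, %.1f um outgrowth, alignment %s",
            idx, z, bodies.count, skel.total_length_um,
            "n/a" if result.aligned_pct is None else f"{result.aligned_pct:.1f}%",
        )
        consecutive_empty = consecutive_empty + 1 if skel.total_length_um == 0 else 0
        if config.stop_after_empty is not None and consecutive_empty >= config.stop_after_empty:
            logger.info("stopping: %d consecutive slices without outgrowth", consecutive_empty)
            break
    return rows


def metrics_frame(metrics: list[SliceMetrics]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(m) for m in metrics])
    return df.sort_values("z_um", kind="stable").reset_index(drop=True)


def write_profile(metrics: list[SliceMetrics], path) -> None:
    """Write the profile CSV (missing alignment as an empty field, 3 decimals)."""
    if not metrics:
        raise ValueError("metrics must be nonempty")
    df = metrics_frame(metrics)
    df.to_csv(path, index=False, float_format="%.3f")


def read_profile(path) -> pd.DataFrame:
    """Parse a profile CSV back; missing alignment comes back as NaN."""
    return pd.read_csv(path)


def evaluate_against_truth(profile: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Join a measured profile with generator truth and report per-slice errors.

    Truth alignment is a fraction in [0, 1]; the profile reports percent.
    """
    merged = profile.merge(truth, on="slice_index", suffixes=("", "_truth"))
    out = merged[["slice_index"]].copy()
    out["z_um"] = merged["z_um"]
    out["cells_abs_err"] = (merged["n_cells"] - merged["true_n_cells"]).abs()
    out["outgrowth_abs_err_um"] = (
        merged["total_outgrowth_um"] - merged["true_outgrowth_um"]
    ).abs()
    out["alignment_abs_err_pct"] = (
        merged["alignment_pct"] - 100.0 * merged["true_aligned_fraction"]
    ).abs()
    return out
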