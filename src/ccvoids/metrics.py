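"""Signal-void extraction and per-region metrics (Analyze-Particles equivalent).

Signal voids are 8-connected components of void pixels inside a region,
after vessel exclusion.  The main outcome is the total signal-void area
as a percentage of the *analyzable* area (region minus excluded pixels);
the per-void area distribution (count, sizes in um^2) is also reported.
Voids are clipped, not rejected, at region boundaries so the macular
subfield partition conserves area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .binarize import TriStateMap
from .scan_model import ContractError, EmptyRegionError, ScanGeometry
from .vessel_mask import ExclusionMask

__all__ = ["VoidMetrics", "label_voids", "void_metrics", "region_void_metrics"]

# 8-connectivity, the Analyze-Particles default for this use.
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


@dataclass
class VoidMetrics:
    """Per-region signal-void summary."""

    region: str
    analyzable_area_mm2: float
    total_void_area_pct: float
    void_count: int
    void_areas_um2: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_void_area_um2: float = float("nan")
    analyzable_px: int = 0
    void_px: int = 0

    def __post_init__(self) -> None:
        self.void_areas_um2 = np.asarray(self.void_areas_um2, dtype=float)
        if not (0.0 <= self.total_void_area_pct <= 100.0):
            raise ContractError("total_void_area_pct must be in [0, 100]")
        if self.void_count != len(self.void_areas_um2):
            raise ContractError("void_count must equal len(void_areas_um2)")


def label_voids(
    tsmap: TriStateMap,
    region_mask: np.ndarray,
    min_void_px: int = 1,
) -> np.ndarray:
    """Label connected void components within a region.

    Components of ``void AND region AND NOT excluded`` under
    8-connectivity; components smaller than ``min_void_px`` pixels are
    dropped (default 1, i.e. no size filter).  Returns an integer grid
    with 0 = background and 1..k component ids.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if tsmap.shape != region_mask.shape:
        raise ContractError(
            f"map shape {tsmap.shape} != region mask shape {region_mask.shape}"
        )
    analyzable = region_mask & ~tsmap.excluded
    if not analyzable.any():
        raise EmptyRegionError("region has no analyzable pixels")
    voids = tsmap.void & analyzable
    labels, k = ndimage.label(voids, structure=_STRUCTURE_8)
    if k and min_void_px > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_void_px)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
            # re-densify ids so they stay 1..k'
            labels, _ = ndimage.label(labels > 0, structure=_STRUCTURE_8)
    return labels


def void_metrics(
    labels: np.ndarray,
    region_mask: np.ndarray,
    exclusion: ExclusionMask | None,
    geometry: ScanGeometry,
    region: str = "region",
) -> VoidMetrics:
    """Summarize labeled voids over a region.

    Analyzable area is ``(region AND NOT excluded)`` in mm^2; the total
    void percentage is void pixels over analyzable pixels; per-void areas
    are component pixel counts converted to um^2 via the squared pitch.
    """
    labels = np.asarray(labels)
    region_mask = np.asarray(region_mask, dtype=bool)
    excluded = exclusion.pixels if exclusion is not None else np.zeros_like(region_mask)
    if not (labels.shape == region_mask.shape == excluded.shape):
        raise ContractError("labels, region mask and exclusion mask must be congruent")
    analyzable = region_mask & ~excluded
    n_analyzable = int(analyzable.sum())
    if n_analyzable == 0:
        raise EmptyRegionError(f"region {region!r} has no analyzable pixels")
    counts = np.bincount(labels[labels > 0].ravel()) if (labels > 0).any() else np.zeros(1, int)
    comp_px = counts[1:][counts[1:] > 0] if counts.size > 1 else np.empty(0, int)
    px_area_um2 = geometry.pitch_um**2
    void_px = int(comp_px.sum())
    areas_um2 = comp_px.astype(float) * px_area_um2
    return VoidMetrics(
        region=region,
        analyzable_area_mm2=n_analyzable * geometry.pixel_area_mm2,
        total_void_area_pct=100.0 * void_px / n_analyzable,
        void_count=len(areas_um2),
        void_areas_um2=areas_um2,
        mean_void_area_um2=float(areas_um2.mean()) if len(areas_um2) else float("nan"),
        analyzable_px=n_analyzable,
        void_px=void_px,
    )


def region_void_metrics(
    tsmap: TriStateMap,
    region_mask: np.ndarray,
    geometry: ScanGeometry,
    region: str = "region",
    min_void_px: int = 1,
) -> VoidMetrics:
    """Convenience chain: label voids then summarize them for one region."""
    labels = label_voids(tsmap, region_mask, min_void_px=min_void_px)
    exclusion = ExclusionMask(tsmap.excluded, provenance="segmented")
    return void_metrics(labels, region_mask, exclusion, geometry, region=region)
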