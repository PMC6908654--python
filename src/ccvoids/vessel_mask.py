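"""Large superficial-vessel exclusion masks.

Major superficial retinal vessels cast shadows onto the choriocapillaris
slab that mimic flow voids, so the CC directly beneath them is excluded
from analysis.  Vessels are segmented from the paired superficial
capillary plexus (SCP) slab: global Otsu threshold on the normalized SCP
image, removal of small bright components (keeping only "major" vessels),
then a safety dilation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .binarize import EXCLUDED, TriStateMap, normalize_intensity
from .scan_model import ContractError, EnFaceImage

__all__ = ["ExclusionMask", "segment_large_vessels", "apply_exclusion"]

DEFAULT_MIN_COMPONENT_PX = 50
DEFAULT_DILATION_PX = 2


@dataclass
class ExclusionMask:
    """Boolean exclusion footprint (True = excluded from CC analysis)."""

    pixels: np.ndarray
    provenance: str = "segmented"  # "segmented" | "ground-truth"
    dilation_px: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ContractError("exclusion mask must be 2-D")
        if self.provenance not in ("segmented", "ground-truth"):
            raise ContractError("provenance must be 'segmented' or 'ground-truth'")


def segment_large_vessels(
    scp: EnFaceImage,
    min_component_px: int = DEFAULT_MIN_COMPONENT_PX,
    dilation_px: int = DEFAULT_DILATION_PX,
) -> ExclusionMask:
    """Segment major vessels from an SCP slab.

    Otsu threshold on the normalized image, 8-connected components smaller
    than ``min_component_px`` discarded, then dilation by ``dilation_px``
    (a disk structuring element) to cover the shadow penumbra.
    """
    if scp.slab != "SCP":
        raise ContractError(f"segment_large_vessels expects an SCP slab, got {scp.slab!r}")
    norm, constant = normalize_intensity(scp)
    if constant:
        mask = np.zeros(norm.shape, dtype=bool)
    else:
        mask = norm > threshold_otsu(norm)
        if min_component_px > 1:
            labels, k = ndimage.label(mask, structure=np.ones((3, 3), bool))
            if k:
                sizes = np.bincount(labels.ravel())
                keep = sizes >= min_component_px
                keep[0] = False
                mask = keep[labels]
        if dilation_px > 0:
            mask = ndimage.binary_dilation(mask, structure=disk(dilation_px))
    return ExclusionMask(mask, provenance="segmented", dilation_px=dilation_px)


def apply_exclusion(tsmap: TriStateMap, mask: ExclusionMask) -> TriStateMap:
    """Mark pixels under the exclusion mask as excluded.

    Flow/void labels elsewhere are unchanged; excluded pixels never enter
    downstream area denominators.  Idempotent, and commutes with region
    mask intersection.
    """
    if tsmap.shape != mask.pixels.shape:
        raise ContractError(
            f"map shape {tsmap.shape} != exclusion mask shape {mask.pixels.shape}"
        )
    labels = tsmap.labels.copy()
    labels[mask.pixels] = EXCLUDED
    return TriStateMap(labels)
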