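"""Topographic analysis regions in fundus coordinates.

The analysis grid comprises three zones:

* the 6-mm macular disc, split into concentric foveal (1.5-mm diameter),
  parafoveal (2.5-mm) and perifoveal (6-mm) subfields centred on the fovea;
* a 500-um-wide peripapillary annulus hugging the optic-disc margin;
* three 4.5-mm-diameter near/mid-peripheral circles externally tangent to
  the macular disc, placed superior, inferior and temporal.

Regions are defined analytically (discs/annuli in millimetres) and
rasterized onto a scan by pixel-centre membership with half-open radial
intervals (inner boundary exclusive, outer inclusive), which makes the
macular subfields an exact pixel-level partition of the 6-mm disc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .scan_model import (
    ParameterError,
    RegionCoverageError,
    ScanGeometry,
    pixel_to_fundus,
    temporal_sign,
)

__all__ = [
    "REGION_NAMES",
    "MACULAR_SUBFIELDS",
    "PERIPHERAL_CIRCLES",
    "RegionSpec",
    "macular_subfields",
    "peripapillary_ring",
    "peripheral_circles",
    "standard_regions",
    "rasterize_region",
    "select_scan_for_region",
]

MACULAR_SUBFIELDS = ("fovea", "parafovea", "perifovea")
PERIPHERAL_CIRCLES = ("periph_superior", "periph_inferior", "periph_temporal")
REGION_NAMES = MACULAR_SUBFIELDS + ("peripapillary",) + PERIPHERAL_CIRCLES

# Diameters in mm of the macular subfields and peripheral circles.
_FOVEA_R = 0.75       # 1.5-mm diameter
_PARAFOVEA_R = 1.25   # 2.5-mm diameter
_MACULA_R = 3.0       # 6-mm diameter
_PERIPH_R = 2.25      # 4.5-mm diameter
_PERIPAP_WIDTH = 0.5  # 500-um-wide annulus


@dataclass(frozen=True)
class RegionSpec:
    """A named disc or annulus in fundus millimetre coordinates."""

    name: str
    shape: str  # "disc" | "annulus"
    center_mm: tuple[float, float]
    inner_radius_mm: float
    outer_radius_mm: float

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "annulus"):
            raise ParameterError("shape must be 'disc' or 'annulus'")
        if not (0 <= self.inner_radius_mm < self.outer_radius_mm):
            raise ParameterError("need 0 <= inner_radius < outer_radius")
        if self.shape == "disc" and self.inner_radius_mm != 0:
            raise ParameterError("a disc has inner radius 0")
        object.__setattr__(self, "center_mm", (float(self.center_mm[0]), float(self.center_mm[1])))

    @property
    def area_mm2(self) -> float:
        """Closed-form area of the disc/annulus."""
        return math.pi * (self.outer_radius_mm**2 - self.inner_radius_mm**2)

    def contains(self, x, y):
        """Membership of fundus points: inner exclusive, outer inclusive."""
        d2 = (np.asarray(x) - self.center_mm[0]) ** 2 + (np.asarray(y) - self.center_mm[1]) ** 2
        inside = d2 <= self.outer_radius_mm**2
        if self.inner_radius_mm > 0:
            inside &= d2 > self.inner_radius_mm**2
        return inside

    def translated(self, delta: Sequence[float]) -> "RegionSpec":
        cx, cy = self.center_mm
        return RegionSpec(self.name, self.shape, (cx + delta[0], cy + delta[1]),
                          self.inner_radius_mm, self.outer_radius_mm)


def macular_subfields(fovea_mm: Sequence[float] = (0.0, 0.0)) -> tuple[RegionSpec, RegionSpec, RegionSpec]:
    """Foveal disc and parafoveal/perifoveal annuli centred on the fovea.

    Radii 0.75 / 1.25 / 3.0 mm (diameters 1.5, 2.5 and 6 mm).  The three
    regions partition the 6-mm macular disc.
    """
    c = (float(fovea_mm[0]), float(fovea_mm[1]))
    return (
        RegionSpec("fovea", "disc", c, 0.0, _FOVEA_R),
        RegionSpec("parafovea", "annulus", c, _FOVEA_R, _PARAFOVEA_R),
        RegionSpec("perifovea", "annulus", c, _PARAFOVEA_R, _MACULA_R),
    )


def peripapillary_ring(disc_center_mm: Sequence[float], disc_radius_mm: float) -> RegionSpec:
    """500-um-wide annulus around the optic-disc margin."""
    if not disc_radius_mm > 0:
        raise ParameterError("disc_radius_mm must be > 0")
    c = (float(disc_center_mm[0]), float(disc_center_mm[1]))
    return RegionSpec("peripapillary", "annulus", c, disc_radius_mm,
                      disc_radius_mm + _PERIPAP_WIDTH)


def peripheral_circles(fovea_mm: Sequence[float], laterality: str) -> tuple[RegionSpec, RegionSpec, RegionSpec]:
    """Three 4.5-mm circles externally tangent to the 6-mm macular disc.

    Centres sit at 3.0 + 2.25 = 5.25 mm from the fovea: superior (+y),
    inferior (-y) and temporal (the x direction implied by laterality).
    """
    tsign = temporal_sign(laterality)
    fx, fy = float(fovea_mm[0]), float(fovea_mm[1])
    d = _MACULA_R + _PERIPH_R
    return (
        RegionSpec("periph_superior", "disc", (fx, fy + d), 0.0, _PERIPH_R),
        RegionSpec("periph_inferior", "disc", (fx, fy - d), 0.0, _PERIPH_R),
        RegionSpec("periph_temporal", "disc", (fx + tsign * d, fy), 0.0, _PERIPH_R),
    )


def standard_regions(
    fovea_mm: Sequence[float],
    disc_center_mm: Sequence[float],
    disc_radius_mm: float,
    laterality: str,
) -> dict[str, RegionSpec]:
    """All seven analysis regions keyed by name."""
    regs = list(macular_subfields(fovea_mm))
    regs.append(peripapillary_ring(disc_center_mm, disc_radius_mm))
    regs.extend(peripheral_circles(fovea_mm, laterality))
    return {r.name: r for r in regs}


def _bbox_intersects(region: RegionSpec, geometry: ScanGeometry) -> bool:
    xmin, xmax, ymin, ymax = geometry.bounds_mm()
    cx, cy = region.center_mm
    r = region.outer_radius_mm
    return (cx + r >= xmin and cx - r <= xmax and cy + r >= ymin and cy - r <= ymax)


def region_fully_inside(region: RegionSpec, geometry: ScanGeometry) -> bool:
    """True when the region's outer circle lies inside the scan footprint."""
    xmin, xmax, ymin, ymax = geometry.bounds_mm()
    cx, cy = region.center_mm
    r = region.outer_radius_mm
    return (cx - r >= xmin and cx + r <= xmax and cy - r >= ymin and cy + r <= ymax)


def rasterize_region(region: RegionSpec, geometry: ScanGeometry) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the region.

    Raises :class:`RegionCoverageError` when the region does not intersect
    the scan footprint (naming the region).  Mask area (pixel count times
    squared pitch) converges to the analytic area as the pitch shrinks.
    """
    if not _bbox_intersects(region, geometry):
        raise RegionCoverageError(
            f"region {region.name!r} lies entirely outside the scan footprint"
        )
    n = geometry.pixels_per_side
    rows = np.arange(n)
    pos = pixel_to_fundus(rows[:, None], rows[None, :], geometry)
    mask = region.contains(pos[..., 0], pos[..., 1])
    if not mask.any():
        raise RegionCoverageError(
            f"region {region.name!r} covers no pixel centre on this scan"
        )
    return mask


def select_scan_for_region(
    region: RegionSpec, geometries: Mapping[str, ScanGeometry]
) -> str:
    """Pick the gaze scan on which to measure a region.

    The central scan is used whenever it fully contains the region;
    otherwise the scan whose centre is nearest the region centre wins,
    with exact distance ties broken by gaze name (lexicographic) so the
    choice is deterministic.
    """
    if not geometries:
        raise ParameterError("no scan geometries supplied")
    central = geometries.get("central")
    if central is not None and region_fully_inside(region, central):
        return "central"
    cx, cy = region.center_mm

    def _key(item):
        gaze, geom = item
        ox, oy = geom.gaze_offset_mm
        return (math.hypot(cx - ox, cy - oy), gaze)

    gaze, geom = min(geometries.items(), key=_key)
    if not _bbox_intersects(region, geom):
        raise RegionCoverageError(
            f"region {region.name!r} is outside every supplied scan footprint"
        )
    return gaze
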