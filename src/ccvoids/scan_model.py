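"""Core data types for widefield en face OCTA scans.

Defines the fundus coordinate frame used throughout the package, the scan
geometry (field of view, pixel grid, gaze offset), the per-slab en face
image container, the per-eye record, pixel <-> fundus-millimetre
conversions, and the SSI-based quality-control filter.

Coordinate convention
---------------------
Fundus positions are expressed in millimetres with the fovea at the
origin.  ``x`` increases rightward on the image and ``y`` increases
upward; image row 0 is the *top* row.  Laterality fixes the anatomical
meaning of the x axis: for an OS (left) eye temporal is ``+x``, for an OD
(right) eye temporal is ``-x`` (standard fundus orientation).  Pixels are
0-based ``(row, col)`` pairs; positions refer to pixel centres and pixel
area is the squared pitch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "GAZES",
    "SLABS",
    "LATERALITIES",
    "ParameterError",
    "ContractError",
    "OutOfFootprintError",
    "EmptyRegionError",
    "RegionCoverageError",
    "GenerationError",
    "QCError",
    "ScanGeometry",
    "EnFaceImage",
    "EyeRecord",
    "pixel_to_fundus",
    "fundus_to_pixel",
    "qc_filter",
    "temporal_sign",
    "write_scan",
    "read_scan",
]

#: Canonical gaze positions of the five partially overlapping 12x12-mm scans.
GAZES = (
    "central",
    "nasal-inferior",
    "nasal-superior",
    "temporal-inferior",
    "temporal-superior",
)

SLABS = ("CC", "SCP")
LATERALITIES = ("OD", "OS")

#: Signal-strength-index cutoff: scans with SSI below this are excluded.
DEFAULT_MIN_SSI = 8.0


class ParameterError(ValueError):
    """An argument violates a documented parameter constraint."""


class ContractError(ValueError):
    """Caller violated an operation precondition (e.g. shape mismatch)."""


class OutOfFootprintError(ValueError):
    """A fundus position lies outside the scan footprint."""


class EmptyRegionError(RuntimeError):
    """A region contains no analyzable pixels."""


class RegionCoverageError(RuntimeError):
    """A region does not intersect any available scan footprint."""


class GenerationError(RuntimeError):
    """The synthetic generator could not reach its target within budget."""


class QCError(RuntimeError):
    """Quality control left nothing to analyze."""


def temporal_sign(laterality: str) -> int:
    """Sign of the temporal direction on the x axis (+1 for OS, -1 for OD)."""
    if laterality == "OS":
        return +1
    if laterality == "OD":
        return -1
    raise ParameterError(f"unknown laterality {laterality!r}; expected OD or OS")


@dataclass(frozen=True)
class ScanGeometry:
    """Geometry of one en face scan.

    Parameters
    ----------
    field_of_view_mm:
        Side length of the square scan footprint, millimetres.
    pixels_per_side:
        Number of pixels along each side of the exported image.
    gaze_offset_mm:
        Displacement ``(x, y)`` of the scan centre from the fovea in
        fundus millimetres (the internal fixation target shift).
    laterality:
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    """

    field_of_view_mm: float = 12.0
    pixels_per_side: int = 500
    gaze_offset_mm: tuple[float, float] = (0.0, 0.0)
    laterality: str = "OD"

    def __post_init__(self) -> None:
        if not self.field_of_view_mm > 0:
            raise ParameterError("field_of_view_mm must be > 0")
        if int(self.pixels_per_side) != self.pixels_per_side or self.pixels_per_side < 2:
            raise ParameterError("pixels_per_side must be an integer >= 2")
        if self.laterality not in LATERALITIES:
            raise ParameterError(f"laterality must be one of {LATERALITIES}")
        object.__setattr__(self, "gaze_offset_mm", (float(self.gaze_offset_mm[0]), float(self.gaze_offset_mm[1])))

    @property
    def pitch_mm(self) -> float:
        """Pixel pitch (centre-to-centre spacing) in millimetres."""
        return self.field_of_view_mm / self.pixels_per_side

    @property
    def pitch_um(self) -> float:
        """Pixel pitch in micrometres (24 um for 12 mm over 500 px)."""
        return self.pitch_mm * 1000.0

    @property
    def pixel_area_mm2(self) -> float:
        return self.pitch_mm**2

    def bounds_mm(self) -> tuple[float, float, float, float]:
        """Footprint as ``(xmin, xmax, ymin, ymax)`` in fundus mm."""
        ox, oy = self.gaze_offset_mm
        half = self.field_of_view_mm / 2.0
        return (ox - half, ox + half, oy - half, oy + half)


@dataclass
class EnFaceImage:
    """A single en face slab image with its acquisition metadata.

    ``pixels`` holds non-negative intensities (any scale; the binarization
    step normalizes).  ``slab`` is ``"CC"`` (choriocapillaris) or ``"SCP"``
    (superficial capillary plexus).  ``ssi`` is the device-reported signal
    strength index used for quality control.
    """

    pixels: np.ndarray
    slab: str
    geometry: ScanGeometry
    gaze: str = "central"
    ssi: float = 10.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.slab not in SLABS:
            raise ParameterError(f"slab must be one of {SLABS}")
        if self.gaze not in GAZES:
            raise ParameterError(f"gaze must be one of {GAZES}")
        n = self.geometry.pixels_per_side
        if self.pixels.shape != (n, n):
            raise ContractError(
                f"pixels shape {self.pixels.shape} does not match geometry "
                f"({n}, {n})"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ContractError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ContractError("pixel intensities must be non-negative")


@dataclass
class EyeRecord:
    """Per-eye bundle: scans, anatomical landmarks and clinical covariates.

    ``choroidal_thickness_um`` maps region names to choroidal thickness in
    micrometres.  ``fovea_mm`` is by convention the origin of the fundus
    frame; ``disc_center_mm``/``disc_radius_mm`` give the optic-disc
    geometry used to build the peripapillary annulus.
    """

    subject_id: str
    group: str
    axial_length_mm: float
    scans: list[EnFaceImage]
    choroidal_thickness_um: dict[str, float] = field(default_factory=dict)
    fovea_mm: tuple[float, float] = (0.0, 0.0)
    disc_center_mm: tuple[float, float] = (4.5, 0.0)
    disc_radius_mm: float = 0.75

    def __post_init__(self) -> None:
        if self.group not in ("myopic", "control"):
            raise ParameterError("group must be 'myopic' or 'control'")
        if not self.axial_length_mm > 0:
            raise ParameterError("axial_length_mm must be > 0")
        if not self.disc_radius_mm > 0:
            raise ParameterError("disc_radius_mm must be > 0")
        have = {(s.slab, s.gaze) for s in self.scans}
        if ("CC", "central") not in have or ("SCP", "central") not in have:
            raise ContractError(
                "EyeRecord requires at least the central-gaze CC and SCP scans"
            )

    @property
    def laterality(self) -> str:
        return self.scans[0].geometry.laterality

    def get_scan(self, slab: str, gaze: str) -> EnFaceImage | None:
        for s in self.scans:
            if s.slab == slab and s.gaze == gaze:
                return s
        return None


# ---------------------------------------------------------------------------
# pixel <-> fundus conversions
# ---------------------------------------------------------------------------

def pixel_to_fundus(row, col, geometry: ScanGeometry) -> np.ndarray:
    """Fundus position (mm) of the centre of pixel ``(row, col)``.

    Accepts scalars or equal-shaped arrays; returns ``(..., 2)`` with
    ``[x, y]`` last.  Row 0 is the top image row, so y decreases with row.
    """
    row = np.asarray(row)
    col = np.asarray(col)
    n = geometry.pixels_per_side
    if np.any(row < 0) or np.any(row >= n) or np.any(col < 0) or np.any(col >= n):
        raise IndexError(f"pixel index outside [0, {n}) grid")
    pitch = geometry.pitch_mm
    half = geometry.field_of_view_mm / 2.0
    ox, oy = geometry.gaze_offset_mm
    x = ox + (col + 0.5) * pitch - half
    y = oy + half - (row + 0.5) * pitch
    return np.stack(np.broadcast_arrays(x, y), axis=-1)


def fundus_to_pixel(pos: Sequence[float], geometry: ScanGeometry) -> tuple[int, int]:
    """Nearest pixel ``(row, col)`` for a fundus position in mm.

    Inverse of :func:`pixel_to_fundus` up to nearest-pixel rounding.  A
    position exactly midway between two pixel centres rounds toward the
    lower index (deterministic tie rule).
    """
    x, y = float(pos[0]), float(pos[1])
    xmin, xmax, ymin, ymax = geometry.bounds_mm()
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise OutOfFootprintError(
            f"position ({x:g}, {y:g}) mm outside scan footprint "
            f"x:[{xmin:g},{xmax:g}] y:[{ymin:g},{ymax:g}]"
        )
    pitch = geometry.pitch_mm
    half = geometry.field_of_view_mm / 2.0
    ox, oy = geometry.gaze_offset_mm
    colf = (x - ox + half) / pitch - 0.5
    rowf = (oy + half - y) / pitch - 0.5

    def _round_half_down(v: float) -> int:
        # nearest integer; exact .5 ties go to the lower index
        return int(math.ceil(v - 0.5))

    n = geometry.pixels_per_side
    row = min(max(_round_half_down(rowf), 0), n - 1)
    col = min(max(_round_half_down(colf), 0), n - 1)
    return row, col


def qc_filter(scans: Iterable[EnFaceImage], min_ssi: float = DEFAULT_MIN_SSI) -> list[EnFaceImage]:
    """Retain scans with ``ssi >= min_ssi`` (order preserved, input unmodified).

    Mirrors the acquisition quality rule that scans with a signal strength
    index below 8 are excluded from analysis.
    """
    if not np.isfinite(min_ssi):
        raise ParameterError("min_ssi must be finite")
    return [s for s in scans if s.ssi >= min_ssi]


# ---------------------------------------------------------------------------
# on-disk interchange: 16-bit TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def write_scan(image: EnFaceImage, path: str | Path) -> Path:
    """Write a scan as 16-bit grayscale TIFF plus a ``.json`` sidecar.

    Intensities are assumed in [0, 1] and quantized to 16 bits (values
    outside are clipped).  The sidecar records slab, gaze, SSI, laterality
    and scan geometry so the scan round-trips.
    """
    path = Path(path)
    q = np.clip(image.pixels, 0.0, 1.0)
    tifffile.imwrite(path, np.round(q * 65535.0).astype(np.uint16))
    meta = {
        "slab": image.slab,
        "gaze": image.gaze,
        "ssi": image.ssi,
        "geometry": {
            "field_of_view_mm": image.geometry.field_of_view_mm,
            "pixels_per_side": image.geometry.pixels_per_side,
            "gaze_offset_mm": list(image.geometry.gaze_offset_mm),
            "laterality": image.geometry.laterality,
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_scan(path: str | Path) -> EnFaceImage:
    """Read a scan written by :func:`write_scan`."""
    path = Path(path)
    raw = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    g = meta["geometry"]
    geometry = ScanGeometry(
        field_of_view_mm=g["field_of_view_mm"],
        pixels_per_side=g["pixels_per_side"],
        gaze_offset_mm=tuple(g["gaze_offset_mm"]),
        laterality=g["laterality"],
    )
    return EnFaceImage(
        pixels=np.asarray(raw, dtype=float) / 65535.0,
        slab=meta["slab"],
        geometry=geometry,
        gaze=meta["gaze"],
        ssi=float(meta["ssi"]),
    )
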