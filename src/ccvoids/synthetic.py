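"""Synthetic widefield angiogram and cohort generation with known ground truth.

The study deposits no images, so the pipeline is exercised on synthetic
en face scans that emulate its statistical structure:

* a bright choriocapillaris flow texture carrying dark elliptical signal
  voids whose pixel fraction is driven to a target (within +-0.01) by
  seeded rejection placement, with void size (and mild elongation)
  increasing with distance from the fovea — mirroring the histological
  widening of inter-capillary spaces toward the periphery;
* a superficial-capillary-plexus slab holding a bright random-walk
  vessel tree whose rasterized footprint is the ground-truth shadow mask;
* five partially overlapping gaze-tiled 12x12-mm scans per eye;
* cohorts whose per-region true void fractions are drawn from log-normal
  distributions calibrated to published median/IQR values per group,
  plus axial-length and choroidal-thickness covariates.

Log-normal calibration matches the median exactly and the quartile ratio
``q3/q1``; a two-parameter log-normal cannot also match an asymmetric
IQR's absolute quartiles, and the medians are the quantities compared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation
from skimage.draw import line
from skimage.morphology import disk

from .regions import (
    PERIPHERAL_CIRCLES,
    REGION_NAMES,
    RegionSpec,
    rasterize_region,
    select_scan_for_region,
    standard_regions,
)
from .scan_model import (
    GAZES,
    EnFaceImage,
    EyeRecord,
    GenerationError,
    ParameterError,
    ScanGeometry,
    temporal_sign,
)

__all__ = [
    "CCGenParams",
    "SCPGenParams",
    "CohortGenParams",
    "MYOPIC_CALIBRATION",
    "CONTROL_CALIBRATION",
    "lognormal_from_median_iqr",
    "sd_from_median_iqr",
    "draw_void_pct",
    "gaze_offsets",
    "generate_cc_image",
    "generate_scp_image",
    "generate_cohort",
    "generate_repeat_scans",
]

_Z75 = 0.6744897501960817  # standard-normal upper quartile

# Published per-region total signal-void medians and quartiles (percent)
# used to calibrate the cohort generator: macular subfields, peripapillary
# annulus, and the three near/mid-peripheral circles, per group.
MYOPIC_CALIBRATION: dict[str, tuple[float, float, float]] = {
    "fovea": (22.5, 20.8, 24.6),
    "parafovea": (21.2, 19.7, 22.5),
    "perifovea": (21.0, 19.3, 22.8),
    "peripapillary": (24.3, 22.4, 27.3),
    "periph_superior": (23.6, 21.6, 25.1),
    "periph_inferior": (23.3, 21.6, 24.4),
    "periph_temporal": (20.9, 19.7, 23.2),
}
CONTROL_CALIBRATION: dict[str, tuple[float, float, float]] = {
    "fovea": (14.7, 12.0, 16.5),
    "parafovea": (13.1, 11.3, 15.9),
    "perifovea": (13.0, 10.8, 15.9),
    "peripapillary": (16.7, 13.5, 19.2),
    "periph_superior": (12.9, 11.6, 15.1),
    "periph_inferior": (13.2, 11.2, 16.1),
    "periph_temporal": (12.3, 11.0, 14.3),
}

#: Group axial-length distributions, mm (mean, SD).
AXIAL_LENGTH_MM = {"myopic": (26.6, 0.6), "control": (23.9, 1.1)}


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and quartile ratio."""
    if not (0 < q1 < q3) or median <= 0:
        raise ParameterError("need 0 < q1 < q3 and median > 0")
    return math.log(median), math.log(q3 / q1) / (2.0 * _Z75)


def sd_from_median_iqr(median: float, q1: float, q3: float) -> float:
    """Standard deviation of the calibrated log-normal (for power analyses)."""
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    return median * math.exp(sigma**2 / 2.0) * math.sqrt(math.exp(sigma**2) - 1.0)


def draw_void_pct(z, median: float, q1: float, q3: float):
    """Map standard-normal draws to void percentages via the calibrated fit."""
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    return np.exp(mu + sigma * np.asarray(z))


@dataclass(frozen=True)
class CCGenParams:
    """Choriocapillaris image generator parameters (intensities on [0, 1]).

    ``base_void_radius_px`` is the mean void semi-minor axis at the fovea;
    ``eccentricity_gain`` grows it per millimetre of distance from the
    fovea.  ``elongation_base``/``elongation_gain`` control the ellipse
    aspect ratio and its peripheral increase.
    """

    target_void_fraction: float = 0.2
    flow_mean: float = 0.75
    void_mean: float = 0.25
    noise_sd: float = 0.05
    base_void_radius_px: float = 2.5
    eccentricity_gain: float = 0.12
    elongation_base: float = 1.2
    elongation_gain: float = 0.08
    radius_jitter: float = 0.3
    shadow_factor: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_void_fraction <= 1.0):
            raise ParameterError("target_void_fraction must be in [0, 1]")
        if not (self.flow_mean > self.void_mean >= 0.0):
            raise ParameterError("need flow_mean > void_mean >= 0")
        if self.noise_sd < 0 or self.base_void_radius_px <= 0:
            raise ParameterError("noise_sd >= 0 and base_void_radius_px > 0 required")
        if self.eccentricity_gain < 0:
            raise ParameterError("eccentricity_gain must be >= 0")


@dataclass(frozen=True)
class SCPGenParams:
    """Superficial-plexus vessel-tree generator parameters."""

    n_branches: int = 10
    widths_px: tuple[int, ...] = (3, 5)
    vessel_intensity: float = 0.85
    background: float = 0.12
    noise_sd: float = 0.03
    step_px: int = 3
    turn_sd_rad: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 0:
            raise ParameterError("n_branches must be >= 0")
        if any(w < 1 for w in self.widths_px):
            raise ParameterError("vessel widths must be >= 1 px")


@dataclass(frozen=True)
class CohortGenParams:
    """Cohort generator: group sizes, calibrations and covariate models."""

    n_myopic: int = 30
    n_control: int = 50
    calibration: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: {"myopic": MYOPIC_CALIBRATION, "control": CONTROL_CALIBRATION}
    )
    axial_mm: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(AXIAL_LENGTH_MM))
    choroid_mean_um: float = 250.0
    choroid_sd_um: float = 50.0
    choroid_void_rho: float = -0.3
    field_of_view_mm: float = 12.0
    pixels_per_side: int = 500
    gaze_offset_mag_mm: float = 3.5
    disc_distance_mm: float = 4.5
    disc_radius_mm: float = 0.75
    vessel_margin_px: int = 2
    cc: CCGenParams = field(default_factory=CCGenParams)
    scp: SCPGenParams = field(default_factory=SCPGenParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_myopic < 1 or self.n_control < 1:
            raise ParameterError("group sizes must be >= 1")
        for group, table in self.calibration.items():
            for region, (med, q1, q3) in table.items():
                if not (0 < q1 < q3):
                    raise ParameterError(f"{group}/{region}: IQR must be positive (q1 < q3)")
                if med <= 0:
                    raise ParameterError(f"{group}/{region}: median must be > 0")
        if not (-1.0 <= self.choroid_void_rho <= 1.0):
            raise ParameterError("choroid_void_rho must be in [-1, 1]")


def gaze_offsets(laterality: str, magnitude_mm: float = 3.5) -> dict[str, tuple[float, float]]:
    """Scan-centre offsets (fundus mm) for the five fixation gazes.

    Diagonal offsets of ``magnitude_mm`` toward the four nasal/temporal x
    superior/inferior quadrants; chosen so every peripheral 4.5-mm circle
    is fully contained in at least one gaze scan at a 12-mm field.
    """
    nasal = -temporal_sign(laterality)
    m = magnitude_mm
    return {
        "central": (0.0, 0.0),
        "nasal-inferior": (nasal * m, -m),
        "nasal-superior": (nasal * m, m),
        "temporal-inferior": (-nasal * m, -m),
        "temporal-superior": (-nasal * m, m),
    }


# ---------------------------------------------------------------------------
# CC image synthesis
# ---------------------------------------------------------------------------

def _ellipse_pixels(r0: int, c0: int, semi_minor: float, aspect: float,
                    theta: float, shape: tuple[int, int]):
    """(rows, cols) of pixels inside a rotated ellipse centred on (r0, c0)."""
    a = semi_minor * aspect  # semi-major
    half = int(math.ceil(a)) + 1
    rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, shape[0])
    clo, chi = max(c0 - half, 0), min(c0 + half + 1, shape[1])
    if rlo >= rhi or clo >= chi:
        return np.empty(0, int), np.empty(0, int)
    rr = np.arange(rlo, rhi)[:, None] - r0
    cc = np.arange(clo, chi)[None, :] - c0
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * cc + st * rr
    v = -st * cc + ct * rr
    inside = (u / a) ** 2 + (v / semi_minor) ** 2 <= 1.0
    rows, cols = np.nonzero(inside)
    return rows + rlo, cols + clo


def _fill_zone(
    rng: np.random.Generator,
    void_mask: np.ndarray,
    zone_mask: np.ndarray,
    target_fraction: float,
    params: CCGenParams,
    geometry: ScanGeometry,
    fovea_mm: Sequence[float],
    tol: float = 0.01,
    max_iter: int = 60000,
) -> None:
    """Place elliptical voids inside one zone until its void pixel count
    equals ``round(target_fraction * zone_px)`` — the last void is trimmed
    to land exactly on target, well within the ``tol`` contract (mutates
    ``void_mask``)."""
    zone_px = int(zone_mask.sum())
    if zone_px == 0 or target_fraction <= 0.0:
        return
    target_px = int(round(target_fraction * zone_px))
    rows, cols = np.nonzero(zone_mask)
    current = int(np.count_nonzero(void_mask & zone_mask))
    pitch = geometry.pitch_mm
    half_fov = geometry.field_of_view_mm / 2.0
    ox, oy = geometry.gaze_offset_mm
    fx, fy = float(fovea_mm[0]), float(fovea_mm[1])
    it = 0
    while current < target_px:
        it += 1
        if it > max_iter:
            raise GenerationError(
                f"void fraction {target_fraction:.3f} unreachable in zone "
                f"({current}/{zone_px} px after {max_iter} placements)"
            )
        i = int(rng.integers(len(rows)))
        r0, c0 = int(rows[i]), int(cols[i])
        x = ox + (c0 + 0.5) * pitch - half_fov
        y = oy + half_fov - (r0 + 0.5) * pitch
        dist = math.hypot(x - fx, y - fy)
        rad = params.base_void_radius_px * (1.0 + params.eccentricity_gain * dist)
        rad *= float(rng.uniform(1.0 - params.radius_jitter, 1.0 + params.radius_jitter))
        rad = max(rad, 1.0)
        aspect = max(params.elongation_base + params.elongation_gain * dist, 1.0)
        theta = float(rng.uniform(0.0, math.pi))
        err, ecc = _ellipse_pixels(r0, c0, rad, aspect, theta, void_mask.shape)
        if err.size == 0:
            continue
        cand = zone_mask[err, ecc] & ~void_mask[err, ecc]
        err, ecc = err[cand], ecc[cand]
        if err.size == 0:
            continue
        need = target_px - current
        if err.size > need:
            # Trim the final void to land exactly on the target pixel
            # count: keep the pixels nearest the void centre.
            d2 = (err - r0) ** 2 + (ecc - c0) ** 2
            keep = np.argsort(d2, kind="stable")[:need]
            err, ecc = err[keep], ecc[keep]
        void_mask[err, ecc] = True
        current += err.size


def generate_cc_image(
    params: CCGenParams,
    geometry: ScanGeometry,
    fovea_mm: Sequence[float] = (0.0, 0.0),
    *,
    zones: Sequence[tuple[np.ndarray, float]] | None = None,
    vessel_mask: np.ndarray | None = None,
    gaze: str = "central",
    ssi: float = 10.0,
    tol: float = 0.01,
) -> tuple[EnFaceImage, np.ndarray]:
    """Generate a CC slab with a known signal-void mask.

    Without ``zones``, voids fill the whole analyzable image (minus any
    vessel footprint) to ``params.target_void_fraction``.  With ``zones``
    — pairs of (boolean mask, target fraction) — each zone is filled to
    its own target, with voids clipped at zone boundaries; this is how
    cohort scans realize different regional void fractions on one image.
    Same seed, same output (bit-identical).
    """
    rng = np.random.default_rng(params.seed)
    n = geometry.pixels_per_side
    shape = (n, n)
    if vessel_mask is not None:
        vessel_mask = np.asarray(vessel_mask, dtype=bool)
        if vessel_mask.shape != shape:
            raise ParameterError("vessel_mask shape must match geometry")
    if zones is None:
        base = np.ones(shape, dtype=bool)
        if vessel_mask is not None:
            base &= ~vessel_mask
        zones = [(base, params.target_void_fraction)]
    void_mask = np.zeros(shape, dtype=bool)
    for zone_mask, target in zones:
        _fill_zone(rng, void_mask, np.asarray(zone_mask, dtype=bool), float(target),
                   params, geometry, fovea_mm, tol=tol)
    img = np.full(shape, params.flow_mean)
    img[void_mask] = params.void_mean
    if vessel_mask is not None:
        img[vessel_mask] *= params.shadow_factor
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, shape)
    img = np.clip(img, 0.0, 1.0)
    return EnFaceImage(img, "CC", geometry, gaze=gaze, ssi=ssi), void_mask


# ---------------------------------------------------------------------------
# SCP image synthesis
# ---------------------------------------------------------------------------

def generate_scp_image(
    params: SCPGenParams,
    geometry: ScanGeometry,
    *,
    gaze: str = "central",
    ssi: float = 10.0,
) -> tuple[EnFaceImage, np.ndarray]:
    """Generate an SCP slab: bright random-walk vessels on a dark background.

    Each branch starts on a random image edge heading inward and walks
    with angular jitter until it leaves the frame; the rasterized,
    width-dilated tree is returned as the ground-truth vessel mask.
    """
    rng = np.random.default_rng(params.seed)
    n = geometry.pixels_per_side
    mask = np.zeros((n, n), dtype=bool)
    for _ in range(params.n_branches):
        center = np.zeros((n, n), dtype=bool)
        edge = int(rng.integers(4))
        t = float(rng.uniform(0, n - 1))
        if edge == 0:   # top
            r, c, ang = 0.0, t, math.pi / 2
        elif edge == 1:  # bottom
            r, c, ang = float(n - 1), t, -math.pi / 2
        elif edge == 2:  # left
            r, c, ang = t, 0.0, 0.0
        else:            # right
            r, c, ang = t, float(n - 1), math.pi
        ang += float(rng.normal(0.0, 0.4))
        for _ in range(3 * n):
            r2 = r + params.step_px * math.sin(ang)
            c2 = c + params.step_px * math.cos(ang)
            rr, cc = line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            center[rr[ok], cc[ok]] = True
            r, c = r2, c2
            if not (0 <= r < n and 0 <= c < n):
                break
            ang += float(rng.normal(0.0, params.turn_sd_rad))
        width = int(rng.choice(params.widths_px))
        if width > 1:
            center = binary_dilation(center, structure=disk(width // 2))
        mask |= center
    img = np.full((n, n), params.background)
    img[mask] = params.vessel_intensity
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, (n, n))
    img = np.clip(img, 0.0, 1.0)
    return EnFaceImage(img, "SCP", geometry, gaze=gaze, ssi=ssi), mask


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------

def _build_eye_scans(
    targets: Mapping[str, float],
    laterality: str,
    fovea_mm: tuple[float, float],
    disc_center_mm: tuple[float, float],
    disc_radius_mm: float,
    params: CohortGenParams,
    rng: np.random.Generator,
) -> tuple[list[EnFaceImage], dict[str, float]]:
    """Build the five gaze CC+SCP scan pairs realizing per-region targets.

    Returns the scans and the *achieved* per-region void fraction (ground
    truth measured on the region's assigned scan, vessel pixels excluded).
    """
    geoms = {
        gaze: ScanGeometry(params.field_of_view_mm, params.pixels_per_side, off, laterality)
        for gaze, off in gaze_offsets(laterality, params.gaze_offset_mag_mm).items()
    }
    specs = standard_regions(fovea_mm, disc_center_mm, disc_radius_mm, laterality)
    assignment: dict[str, list[str]] = {g: [] for g in GAZES}
    for name, spec in specs.items():
        if name in targets:
            assignment[select_scan_for_region(spec, geoms)].append(name)
    background_target = float(np.mean(list(targets.values())))
    scans: list[EnFaceImage] = []
    achieved: dict[str, float] = {}
    for gaze in GAZES:
        geom = geoms[gaze]
        scp_seed = int(rng.integers(2**31))
        cc_seed = int(rng.integers(2**31))
        ssi_scp = float(rng.uniform(8.5, 10.0))
        ssi_cc = float(rng.uniform(8.5, 10.0))
        scp_img, vmask = generate_scp_image(
            replace(params.scp, seed=scp_seed), geom, gaze=gaze, ssi=ssi_scp
        )
        # Keep voids a small margin away from vessels: the analyzable area
        # of a region is its footprint minus the vessel shadow plus this
        # margin, so ground truth and vessel-excluded measurement refer to
        # the same area.
        if params.vessel_margin_px > 0:
            standoff = binary_dilation(vmask, structure=disk(params.vessel_margin_px))
        else:
            standoff = vmask
        zones: list[tuple[np.ndarray, float]] = []
        zone_masks: list[tuple[str, np.ndarray]] = []
        occupied = np.zeros_like(vmask)
        for name in assignment[gaze]:
            zmask = rasterize_region(specs[name], geom) & ~standoff
            zones.append((zmask, targets[name]))
            zone_masks.append((name, zmask))
            occupied |= zmask
        zones.append((~occupied & ~standoff, background_target))
        cc_img, void_mask = generate_cc_image(
            replace(params.cc, seed=cc_seed), geom, fovea_mm,
            zones=zones, vessel_mask=vmask, gaze=gaze, ssi=ssi_cc,
        )
        for name, zmask in zone_masks:
            zpx = int(zmask.sum())
            achieved[name] = float(np.count_nonzero(void_mask & zmask)) / zpx if zpx else float("nan")
        scans.extend([cc_img, scp_img])
    return scans, achieved


def generate_cohort(params: CohortGenParams) -> tuple[list[EyeRecord], pd.DataFrame]:
    """Generate a full two-group cohort with per-eye ground truth.

    Returns the eye records and a tidy truth table with one row per eye
    and region: the drawn (target) void percent and the achieved ground
    truth on the generated scans.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    eyes: list[EyeRecord] = []
    rows: list[dict] = []
    plan = [("myopic", i) for i in range(params.n_myopic)] + [
        ("control", i) for i in range(params.n_control)
    ]
    for group, i in plan:
        subject_id = f"{'M' if group == 'myopic' else 'C'}{i + 1:03d}"
        laterality = str(rng.choice(["OD", "OS"]))
        nasal = -temporal_sign(laterality)
        fovea = (0.0, 0.0)
        disc_center = (nasal * params.disc_distance_mm, 0.0)
        table = params.calibration[group]
        z = {region: float(rng.standard_normal()) for region in table}
        targets = {
            region: float(draw_void_pct(z[region], *table[region])) / 100.0
            for region in table
        }
        mean_al, sd_al = params.axial_mm[group]
        axial = float(rng.normal(mean_al, sd_al))
        rho = params.choroid_void_rho
        thickness = {
            region: float(
                params.choroid_mean_um
                + params.choroid_sd_um
                * (rho * z[region] + math.sqrt(1.0 - rho**2) * rng.standard_normal())
            )
            for region in table
        }
        scans, achieved = _build_eye_scans(
            targets, laterality, fovea, disc_center, params.disc_radius_mm, params, rng
        )
        eyes.append(
            EyeRecord(
                subject_id=subject_id,
                group=group,
                axial_length_mm=axial,
                scans=scans,
                choroidal_thickness_um=thickness,
                fovea_mm=fovea,
                disc_center_mm=disc_center,
                disc_radius_mm=params.disc_radius_mm,
            )
        )
        for region in table:
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "region": region,
                    "target_void_pct": targets[region] * 100.0,
                    "true_void_pct": achieved.get(region, float("nan")) * 100.0,
                }
            )
    return eyes, pd.DataFrame(rows)


def generate_repeat_scans(
    eyes: Sequence[EyeRecord],
    truth: pd.DataFrame,
    params: CohortGenParams,
    seed: int,
) -> list[EyeRecord]:
    """Re-acquire the cohort: same eyes and true void fractions, fresh
    speckle and void placement — a synthetic second imaging session."""
    rng = np.random.default_rng(seed)
    out: list[EyeRecord] = []
    for eye in eyes:
        sub = truth[truth["subject_id"] == eye.subject_id]
        targets = {
            r.region: r.target_void_pct / 100.0 for r in sub.itertuples()
        }
        scans, _ = _build_eye_scans(
            targets, eye.laterality, eye.fovea_mm, eye.disc_center_mm,
            eye.disc_radius_mm, params, rng,
        )
        out.append(
            EyeRecord(
                subject_id=eye.subject_id,
                group=eye.group,
                axial_length_mm=eye.axial_length_mm,
                scans=scans,
                choroidal_thickness_um=dict(eye.choroidal_thickness_um),
                fovea_mm=eye.fovea_mm,
                disc_center_mm=eye.disc_center_mm,
                disc_radius_mm=eye.disc_radius_mm,
            )
        )
    return out
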