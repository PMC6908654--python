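"""Intensity normalization and Phansalkar local-threshold binarization.

The choriocapillaris slab is binarized into *flow* and *signal void*
(flow deficit) with the Phansalkar local threshold, a variant of
Sauvola's method designed for low-contrast images.  For each pixel the
threshold is computed from the mean ``m`` and standard deviation ``s`` of
the normalized intensities inside a circular window of radius
``radius_px``::

    t = m * (1 + p * exp(-q * m) + k * ((s / r) - 1))

with conventional defaults k=0.25, r=0.5, p=2, q=10 on intensities in
[0, 1].  Windows are clipped at the image border: statistics are taken
over in-image pixels only, never over padded values.

The window mean/mean-of-squares are computed with FFT convolutions of the
binary disk kernel, which is exact up to floating rounding and fast
enough for 500x500 scans; a brute-force window enumeration serves as the
test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.signal import fftconvolve

from .scan_model import ContractError, EnFaceImage, ParameterError

__all__ = [
    "FLOW",
    "VOID",
    "EXCLUDED",
    "PhansalkarParams",
    "TriStateMap",
    "NormalizedImage",
    "normalize_intensity",
    "phansalkar_threshold",
    "binarize_cc",
]

# Tri-state pixel codes.
FLOW = np.uint8(0)
VOID = np.uint8(1)
EXCLUDED = np.uint8(2)


@dataclass(frozen=True)
class PhansalkarParams:
    """Phansalkar threshold parameters.

    ``radius_px`` is the circular-window radius in pixels (default 15 px,
    about 360 um at the 24-um pitch of a 12-mm/500-px scan).  ``r``
    normalizes the window standard deviation and assumes intensities in
    [0, 1]; ``k``, ``p`` and ``q`` are the standard shape parameters.
    """

    radius_px: int = 15
    k: float = 0.25
    r: float = 0.5
    p: float = 2.0
    q: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_px < 1:
            raise ParameterError("radius_px must be >= 1")
        if not self.r > 0:
            raise ParameterError("r must be > 0")


@dataclass
class TriStateMap:
    """Per-pixel classification of a scan into flow / void / excluded."""

    labels: np.ndarray  # uint8 grid of FLOW/VOID/EXCLUDED

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise ContractError("TriStateMap labels must be 2-D")
        if not np.isin(self.labels, (FLOW, VOID, EXCLUDED)).all():
            raise ContractError("TriStateMap labels must be 0 (flow), 1 (void) or 2 (excluded)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def flow(self) -> np.ndarray:
        return self.labels == FLOW

    @property
    def void(self) -> np.ndarray:
        return self.labels == VOID

    @property
    def excluded(self) -> np.ndarray:
        return self.labels == EXCLUDED


class NormalizedImage(NamedTuple):
    pixels: np.ndarray
    was_constant: bool


def normalize_intensity(image: EnFaceImage | np.ndarray) -> NormalizedImage:
    """Affine rescale of intensities to [0, 1] (min -> 0, max -> 1).

    A constant image cannot be rescaled; it maps to all-zeros with
    ``was_constant=True`` so callers can flag the scan.
    """
    px = image.pixels if isinstance(image, EnFaceImage) else np.asarray(image, dtype=float)
    px = px.astype(float, copy=False)
    lo = float(px.min())
    hi = float(px.max())
    if hi == lo:
        return NormalizedImage(np.zeros_like(px), True)
    return NormalizedImage((px - lo) / (hi - lo), False)


def _disk_kernel(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    return ((ax[:, None] ** 2 + ax[None, :] ** 2) <= radius * radius).astype(float)


def phansalkar_threshold(pixels: np.ndarray, params: PhansalkarParams = PhansalkarParams()) -> np.ndarray:
    """Per-pixel Phansalkar threshold map for a [0, 1] image.

    Border windows are clipped to the image: ``m`` and ``s`` are computed
    over the in-image window pixels only.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ContractError("expected a 2-D image")
    if pixels.size and (pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9):
        raise ContractError("phansalkar_threshold expects intensities in [0, 1]")
    if params.radius_px > min(pixels.shape):
        raise ParameterError(
            f"window radius {params.radius_px} px exceeds image side {min(pixels.shape)} px"
        )
    kernel = _disk_kernel(params.radius_px)
    ones = np.ones_like(pixels)
    counts = fftconvolve(ones, kernel, mode="same")
    counts = np.maximum(np.round(counts), 1.0)  # kernel is binary -> integer counts
    s1 = fftconvolve(pixels, kernel, mode="same")
    s2 = fftconvolve(pixels * pixels, kernel, mode="same")
    m = s1 / counts
    var = np.maximum(s2 / counts - m * m, 0.0)
    s = np.sqrt(var)
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * ((s / params.r) - 1.0))


def binarize_cc(pixels: np.ndarray, thresholds: np.ndarray) -> TriStateMap:
    """Classify each pixel as flow (intensity > threshold) or void.

    The comparison is strict: intensity equal to the threshold counts as
    void (absence of detectable flow).  No pixel is excluded at this
    stage; vessel-shadow exclusion is applied afterwards.
    """
    pixels = np.asarray(pixels, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if pixels.shape != thresholds.shape:
        raise ContractError(
            f"image shape {pixels.shape} != threshold shape {thresholds.shape}"
        )
    labels = np.where(pixels > thresholds, FLOW, VOID).astype(np.uint8)
    return TriStateMap(labels)
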