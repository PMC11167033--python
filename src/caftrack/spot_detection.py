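"""Laplacian-of-Gaussian blob detection for cell-sized fluorescent objects.

Motile cells imaged at low magnification appear as near-Gaussian bright
blobs; the detector used throughout the pipeline is a scale-normalized
Laplacian-of-Gaussian (LoG) filter whose scale is set from the expected
object diameter, followed by strict local-maximum extraction, a quality
threshold and proximity suppression.  The "quality" of a spot is the
filter response at its maximum, in the same units the original tracking
configuration expressed its quality threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "DetectionParams",
    "Spot",
    "default_detection_params",
    "log_sigma_px",
    "log_response",
    "detect_spots",
]


@dataclass(frozen=True)
class DetectionParams:
    """Blob-detection parameters.

    Parameters
    ----------
    diameter_um
        Expected object diameter in micrometres.  The LoG scale is
        derived from it as ``sigma = (diameter / pixel_size) / (2*sqrt(2))``,
        the scale at which a disk of that diameter maximizes the
        scale-normalized response.
    quality_min
        Minimal retained filter response (filter-response units; they
        scale with image intensity).
    subpixel
        If true, refine maxima by a 1-D quadratic fit along each axis.
    """

    diameter_um: float = 8.0
    quality_min: float = 1.0
    subpixel: bool = False

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be > 0")


@dataclass(frozen=True)
class Spot:
    """A single detection: frame index, pixel position, filter quality."""

    frame: int
    x_px: float
    y_px: float
    quality: float


def default_detection_params() -> DetectionParams:
    """Defaults of the tracked-cell detector: 8 µm diameter, quality ≥ 1."""
    return DetectionParams(diameter_um=8.0, quality_min=1.0)


def log_sigma_px(diameter_um: float, pixel_size_um: float) -> float:
    """LoG sigma in pixels for an expected object diameter.

    A bright disk of radius r gives its maximal scale-normalized LoG
    response at sigma = r / sqrt(2), hence sigma = diameter / (2*sqrt(2)).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    d_px = diameter_um / pixel_size_um
    if d_px < 1.0:
        raise ValueError(
            f"object diameter {diameter_um} um is smaller than one pixel "
            f"({pixel_size_um} um/px)"
        )
    return d_px / (2.0 * math.sqrt(2.0))


def log_response(
    image: np.ndarray, diameter_um: float, pixel_size_um: float
) -> np.ndarray:
    """Scale-normalized LoG response, positive at bright blob centers.

    Filtering uses reflect padding at the borders; the response of a
    constant image is identically zero (the Laplacian kills the DC
    component).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    sigma = log_sigma_px(diameter_um, pixel_size_um)
    gl = ndi.gaussian_laplace(image, sigma, mode="reflect")
    # the truncated discrete kernel does not sum exactly to zero; subtract
    # the kernel sum times the image so the filter is exactly zero-DC
    n = 2 * int(math.ceil(4 * sigma)) + 3
    k_sum = ndi.gaussian_laplace(np.ones((n, n)), sigma, mode="reflect")[n // 2, n // 2]
    # minus sign: gaussian_laplace is negative at bright-blob centers
    return -(sigma**2) * (gl - k_sum * image)


def _strict_local_maxima(resp: np.ndarray) -> np.ndarray:
    """Boolean map of strict 8-connected local maxima."""
    padded = np.pad(resp, 1, mode="constant", constant_values=-np.inf)
    center = padded[1:-1, 1:-1]
    out = np.ones_like(center, dtype=bool)
    h, w = padded.shape
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            out &= center > padded[1 + dy : h - 1 + dy, 1 + dx : w - 1 + dx]
    return out


def _refine_quadratic(resp: np.ndarray, y: int, x: int) -> tuple[float, float]:
    """Sub-pixel peak offset from a 1-D parabola fit along each axis."""

    def offset(a: float, b: float, c: float) -> float:
        denom = a - 2.0 * b + c
        if denom >= 0:  # not a proper maximum; keep integer position
            return 0.0
        return float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < y < resp.shape[0] - 1:
        dy = offset(resp[y - 1, x], resp[y, x], resp[y + 1, x])
    if 0 < x < resp.shape[1] - 1:
        dx = offset(resp[y, x - 1], resp[y, x], resp[y, x + 1])
    return dy, dx


def detect_spots(
    image: np.ndarray,
    params: DetectionParams,
    pixel_size_um: float,
    frame: int = 0,
) -> list[Spot]:
    """Detect bright blobs in one frame.

    Spots are strict 8-connected local maxima of the scale-normalized
    LoG response with quality >= ``params.quality_min``.  Maxima within
    ``diameter/2`` pixels of a stronger maximum are suppressed, as are
    maxima within ``diameter/2`` pixels of the image border.  The result
    is sorted by descending quality (ties by (y, x)).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        return []
    resp = log_response(image, params.diameter_um, pixel_size_um)
    radius_px = (params.diameter_um / pixel_size_um) / 2.0

    maxima = _strict_local_maxima(resp)
    ys, xs = np.nonzero(maxima)
    if ys.size == 0:
        return []
    quals = resp[ys, xs]

    keep = quals >= params.quality_min
    ys, xs, quals = ys[keep], xs[keep], quals[keep]

    # border policy: discard maxima within diameter/2 of any edge
    h, w = image.shape
    inside = (
        (ys >= radius_px)
        & (ys <= h - 1 - radius_px)
        & (xs >= radius_px)
        & (xs <= w - 1 - radius_px)
    )
    ys, xs, quals = ys[inside], xs[inside], quals[inside]
    if ys.size == 0:
        return []

    order = np.lexsort((xs, ys, -quals))
    accepted: list[int] = []
    for idx in order:
        y, x = ys[idx], xs[idx]
        ok = True
        for j in accepted:
            if (ys[j] - y) ** 2 + (xs[j] - x) ** 2 < radius_px**2:
                ok = False
                break
        if ok:
            accepted.append(int(idx))

    spots = []
    for idx in accepted:
        y, x = int(ys[idx]), int(xs[idx])
        fy, fx = float(y), float(x)
        if params.subpixel:
            dy, dx = _refine_quadratic(resp, y, x)
            fy, fx = y + dy, x + dx
        spots.append(Spot(frame=frame, x_px=fx, y_px=fy, quality=float(quals[idx])))
    return spots
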