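"""Diffraction-limited spot detection with subpixel localization.

A scale-normalized Laplacian-of-Gaussian (LoG) filter followed by
non-maximum suppression and closed-form quadratic subpixel refinement —
the standard kernel behind batch single-molecule spot detectors.
Quadratic 3x3 refinement approximates Gaussian-MLE localization and is
closed-form; the offset is clamped to +-0.5 px per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class Spot:
    """A subpixel detection in one frame.

    ``quality`` is the LoG response at the maximum; ``intensity`` the
    background-subtracted integrated intensity in a radius-r disc
    (background = median of a surrounding annulus).
    """

    frame: int
    x_px: float
    y_px: float
    quality: float
    intensity: float = 0.0


def log_response(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Scale-normalized negated LoG response.

    Bright blobs of radius ~ sigma*sqrt(2) produce positive maxima. The
    operator is linear: response(a * I) == a * response(I).
    """
    if sigma_px <= 0.5:
        raise ValueError("sigma_px must exceed 0.5")
    image = np.asarray(image, dtype=float)
    # truncate=8 keeps the discrete kernel's DC response at float noise,
    # so constant images map to (numerically) zero
    return -(sigma_px**2) * ndimage.gaussian_laplace(image, sigma_px,
                                                     truncate=8.0)


def detect_spots(
    image: np.ndarray,
    radius_px: float = 2.0,
    quality_threshold: float = 10.0,
    frame: int = 0,
    intensity_radius_px: float | None = None,
) -> list[Spot]:
    """Detect spots as thresholded LoG maxima with subpixel refinement.

    ``radius_px`` sets both the blob scale (sigma = radius/sqrt(2)) and
    the non-maximum suppression radius. Constant-maximum plateaus are
    resolved toward the lowest (row, col) index and logged.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    image = np.asarray(image, dtype=float)
    sigma = radius_px / np.sqrt(2.0)
    resp = log_response(image, sigma)

    size = 2 * int(np.ceil(radius_px)) + 1
    footprint = _disc_footprint(size, radius_px)
    local_max = resp == ndimage.maximum_filter(
        resp, footprint=footprint, mode="nearest"
    )
    candidates = np.argwhere(local_max & (resp > quality_threshold))
    if len(candidates) == 0:
        return []

    # plateau tie-break: keep the lowest-index pixel of any connected
    # plateau of equal response
    keep = []
    seen_vals: dict[float, list[tuple[int, int]]] = {}
    for r, c in candidates:
        seen_vals.setdefault(resp[r, c], []).append((int(r), int(c)))
    plateau_logged = False
    for val, pix in seen_vals.items():
        if len(pix) > 1:
            # distinguish separated equal-valued maxima from plateaus
            pix_sorted = sorted(pix)
            chosen: list[tuple[int, int]] = []
            for p in pix_sorted:
                if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > radius_px
                       for q in chosen):
                    chosen.append(p)
                elif not plateau_logged:
                    logger.info("plateau tie at response %.3g broken to "
                                "lowest index", val)
                    plateau_logged = True
            keep.extend(chosen)
        else:
            keep.extend(pix)

    rows, cols = image.shape
    spots = []
    for r, c in sorted(keep):
        dy = _quadratic_offset(resp, r, c, axis=0)
        dx = _quadratic_offset(resp, r, c, axis=1)
        x, y = c + dx, r + dy
        if not (0 <= x <= cols - 1 and 0 <= y <= rows - 1):
            continue
        inten = _integrated_intensity(
            image, x, y,
            intensity_radius_px if intensity_radius_px else radius_px,
        )
        spots.append(Spot(frame, float(x), float(y), float(resp[r, c]), inten))
    return spots


def _disc_footprint(size: int, radius: float) -> np.ndarray:
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    return (yy**2 + xx**2) <= radius**2


def _quadratic_offset(resp: np.ndarray, r: int, c: int, axis: int) -> float:
    """1D quadratic-fit offset from the 3-sample neighborhood, clamped to
    +-0.5 px."""
    n = resp.shape[axis]
    i = r if axis == 0 else c
    if i == 0 or i == n - 1:
        return 0.0
    if axis == 0:
        fm, f0, fp = resp[r - 1, c], resp[r, c], resp[r + 1, c]
    else:
        fm, f0, fp = resp[r, c - 1], resp[r, c], resp[r, c + 1]
    denom = fm - 2.0 * f0 + fp
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))


def _integrated_intensity(
    image: np.ndarray, x: float, y: float, radius: float
) -> float:
    rows, cols = image.shape
    r_out = radius + 3.0
    r0 = max(0, int(np.floor(y - r_out)))
    r1 = min(rows, int(np.ceil(y + r_out)) + 1)
    c0 = max(0, int(np.floor(x - r_out)))
    c1 = min(cols, int(np.ceil(x + r_out)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    disc = d2 <= radius**2
    annulus = (d2 > radius**2) & (d2 <= r_out**2)
    if not disc.any():
        return 0.0
    patch = image[r0:r1, c0:c1]
    background = float(np.median(patch[annulus])) if annulus.any() else 0.0
    return float(patch[disc].sum() - background * disc.sum())


def spots_to_frame(spots: list[Spot], channel: str = "") -> pd.DataFrame:
    """Spots table with columns (channel, frame, x_px, y_px, quality,
    intensity)."""
    return pd.DataFrame([
        {"channel": channel, "frame": s.frame, "x_px": s.x_px, "y_px": s.y_px,
         "quality": s.quality, "intensity": s.intensity}
        for s in spots
    ], columns=["channel", "frame", "x_px", "y_px", "quality", "intensity"])


def detect_stack(
    stack: np.ndarray, radius_px: float = 2.0, quality_threshold: float = 10.0
) -> list[list[Spot]]:
    """Run detect_spots on every frame of a (T, Y, X) array."""
    return [
        detect_spots(stack[t], radius_px, quality_threshold, frame=t)
        for t in range(stack.shape[0])
    ]
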