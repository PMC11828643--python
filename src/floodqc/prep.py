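"""NEMA preparation stage: pixel-size gate, sum-method rebinning, FOV masks.

NEMA NU 1-2018 requires flood images stored at an effective pixel size of
6.4 mm +- 30% (4.48 to 8.32 mm). Images acquired finer than that are rebinned
by summing k x k blocks of adjacent pixels ("sum method"); images coarser than
the window cannot be fixed by rebinning, so the gate only warns.

The useful field of view (UFOV) is derived from the image itself: the bounding
box of strictly positive pixels, with cold edge pixels (below a fraction of
the central mean) peeled off iteratively. The central field of view (CFOV) is
the centered sub-rectangle spanning 75% of the UFOV's linear dimensions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyFovError, FovTooSmallError, GeometryError
from .image_io import FloodImage

__all__ = [
    "PixelSizeReport",
    "FovMasks",
    "check_pixel_size",
    "rebin_sum",
    "compute_fov_masks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PixelSizeReport:
    """Outcome of the NEMA pixel-size gate for one image."""

    pixel_mm: float
    lower_mm: float
    upper_mm: float
    compliant: bool
    suggested_factor: int | None
    warning: str | None = None


@dataclass
class FovMasks:
    """Paired boolean masks over the matrix grid; CFOV is a subset of UFOV."""

    ufov: np.ndarray
    cfov: np.ndarray
    cfov_fraction: float

    def __post_init__(self) -> None:
        if self.ufov.shape != self.cfov.shape:
            raise ValueError("ufov and cfov masks must share a shape")
        if (self.cfov & ~self.ufov).any():
            raise ValueError("cfov must be a subset of ufov")


def check_pixel_size(
    img: FloodImage, nominal_mm: float = 6.4, tol_fraction: float = 0.30
) -> PixelSizeReport:
    """Check the image's pixel size against the NEMA window nominal +- tol.

    With the defaults this is the 6.4 mm +- 30% window, i.e. 4.48 to 8.32 mm.
    If the pixel is finer than the window, ``suggested_factor`` is the
    smallest integer k >= 2 whose k-fold sum-rebin lands inside it (``None``
    if no such k exists). A pixel coarser than the window cannot be repaired
    by rebinning, so only a warning is attached.
    """
    r, c = img.pixel_spacing_mm
    if abs(r - c) > 0.01 * (r + c) / 2:
        raise GeometryError(f"pixel spacing not square within 1%: ({r}, {c}) mm")
    pixel = (r + c) / 2
    lower = nominal_mm * (1 - tol_fraction)
    upper = nominal_mm * (1 + tol_fraction)
    compliant = lower <= pixel <= upper
    factor: int | None = None
    warning: str | None = None
    if pixel < lower:
        for k in range(2, int(math.floor(upper / pixel)) + 1):
            if lower <= k * pixel <= upper:
                factor = k
                break
    elif pixel > upper:
        warning = (
            f"pixel size {pixel:.3f} mm exceeds the NEMA maximum {upper:.2f} mm; "
            "size reduction is not executed"
        )
        logger.warning(warning)
    return PixelSizeReport(pixel, lower, upper, compliant, factor, warning)


def rebin_sum(img: FloodImage, factor: int) -> FloodImage:
    """Rebin by summing factor x factor blocks of adjacent pixels.

    Pixel spacing is multiplied by ``factor``; trailing rows/columns that do
    not fill a block are dropped, and the total count they carried is logged
    and recorded in ``meta["rebin_dropped_counts"]``. Counts over full blocks
    are conserved exactly.
    """
    if factor < 1:
        raise ValueError(f"rebin factor must be >= 1, got {factor}")
    n, m = img.shape
    if factor > n or factor > m:
        raise ValueError(f"rebin factor {factor} exceeds image dimensions {img.shape}")
    if factor == 1:
        return FloodImage(
            img.counts.copy(), img.pixel_spacing_mm, img.detector_id, dict(img.meta)
        )
    nb, mb = n // factor, m // factor
    trimmed = img.counts[: nb * factor, : mb * factor]
    out = trimmed.reshape(nb, factor, mb, factor).sum(axis=(1, 3))
    dropped = float(img.counts.sum() - trimmed.sum())
    if dropped:
        logger.info(
            "rebin_sum factor %d dropped %g counts in trailing rows/columns",
            factor,
            dropped,
        )
    r, c = img.pixel_spacing_mm
    meta = dict(img.meta)
    meta.update(rebin_factor=factor, rebin_dropped_counts=dropped)
    return FloodImage(out, (r * factor, c * factor), img.detector_id, meta)


def _bounding_box(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return rows[0], rows[-1], cols[0], cols[-1]


def _centered_cfov(ufov: np.ndarray, fraction: float) -> np.ndarray:
    """Centered sub-rectangle of the UFOV bounding box, intersected with UFOV.

    Linear dimensions are rounded to the nearest integer (ties up); when the
    excluded margin is odd, the extra excluded row/column goes to the
    bottom/right.
    """
    r0, r1, c0, c1 = _bounding_box(ufov)
    h, w = r1 - r0 + 1, c1 - c0 + 1
    hc = int(math.floor(fraction * h + 0.5))
    wc = int(math.floor(fraction * w + 0.5))
    top = r0 + (h - hc) // 2
    left = c0 + (w - wc) // 2
    rect = np.zeros_like(ufov)
    rect[top : top + hc, left : left + wc] = True
    return rect & ufov


def compute_fov_masks(
    img: FloodImage,
    edge_threshold_fraction: float = 0.75,
    cfov_fraction: float = 0.75,
) -> FovMasks:
    """Derive UFOV and CFOV masks with iterative cold-edge peeling.

    Algorithm: (1) provisional UFOV = strictly positive pixels within their
    bounding box; (2) provisional CFOV = centered sub-rectangle spanning
    ``cfov_fraction`` of the UFOV bounding box; (3) UFOV edge pixels with
    counts below ``edge_threshold_fraction`` times the CFOV mean are removed.
    Steps 2–3 repeat until stable (the mask shrinks monotonically, so the
    fixed point exists); the final CFOV is recomputed from the final UFOV.

    Raises
    ------
    EmptyFovError
        If the image has no positive pixels (or peeling empties it).
    FovTooSmallError
        If the UFOV bounding box is smaller than 5 x 5 pixels, where
        differential uniformity is undefined.
    """
    counts = img.counts
    positive = counts > 0
    if not positive.any():
        raise EmptyFovError("image has no positive pixels")
    r0, r1, c0, c1 = _bounding_box(positive)
    if r1 - r0 + 1 < 5 or c1 - c0 + 1 < 5:
        raise FovTooSmallError(
            f"UFOV bounding box {(r1 - r0 + 1, c1 - c0 + 1)} is smaller than 5x5"
        )
    ufov = np.zeros_like(positive)
    ufov[r0 : r1 + 1, c0 : c1 + 1] = True
    ufov &= positive

    while True:
        cfov = _centered_cfov(ufov, cfov_fraction)
        if not cfov.any():
            raise FovTooSmallError("CFOV is empty after edge peeling")
        cfov_mean = counts[cfov].mean()
        # edge = in-mask pixels with an out-of-mask 4-neighbour or on the border
        edge = ufov & ~ndimage.binary_erosion(ufov)
        drop = edge & (counts < edge_threshold_fraction * cfov_mean)
        if not drop.any():
            break
        ufov = ufov & ~drop
        if not ufov.any():
            raise EmptyFovError("edge peeling removed every pixel")
        rr0, rr1, cc0, cc1 = _bounding_box(ufov)
        if rr1 - rr0 + 1 < 5 or cc1 - cc0 + 1 < 5:
            raise FovTooSmallError("UFOV shrank below 5x5 during edge peeling")
    return FovMasks(ufov=ufov, cfov=cfov, cfov_fraction=cfov_fraction)
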