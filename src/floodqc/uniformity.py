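"""NEMA uniformity statistics: nine-point smoothing, integral and differential
uniformity on the CFOV and UFOV.

The statistics are the NU 1-2018 definitions. Integral uniformity (IU) is
100*(max-min)/(max+min) over all in-FOV pixels of the smoothed image.
Differential uniformity (DU) is the worst such contrast over every run of five
contiguous in-FOV pixels along rows (x) or columns (y). Both are percentages;
by construction DU <= IU on the same mask and IU_CFOV <= IU_UFOV.

Smoothing uses the NEMA nine-point kernel

    1 2 1
    2 4 2       (sum 16)
    1 2 1

applied as a weighted mean over the in-mask neighbourhood: at mask edges the
weights are renormalized over the neighbours actually present rather than
zero-padding, which would fabricate cold edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import DataError, FovTooSmallError, PixelSizeError
from .image_io import FloodImage
from .prep import check_pixel_size, compute_fov_masks, rebin_sum

__all__ = [
    "SmoothingKernel",
    "NEMA_KERNEL",
    "AnalyzerConfig",
    "UniformityResult",
    "smooth_nema",
    "integral_uniformity",
    "differential_uniformity",
    "analyze_flood",
]


@dataclass(frozen=True)
class SmoothingKernel:
    """A 3x3 non-negative smoothing kernel, symmetric under horizontal and
    vertical flips, with its maximum at the center."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (3, 3):
            raise ValueError(f"kernel must be 3x3, got {w.shape}")
        if (w < 0).any():
            raise ValueError("kernel weights must be non-negative")
        if w[1, 1] < w.max():
            raise ValueError("kernel center weight must be the maximum")
        if not (np.allclose(w, w[::-1, :]) and np.allclose(w, w[:, ::-1])):
            raise ValueError("kernel must be symmetric under horizontal/vertical flip")
        object.__setattr__(self, "weights", w)


#: NEMA NU 1-2018 nine-point kernel (sum 16).
NEMA_KERNEL = SmoothingKernel(np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=float))


def smooth_nema(
    counts: np.ndarray, mask: np.ndarray, kernel: SmoothingKernel = NEMA_KERNEL
) -> np.ndarray:
    """Weighted-mean smoothing restricted to the mask.

    Each in-mask pixel becomes sum(w_ij * c_ij) over its in-mask 3x3
    neighbourhood divided by the sum of the weights actually used
    (renormalization at mask edges). Out-of-mask pixels are 0 in the output.
    """
    counts = np.asarray(counts, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != counts.shape:
        raise ValueError("mask shape must equal counts shape")
    w = kernel.weights
    m = mask.astype(float)
    num = ndimage.correlate(counts * m, w, mode="constant", cval=0.0)
    den = ndimage.correlate(m, w, mode="constant", cval=0.0)
    out = np.zeros_like(counts)
    out[mask] = num[mask] / den[mask]
    return out


def integral_uniformity(counts: np.ndarray, mask: np.ndarray) -> float:
    """100 * (max - min) / (max + min) over in-mask pixels."""
    vals = np.asarray(counts, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < 2:
        raise FovTooSmallError("integral uniformity needs at least 2 in-mask pixels")
    if (vals <= 0).any():
        raise DataError("non-positive in-mask value; masking should have removed it")
    vmax, vmin = float(vals.max()), float(vals.min())
    return 100.0 * (vmax - vmin) / (vmax + vmin)


def differential_uniformity(
    counts: np.ndarray, mask: np.ndarray, axis: str, window: int = 5
) -> tuple[float, int]:
    """Worst windowed contrast along rows (axis="x") or columns (axis="y").

    Every run of exactly ``window`` contiguous in-mask pixels is scored as
    100*(max-min)/(max+min); windows containing any out-of-mask pixel are
    skipped (NEMA windows are fixed-length, never shrunk). Returns the worst
    score and the number of windows evaluated.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if window < 1:
        raise ValueError(f"window must be positive, got {window}")
    counts = np.asarray(counts, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != counts.shape:
        raise ValueError("mask shape must equal counts shape")
    a = counts if axis == "x" else counts.T
    m = mask if axis == "x" else mask.T
    if a.shape[1] < window:
        raise FovTooSmallError(f"no run of {window} pixels fits along axis {axis}")
    cw = sliding_window_view(a, window, axis=1)
    mw = sliding_window_view(m, window, axis=1).all(axis=-1)
    if not mw.any():
        raise FovTooSmallError(f"no run of {window} contiguous in-mask pixels along axis {axis}")
    sel = cw[mw]
    if (sel <= 0).any():
        raise DataError("non-positive in-mask value in a differential window")
    wmax = sel.max(axis=-1)
    wmin = sel.min(axis=-1)
    du = 100.0 * (wmax - wmin) / (wmax + wmin)
    return float(du.max()), int(mw.sum())


@dataclass(frozen=True)
class AnalyzerConfig:
    """Parameters of one analyzer configuration ("software variant").

    The defaults reproduce the NEMA protocol: nine-point smoothing, 6.4 mm
    +- 30% pixel gate with automatic sum-rebinning, 75% cold-edge threshold,
    75% CFOV fraction, five-pixel differential windows.
    """

    name: str = "nema"
    kernel: SmoothingKernel = NEMA_KERNEL
    smoothing_enabled: bool = True
    auto_rebin: bool = True
    nominal_pixel_mm: float = 6.4
    pixel_tol_fraction: float = 0.30
    edge_threshold_fraction: float = 0.75
    cfov_fraction: float = 0.75
    window: int = 5

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "kernel": self.kernel.weights.tolist(),
            "smoothing_enabled": self.smoothing_enabled,
            "auto_rebin": self.auto_rebin,
            "nominal_pixel_mm": self.nominal_pixel_mm,
            "pixel_tol_fraction": self.pixel_tol_fraction,
            "edge_threshold_fraction": self.edge_threshold_fraction,
            "cfov_fraction": self.cfov_fraction,
            "window": self.window,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalyzerConfig":
        d = dict(d)
        if "kernel" in d:
            d["kernel"] = SmoothingKernel(np.asarray(d["kernel"], dtype=float))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalyzerConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_name(self, name: str) -> "AnalyzerConfig":
        return replace(self, name=name)


@dataclass(frozen=True)
class UniformityResult:
    """Six NEMA uniformity percentages for one image under one configuration.

    ``n_windows_x`` / ``n_windows_y`` count the UFOV differential windows
    evaluated; provenance records every parameter used.
    """

    iu_ufov: float
    iu_cfov: float
    du_x_ufov: float
    du_x_cfov: float
    du_y_ufov: float
    du_y_cfov: float
    n_windows_x: int
    n_windows_y: int
    provenance: dict[str, Any] = field(default_factory=dict)

    _METRICS = ("iu", "du_x", "du_y")
    _FOVS = ("cfov", "ufov")

    def value(self, metric: str, fov: str) -> float:
        return getattr(self, f"{metric}_{fov}")

    def as_dict(self, ndigits: int | None = None) -> dict[str, float]:
        d = {
            f"{m}_{f}": self.value(m, f) for m in self._METRICS for f in self._FOVS
        }
        if ndigits is not None:
            d = {k: round(v, ndigits) for k, v in d.items()}
        return d

    @property
    def max_value(self) -> float:
        return max(self.as_dict().values())


def analyze_flood(img: FloodImage, config: AnalyzerConfig | None = None) -> UniformityResult:
    """Full NEMA analysis chain for one flood image.

    Chains the pixel-size gate (with optional automatic sum-rebinning),
    UFOV/CFOV mask derivation, nine-point smoothing, and the four uniformity
    statistics on both fields of view. Deterministic for a fixed input image
    and configuration.
    """
    cfg = config or AnalyzerConfig()
    report = check_pixel_size(img, cfg.nominal_pixel_mm, cfg.pixel_tol_fraction)
    rebinned = None
    if not report.compliant:
        if cfg.auto_rebin and report.suggested_factor is not None:
            rebinned = report.suggested_factor
            img = rebin_sum(img, rebinned)
            report = check_pixel_size(img, cfg.nominal_pixel_mm, cfg.pixel_tol_fraction)
        if not report.compliant:
            raise PixelSizeError(
                f"pixel size {report.pixel_mm:.3f} mm fails the NEMA gate "
                f"[{report.lower_mm:.2f}, {report.upper_mm:.2f}] mm and no "
                "rebin factor brings it in range"
            )
    masks = compute_fov_masks(img, cfg.edge_threshold_fraction, cfg.cfov_fraction)
    if cfg.smoothing_enabled:
        work = smooth_nema(img.counts, masks.ufov, cfg.kernel)
    else:
        work = np.where(masks.ufov, img.counts, 0.0)

    iu_u = integral_uniformity(work, masks.ufov)
    iu_c = integral_uniformity(work, masks.cfov)
    du_x_u, nxu = differential_uniformity(work, masks.ufov, "x", cfg.window)
    du_x_c, nxc = differential_uniformity(work, masks.cfov, "x", cfg.window)
    du_y_u, nyu = differential_uniformity(work, masks.ufov, "y", cfg.window)
    du_y_c, nyc = differential_uniformity(work, masks.cfov, "y", cfg.window)

    provenance: dict[str, Any] = {
        "config": cfg.to_dict(),
        "pixel_mm": report.pixel_mm,
        "pixel_bounds_mm": (report.lower_mm, report.upper_mm),
        "rebin_factor": rebinned,
        "ufov_pixels": int(masks.ufov.sum()),
        "cfov_pixels": int(masks.cfov.sum()),
        "n_windows": {"x_ufov": nxu, "x_cfov": nxc, "y_ufov": nyu, "y_cfov": nyc},
        "detector_id": img.detector_id,
    }
    return UniformityResult(
        iu_ufov=iu_u,
        iu_cfov=iu_c,
        du_x_ufov=du_x_u,
        du_x_cfov=du_x_c,
        du_y_ufov=du_y_u,
        du_y_cfov=du_y_c,
        n_windows_x=nxu,
        n_windows_y=nyu,
        provenance=provenance,
    )
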