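"""Seedable synthetic flood-field acquisitions and paired software readings.

The generator stands in for the scanner: a flood acquisition is modelled as an
independent per-pixel Poisson count field whose mean is a uniform intensity
over the active detector area, modulated multiplicatively by parametric
nonuniformity defects (linear gradients from PMT gain drift, Gaussian blobs
from a weak PMT, annular rings — the canonical ring artifact). Defects are
multiplicative because flood nonuniformity physically scales with local
sensitivity.

The default acquisition mirrors routine intrinsic-uniformity QC: a 128x128
matrix stopped at 20,000 kilocounts. A flat 128x128 flood at that total gives
~1221 counts/pixel, so the separate recommendation of >=10,000 counts in the
center pixel (which presumes coarser binning) cannot hold simultaneously; the
total is treated as binding and the achieved expected center-pixel count is
recorded in the image metadata. ``PhantomSpec.desk_scale()`` gives a fast
64x64 / 2,000-kilocount profile for tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .agreement import PairedSample
from .errors import ParameterError
from .image_io import FloodImage

__all__ = [
    "DefectModel",
    "PhantomSpec",
    "expected_field",
    "generate_flood",
    "generate_paired_readings",
]


@dataclass(frozen=True)
class DefectModel:
    """One multiplicative nonuniformity defect.

    kind="gradient": 1 + a*(2t - 1), t the normalized coordinate along
    ``orientation_deg`` (0 deg = along +x) over the active area, so the field
    spans [1-a, 1+a] exactly.
    kind="blob": 1 + a*exp(-r^2 / 2 sigma^2) around ``center`` (row, col).
    kind="ring": 1 + a on the annulus |r - radius| <= width/2 around ``center``.

    ``amplitude`` is the fractional modulation, in (-1, 1).
    """

    kind: str
    amplitude: float
    orientation_deg: float = 0.0
    center: tuple[float, float] | None = None
    sigma_px: float = 6.0
    radius_px: float = 20.0
    width_px: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("gradient", "blob", "ring"):
            raise ParameterError(f"unknown defect kind {self.kind!r}")
        if not -1.0 < self.amplitude < 1.0:
            raise ParameterError(f"amplitude must be in (-1, 1), got {self.amplitude}")
        if self.sigma_px <= 0 or self.radius_px <= 0 or self.width_px <= 0:
            raise ParameterError("defect geometry parameters must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """Seedable description of one synthetic flood acquisition.

    ``active_shape`` is "rectangle" (dimensions ``active_size`` in pixels,
    default the full matrix) or "circle" (``active_radius_px``, default half
    the smaller matrix dimension minus one). ``total_kilocounts`` is the
    acquisition stop condition; ``noiseless=True`` returns the expected field
    itself (real-valued) instead of a Poisson draw.
    """

    matrix_size: tuple[int, int] = (128, 128)
    pixel_mm: float = 6.4
    active_shape: str = "rectangle"
    active_size: tuple[int, int] | None = None
    active_radius_px: float | None = None
    total_kilocounts: float = 20000.0
    defects: tuple[DefectModel, ...] = ()
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.matrix_size
        if rows < 1 or cols < 1:
            raise ParameterError(f"matrix_size must be positive, got {self.matrix_size}")
        if self.pixel_mm <= 0:
            raise ParameterError("pixel_mm must be positive")
        if self.active_shape not in ("rectangle", "circle"):
            raise ParameterError(f"unknown active_shape {self.active_shape!r}")
        if self.total_kilocounts <= 0:
            raise ParameterError("total_kilocounts must be positive")
        object.__setattr__(self, "defects", tuple(self.defects))

    @classmethod
    def desk_scale(cls, **overrides: Any) -> "PhantomSpec":
        """Fast test profile: 64x64 matrix, 2,000 kilocounts."""
        base = dict(matrix_size=(64, 64), total_kilocounts=2000.0)
        base.update(overrides)
        return cls(**base)

    def replace(self, **changes: Any) -> "PhantomSpec":
        return replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return {
            "matrix_size": list(self.matrix_size),
            "pixel_mm": self.pixel_mm,
            "active_shape": self.active_shape,
            "active_size": list(self.active_size) if self.active_size else None,
            "active_radius_px": self.active_radius_px,
            "total_kilocounts": self.total_kilocounts,
            "defects": [
                {
                    "kind": d.kind,
                    "amplitude": d.amplitude,
                    "orientation_deg": d.orientation_deg,
                    "center": list(d.center) if d.center else None,
                    "sigma_px": d.sigma_px,
                    "radius_px": d.radius_px,
                    "width_px": d.width_px,
                }
                for d in self.defects
            ],
            "noiseless": self.noiseless,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhantomSpec":
        d = dict(d)
        d["matrix_size"] = tuple(d.get("matrix_size", (128, 128)))
        if d.get("active_size"):
            d["active_size"] = tuple(d["active_size"])
        defects = []
        for dd in d.get("defects", []) or []:
            dd = dict(dd)
            if dd.get("center"):
                dd["center"] = tuple(dd["center"])
            else:
                dd.pop("center", None)
            defects.append(DefectModel(**dd))
        d["defects"] = tuple(defects)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _active_mask(spec: PhantomSpec) -> np.ndarray:
    rows, cols = spec.matrix_size
    if spec.active_shape == "rectangle":
        h, w = spec.active_size or (rows, cols)
        if h > rows or w > cols or h < 1 or w < 1:
            raise ParameterError(f"active_size {(h, w)} does not fit in {spec.matrix_size}")
        mask = np.zeros((rows, cols), dtype=bool)
        top = (rows - h) // 2
        left = (cols - w) // 2
        mask[top : top + h, left : left + w] = True
        return mask
    radius = spec.active_radius_px or (min(rows, cols) / 2.0 - 1.0)
    if radius <= 0 or radius > min(rows, cols) / 2.0:
        raise ParameterError(f"active_radius_px {radius} does not fit in {spec.matrix_size}")
    rr, cc = np.indices((rows, cols))
    r2 = (rr - (rows - 1) / 2.0) ** 2 + (cc - (cols - 1) / 2.0) ** 2
    return r2 <= radius**2


def expected_field(spec: PhantomSpec) -> np.ndarray:
    """Closed-form expected count field: uniform over the active area,
    modulated by each defect, scaled so the sum is total_kilocounts * 1000."""
    rows, cols = spec.matrix_size
    active = _active_mask(spec)
    field_ = active.astype(float)
    rr, cc = np.indices((rows, cols), dtype=float)
    for defect in spec.defects:
        a = defect.amplitude
        center = defect.center or ((rows - 1) / 2.0, (cols - 1) / 2.0)
        if defect.kind == "gradient":
            theta = math.radians(defect.orientation_deg)
            u = cc * math.cos(theta) + rr * math.sin(theta)
            ua = u[active]
            span = ua.max() - ua.min()
            if span == 0:
                raise ParameterError("gradient defect needs a >1 pixel active span")
            t = (u - ua.min()) / span
            mod = 1.0 + a * (2.0 * t - 1.0)
        elif defect.kind == "blob":
            r2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
            mod = 1.0 + a * np.exp(-r2 / (2.0 * defect.sigma_px**2))
        else:  # ring
            r = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
            mod = np.where(np.abs(r - defect.radius_px) <= defect.width_px / 2.0, 1.0 + a, 1.0)
        field_ *= mod
    if (field_[active] <= 0).any():
        raise ParameterError("defect stack drives an expected pixel value to <= 0")
    field_[~active] = 0.0
    field_ *= spec.total_kilocounts * 1000.0 / field_.sum()
    return field_


def generate_flood(spec: PhantomSpec, seed: int | None = None) -> FloodImage:
    """Generate one flood acquisition; a pure function of (spec, seed).

    Noiseless specs return the real-valued expected field (integer rounding is
    deferred to DICOM export, preserving analytic uniformity values); noisy
    specs draw each pixel independently from a Poisson law with the expected
    field as mean.
    """
    if seed is None:
        seed = spec.seed
    expected = expected_field(spec)
    if spec.noiseless:
        counts = expected.copy()
    else:
        counts = np.random.default_rng(seed).poisson(expected).astype(float)
    rows, cols = spec.matrix_size
    center_expected = float(expected[rows // 2, cols // 2])
    meta = {
        "phantom_spec": spec.to_dict(),
        "seed": int(seed),
        "expected_center_pixel_counts": center_expected,
        "center_pixel_meets_10k": bool(center_expected >= 10_000.0),
    }
    return FloodImage(
        counts=counts,
        pixel_spacing_mm=(spec.pixel_mm, spec.pixel_mm),
        detector_id=f"sim-{seed}",
        meta=meta,
    )


def generate_paired_readings(
    n: int,
    bias: float = 0.0,
    proportional: float = 0.0,
    noise_sd: float = 0.0,
    base_values: Sequence[float] | None = None,
    seed: int = 0,
) -> PairedSample:
    """Emulated paired software readings for the agreement layer.

    ``a`` holds the reference readings (supplied ``base_values`` or uniform
    draws on [2, 6], the percentage range of a passing uniformity test);
    ``b_i = a_i + bias + proportional * a_i + eps_i`` with
    eps ~ Normal(0, noise_sd). Seeded and reproducible.
    """
    if n < 3:
        raise ValueError(f"paired samples need n >= 3, got {n}")
    rng = np.random.default_rng(seed)
    if base_values is None:
        a = rng.uniform(2.0, 6.0, size=n)
    else:
        a = np.asarray(base_values, dtype=float)
        if a.size != n:
            raise ValueError(f"base_values length {a.size} != n {n}")
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    b = a + bias + proportional * a + eps
    return PairedSample(a=a, b=b)
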