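"""Agreement statistics for paired software readings.

Three layers, mirroring how between-software QC comparisons are reported:
percentage deviation of one method from a reference, the Mann–Whitney U rank
test (normal approximation with midranks and tie-corrected variance), and
Bland–Altman 95% limits of agreement in both the classic constant form and
the regression-based form, where bias and spread are allowed to vary linearly
with the pair mean (used when differences are non-normal or trend with
magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, DataError, DegenerateDataError

__all__ = [
    "PairedSample",
    "MannWhitneyResult",
    "LinearForm",
    "AgreementReport",
    "percent_deviation",
    "mann_whitney",
    "bland_altman_classic",
    "bland_altman_regression",
    "agreement_frame",
]


@dataclass
class PairedSample:
    """Paired readings: ``a`` the reference method, ``b`` the comparison."""

    a: np.ndarray
    b: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 1 or b.ndim != 1 or a.size != b.size:
            raise ValueError("a and b must be 1-D vectors of equal length")
        if not (np.isfinite(a).all() and np.isfinite(b).all()):
            raise ValueError("paired sample contains missing/non-finite values")
        if self.labels is not None and len(self.labels) != a.size:
            raise ValueError("labels length must match sample length")
        self.a, self.b = a, b

    def __len__(self) -> int:
        return self.a.size

    def diffs(self) -> np.ndarray:
        return self.b - self.a

    def means(self) -> np.ndarray:
        return (self.a + self.b) / 2.0


def percent_deviation(sample: PairedSample, mode: str = "points") -> tuple[float, float]:
    """Mean and sample SD of per-pair deviations of ``b`` from ``a``.

    mode="points": d_i = b_i - a_i, in percentage points (both readings are
    already percentages). mode="relative": d_i = 100*(b_i - a_i)/a_i.
    The SD uses the n-1 denominator.
    """
    if mode == "points":
        d = sample.diffs()
    elif mode == "relative":
        zero = np.flatnonzero(sample.a == 0)
        if zero.size:
            label = (
                sample.labels[zero[0]] if sample.labels is not None else f"index {zero[0]}"
            )
            raise DataError(f"relative deviation undefined: zero reference at {label}")
        d = 100.0 * sample.diffs() / sample.a
    else:
        raise ValueError(f"mode must be 'points' or 'relative', got {mode!r}")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(np.mean(d)), sd


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    z: float
    p_two_sided: float
    mean_rank_a: float
    mean_rank_b: float
    tie_corrected: bool


def mann_whitney(
    sample_a: Sequence[float], sample_b: Sequence[float], continuity: bool = False
) -> MannWhitneyResult:
    """Mann–Whitney U with midranks and tie-corrected normal approximation.

    U is reported for group ``a`` (U_a = R_a - n_a(n_a+1)/2, so complete
    separation with all of ``b`` above ``a`` gives U = 0). The variance is
    sigma^2 = (n_a n_b / 12) * ((N+1) - sum(t^3 - t)/(N(N-1))) over tie-group
    sizes t, and z = (U - n_a n_b / 2)/sigma with an optional 0.5 continuity
    correction toward the mean. The two-sided p comes from the normal law.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs at least one observation")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    _, tie_sizes = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_sizes**3 - tie_sizes).sum()) / (n * (n - 1)))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        raise DegenerateDataError("all pooled values identical; U variance is zero")
    delta = u - n_a * n_b / 2.0
    if continuity and delta != 0:
        delta -= 0.5 * math.copysign(1.0, delta)
    z = delta / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return MannWhitneyResult(
        u=float(u),
        z=float(z),
        p_two_sided=float(min(p, 1.0)),
        mean_rank_a=r_a / n_a,
        mean_rank_b=float(ranks[n_a:].sum()) / n_b,
        tie_corrected=bool((tie_sizes > 1).any()),
    )


@dataclass(frozen=True)
class LinearForm:
    """A line over the pair mean m: value(m) = intercept + slope * m."""

    intercept: float
    slope: float

    def __call__(self, m: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(m, dtype=float)


@dataclass(frozen=True)
class AgreementReport:
    """Bias and 95% limits of agreement for a paired sample.

    In classic mode ``bias`` and ``loa_half_width`` are constants; in
    regression mode both are :class:`LinearForm` lines over the pair mean.
    ``coverage`` is the fraction of pairs inside their own limits.
    """

    mode: str  # "classic" | "regression"
    bias: float | LinearForm
    loa_half_width: float | LinearForm
    coverage: float
    n: int
    k: float = 1.96

    def limits_at(self, m: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) limits evaluated at pair mean(s) m."""
        m = np.asarray(m, dtype=float)
        bias = self.bias(m) if isinstance(self.bias, LinearForm) else np.full_like(m, self.bias)
        half = (
            np.maximum(self.loa_half_width(m), 0.0)
            if isinstance(self.loa_half_width, LinearForm)
            else np.full_like(m, self.loa_half_width)
        )
        return bias - half, bias + half


def bland_altman_classic(sample: PairedSample, k: float = 1.96) -> AgreementReport:
    """Classic Bland–Altman: constant bias mean(d) and limits bias +- k*sd(d)."""
    if len(sample) < 3:
        raise ValueError("classic limits of agreement need n >= 3 pairs")
    d = sample.diffs()
    bias = float(np.mean(d))
    half = float(k * np.std(d, ddof=1))
    coverage = float(np.mean((d >= bias - half) & (d <= bias + half)))
    return AgreementReport(
        mode="classic", bias=bias, loa_half_width=half, coverage=coverage, n=len(sample), k=k
    )


def bland_altman_regression(sample: PairedSample, k: float = 1.96) -> AgreementReport:
    """Regression-based Bland–Altman limits of agreement.

    (1) OLS of the differences d_i on the pair means m_i gives the bias line
    D(m); (2) OLS of the absolute residuals on m_i gives R(m); (3) the limits
    are D(m) +- k*sqrt(pi/2)*R(m) (the sqrt(pi/2) factor converts a mean
    absolute deviation to a normal SD). The half-width line is floored at 0
    when evaluating limits.
    """
    if len(sample) < 4:
        raise ValueError("regression limits of agreement need n >= 4 pairs")
    m = sample.means()
    d = sample.diffs()
    if np.ptp(m) == 0:
        raise CollinearityError("all pair means equal; use bland_altman_classic")
    design = sm.add_constant(m)
    bias_fit = sm.OLS(d, design).fit()
    bias_line = LinearForm(float(bias_fit.params[0]), float(bias_fit.params[1]))
    resid = d - bias_line(m)
    scale_fit = sm.OLS(np.abs(resid), design).fit()
    c = k * math.sqrt(math.pi / 2.0)
    half_line = LinearForm(c * float(scale_fit.params[0]), c * float(scale_fit.params[1]))
    half = np.maximum(half_line(m), 0.0)
    coverage = float(np.mean(np.abs(resid) <= half))
    return AgreementReport(
        mode="regression",
        bias=bias_line,
        loa_half_width=half_line,
        coverage=coverage,
        n=len(sample),
        k=k,
    )


def agreement_frame(sample: PairedSample, report: AgreementReport) -> pd.DataFrame:
    """Plot-ready table: pair mean, difference, fitted bias, lower/upper limit."""
    m = sample.means()
    d = sample.diffs()
    bias = report.bias(m) if isinstance(report.bias, LinearForm) else np.full_like(m, report.bias)
    lower, upper = report.limits_at(m)
    frame = pd.DataFrame(
        {
            "pair_mean": m,
            "difference": d,
            "fitted_bias": bias,
            "lower_limit": lower,
            "upper_limit": upper,
        }
    )
    if sample.labels is not None:
        frame.insert(0, "label", list(sample.labels))
    return frame
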