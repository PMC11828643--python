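"""Comparison-study orchestration: many images x many analyzer variants.

A "software variant" is an analyzer configuration (kernel on/off, mask
fractions, rebinning policy) standing in for an independent QC program. The
study analyzes every image under a reference configuration and each variant,
tabulates per-metric percentage deviations from the reference, runs the
Mann–Whitney comparison per metric, fits Bland–Altman limits of agreement,
and applies a pass/fail tolerance verdict (default: any uniformity value
>= 5% fails, the scanner-level acceptance limit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementReport,
    LinearForm,
    MannWhitneyResult,
    PairedSample,
    agreement_frame,
    bland_altman_classic,
    bland_altman_regression,
    mann_whitney,
    percent_deviation,
)
from .errors import CollinearityError, DegenerateDataError, FloodQCError
from .image_io import FloodImage
from .uniformity import AnalyzerConfig, UniformityResult, analyze_flood

__all__ = ["VariantConfig", "StudyReport", "run_study", "export_report"]

#: Variants are plain analyzer configurations distinguished by name.
VariantConfig = AnalyzerConfig

_METRIC_FOVS = [
    ("iu", "cfov"),
    ("iu", "ufov"),
    ("du_x", "cfov"),
    ("du_x", "ufov"),
    ("du_y", "cfov"),
    ("du_y", "ufov"),
]

_FLOAT_FMT = "%.10g"


@dataclass
class StudyReport:
    """Everything one comparison run produced, keyed by variant name."""

    reference: str
    variant_names: list[str]
    results: dict[str, list[UniformityResult]]
    deviations: pd.DataFrame
    mannwhitney: dict[str, dict[str, MannWhitneyResult | None]]
    agreement: dict[str, dict[str, AgreementReport | None]]
    samples: dict[str, dict[str, PairedSample]]
    verdicts: pd.DataFrame
    threshold_pct: float


def _metric_vector(results: Sequence[UniformityResult], metric: str, fov: str) -> np.ndarray:
    return np.array([r.value(metric, fov) for r in results])


def run_study(
    images: Sequence[FloodImage],
    reference_variant: VariantConfig,
    variants: Sequence[VariantConfig],
    threshold_pct: float = 5.0,
) -> StudyReport:
    """Analyze every image under every configuration and compare to reference.

    Deterministic for fixed inputs. Deviations use point differences
    (variant minus reference, in percentage points), so configurations that
    inflate uniformity — e.g. smoothing disabled — show positive means.
    A Mann–Whitney comparison whose pooled values are all tied (every image
    yielding the same value under both configurations) has no defined z and
    is recorded as ``None``; agreement fits fall
    back from regression to classic form when the design is too small or
    collinear.
    """
    if len(images) < 2:
        raise ValueError("a study needs at least 2 images")
    names = [reference_variant.name] + [v.name for v in variants]
    if len(set(names)) != len(names):
        raise ValueError(f"variant names must be unique, got {names}")

    results: dict[str, list[UniformityResult]] = {}
    for cfg in [reference_variant, *variants]:
        rows = []
        for i, img in enumerate(images):
            try:
                rows.append(analyze_flood(img, cfg))
            except FloodQCError as exc:
                raise FloodQCError(
                    f"analysis failed for image #{i} ({img.detector_id!r}) "
                    f"under variant {cfg.name!r}: {exc}"
                ) from exc
        results[cfg.name] = rows

    dev_rows = []
    mw: dict[str, dict[str, MannWhitneyResult | None]] = {}
    agr: dict[str, dict[str, AgreementReport | None]] = {}
    samples: dict[str, dict[str, PairedSample]] = {}
    ref_results = results[reference_variant.name]
    for variant in variants:
        mw[variant.name] = {}
        agr[variant.name] = {}
        samples[variant.name] = {}
        for metric, fov in _METRIC_FOVS:
            key = f"{metric}_{fov}"
            ref = _metric_vector(ref_results, metric, fov)
            var = _metric_vector(results[variant.name], metric, fov)
            sample = PairedSample(ref, var)
            samples[variant.name][key] = sample
            mean, sd = percent_deviation(sample, mode="points")
            dev_rows.append(
                {"variant": variant.name, "metric": metric, "fov": fov, "mean": mean, "sd": sd}
            )
            try:
                mw[variant.name][key] = mann_whitney(ref, var)
            except DegenerateDataError:
                mw[variant.name][key] = None
            report: AgreementReport | None
            try:
                if len(sample) >= 4:
                    report = bland_altman_regression(sample)
                else:
                    report = bland_altman_classic(sample)
            except CollinearityError:
                report = bland_altman_classic(sample)
            agr[variant.name][key] = report

    deviations = pd.DataFrame(dev_rows, columns=["variant", "metric", "fov", "mean", "sd"])

    verdict_rows = []
    for name in names:
        for i, res in enumerate(results[name]):
            worst = res.max_value
            verdict_rows.append(
                {
                    "image": i,
                    "variant": name,
                    "max_uniformity_pct": worst,
                    "passed": bool(worst < threshold_pct),
                }
            )
    verdicts = pd.DataFrame(verdict_rows)

    return StudyReport(
        reference=reference_variant.name,
        variant_names=[v.name for v in variants],
        results=results,
        deviations=deviations,
        mannwhitney=mw,
        agreement=agr,
        samples=samples,
        verdicts=verdicts,
        threshold_pct=threshold_pct,
    )


def _mw_to_dict(res: MannWhitneyResult | None) -> dict[str, Any] | None:
    if res is None:
        return None
    return {
        "u": res.u,
        "z": round(res.z, 6),
        "p_two_sided": float(f"{res.p_two_sided:.6g}"),
        "mean_rank_a": res.mean_rank_a,
        "mean_rank_b": res.mean_rank_b,
        "tie_corrected": res.tie_corrected,
    }


def _agreement_row(name: str, key: str, rep: AgreementReport | None) -> dict[str, Any]:
    metric, _, fov = key.rpartition("_")
    row: dict[str, Any] = {"variant": name, "metric": metric, "fov": fov}
    if rep is None:
        return row
    row["mode"] = rep.mode
    if isinstance(rep.bias, LinearForm):
        row.update(
            bias_intercept=rep.bias.intercept,
            bias_slope=rep.bias.slope,
            half_width_intercept=rep.loa_half_width.intercept,
            half_width_slope=rep.loa_half_width.slope,
        )
    else:
        row.update(bias_intercept=rep.bias, bias_slope=0.0,
                   half_width_intercept=rep.loa_half_width, half_width_slope=0.0)
    row.update(coverage=rep.coverage, n=rep.n, k=rep.k)
    return row


def export_report(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Write the study to CSV/JSON files; reruns are byte-identical.

    Emits deviations.csv, mannwhitney.json, study.json, and — when variants
    exist — agreement.csv plus one Bland–Altman plot-data CSV per
    (variant, metric, fov) comparison.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    dev_path = out_dir / "deviations.csv"
    report.deviations.to_csv(dev_path, index=False, float_format=_FLOAT_FMT)
    written.append(dev_path)

    mw_payload = {
        name: {key: _mw_to_dict(res) for key, res in comparisons.items()}
        for name, comparisons in report.mannwhitney.items()
    }
    mw_path = out_dir / "mannwhitney.json"
    mw_path.write_text(json.dumps(mw_payload, indent=2, sort_keys=True) + "\n")
    written.append(mw_path)

    if report.variant_names:
        rows = [
            _agreement_row(name, key, rep)
            for name, comparisons in report.agreement.items()
            for key, rep in comparisons.items()
        ]
        agr_path = out_dir / "agreement.csv"
        pd.DataFrame(rows).to_csv(agr_path, index=False, float_format=_FLOAT_FMT)
        written.append(agr_path)
        for name, comparisons in report.agreement.items():
            for key, rep in comparisons.items():
                if rep is None:
                    continue
                frame = agreement_frame(report.samples[name][key], rep)
                p = out_dir / f"ba_{name}_{key}.csv"
                frame.to_csv(p, index=False, float_format=_FLOAT_FMT)
                written.append(p)

    study_payload = {
        "reference": report.reference,
        "variants": report.variant_names,
        "threshold_pct": report.threshold_pct,
        "results": {
            name: [r.as_dict(ndigits=6) for r in rows]
            for name, rows in report.results.items()
        },
        "verdicts": report.verdicts.to_dict(orient="records"),
    }
    study_path = out_dir / "study.json"
    study_path.write_text(json.dumps(study_payload, indent=2, sort_keys=True) + "\n")
    written.append(study_path)
    return written
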