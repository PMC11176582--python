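"""End-to-end orchestration: stack -> profile -> metrics -> response -> GI50.

Every stage is also runnable standalone on the previous stage's files via
the CLI; these helpers operate on in-memory objects so tests and the CLI
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import growth, profiles, response, vmetrics
from .synthetic import Cohort

__all__ = ["StackAnalysisParams", "analyze_stack", "cohort_metrics_table",
           "cohort_dose_response", "fit_cohort_gi50", "PipelineResult",
           "run_pipeline"]


@dataclass(frozen=True)
class StackAnalysisParams:
    smoothing_window: int = 3
    roi_width_px: int = 10
    roi_length_factor: float = 1.5
    prominence_frac: float = 0.05
    min_separation: int = 5


def analyze_stack(stack: profiles.SpheroidStack,
                  params: StackAnalysisParams = StackAnalysisParams()
                  ) -> tuple[vmetrics.ViabilityMetrics, profiles.PlotProfile]:
    """Auto-ROI profile extraction, smoothing, baselining, peak detection
    and metric assembly for one spheroid stack.  The diameter comes from
    Otsu segmentation of the central TL slice."""
    roi = profiles.auto_roi(stack, width_px=params.roi_width_px,
                            length_factor=params.roi_length_factor)
    prof = profiles.extract_stack_profile(stack, roi)
    prof = profiles.smooth_profile(prof, window=params.smoothing_window)
    profiles.baseline_and_auc(prof)
    peaks = {
        ch: vmetrics.detect_peaks(prof, ch,
                                  prominence_frac=params.prominence_frac,
                                  min_separation=params.min_separation)
        for ch in stack.channel_names
    }
    zc = stack.shape[1] // 2
    area_mm2, _ = growth.segment_spheroid_area(
        stack.channel("TL")[zc], stack.pixel_size_um
    )
    diameter = growth.diameter_from_area(area_mm2)
    metrics = vmetrics.compute_metrics(prof, peaks, diameter)
    return metrics, prof


def cohort_metrics_table(cohort: Cohort,
                         params: StackAnalysisParams = StackAnalysisParams()
                         ) -> pd.DataFrame:
    """One annotated metrics row per viability stack in a cohort."""
    rows = []
    for ann, stack, _truth in cohort.stacks:
        metrics, _ = analyze_stack(stack, params)
        rows.append({**ann, **metrics.to_dict()})
    if not rows:
        raise ValueError("cohort contains no viability stacks")
    return pd.DataFrame(rows)


def cohort_dose_response(growth_table: pd.DataFrame, day: int
                         ) -> dict[str, growth.DoseResponse]:
    """Per-cell-line dose-response (percent inhibition vs concentration)
    at one timepoint, from a tidy growth table."""
    sub = growth_table[growth_table["day"] == day]
    if sub.empty:
        raise ValueError(f"no growth records for day {day}")
    poc = growth.percent_of_control(sub)
    out = {}
    for line, grp in poc.groupby("cell_line"):
        treated = grp[grp["concentration_ug_ml"] > 0]
        out[line] = growth.DoseResponse(
            concentrations_ug_ml=treated["concentration_ug_ml"].to_numpy(),
            percent_inhibition=treated["percent_inhibition"].to_numpy(),
        )
    return out


def fit_cohort_gi50(growth_table: pd.DataFrame, day: int) -> pd.DataFrame:
    """Absolute GI50 / Emax fit per cell line at one timepoint."""
    fits = []
    for line, dr in cohort_dose_response(growth_table, day).items():
        fit = growth.fit_absolute_gi50(dr)
        fits.append({"cell_line": line, "day": day, **fit.to_dict()})
    return pd.DataFrame(fits)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    model: response.PCAModel
    responses: pd.DataFrame
    thresholds: tuple[float, float]
    gi50: pd.DataFrame
    report: dict = field(default_factory=dict)


def run_pipeline(cohort: Cohort,
                 params: StackAnalysisParams = StackAnalysisParams(),
                 loading_threshold: float = 0.5,
                 gi50_day: int | None = None) -> PipelineResult:
    """Full analysis of an in-memory cohort: viability metrics, filtered
    PCA with distance classes, GI50 fits at the final treatment day, and
    cross-line correlation summaries."""
    metrics = cohort_metrics_table(cohort, params)
    model = response.fit_response_model(metrics, loading_threshold=loading_threshold)
    distances = response.group_distances(model, metrics)
    responses, q25, q75 = response.classify_responses(distances)
    day = gi50_day if gi50_day is not None else max(cohort.schedule.viability_days)
    gi50_fits = fit_cohort_gi50(cohort.growth, day)

    report: dict = {"gi50_day": day, "q25": q25, "q75": q75}
    usable = gi50_fits[gi50_fits["gi50_defined"]]
    if len(usable) >= 3:
        r, p, r2 = growth.correlate(np.log10(usable["gi50_absolute"]),
                                    usable["emax"])
        report["gi50_emax_correlation"] = {"r": r, "p": p, "r2": r2}
    if cohort.ocr_ecar is not None and len(gi50_fits) >= 3:
        merged = gi50_fits.merge(cohort.ocr_ecar, on="cell_line")
        if len(merged) >= 3:
            r, p, r2 = growth.correlate(merged["emax"], merged["ocr_ecar"])
            report["emax_ocr_ecar_correlation"] = {"r": r, "p": p, "r2": r2}
    return PipelineResult(metrics=metrics, model=model, responses=responses,
                          thresholds=(q25, q75), gi50=gi50_fits, report=report)
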