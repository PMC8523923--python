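"""Cohort-level orchestration: series -> thresholds -> splines -> slopes ->
regressions, the chain behind both the CLI and the acceptance runs."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .logutil import get_logger
from .recruit import (
    LevelSeries,
    RecruitSlope,
    RegressionResult,
    aggregate_low_freq,
    estimate_threshold,
    fit_growth_spline,
    median_slope,
    regress_slope_vs_threshold,
)
from .synthgen import CohortEar, simulate_cohort

__all__ = ["CohortResult", "analyze_series", "run_cohort_analysis"]

log = get_logger("pipeline")


def analyze_series(
    series: LevelSeries, config: RunConfig | None = None
) -> RecruitSlope | None:
    """Threshold, spline fit, and median slope for one level series."""
    cfg = config or RunConfig()
    threshold = estimate_threshold(series, criterion=cfg.snr_criterion)
    if threshold is None:
        return None
    try:
        fit = fit_growth_spline(
            series, smoothing=cfg.smoothing, snr_criterion=cfg.snr_criterion
        )
    except ValueError:
        return None  # too few supra-criterion levels to constrain a spline
    return median_slope(fit, threshold, frequency=series.frequency, label=series.label)


@dataclass
class CohortResult:
    ears: list[CohortEar]
    slopes: dict  # (ear_id, label) -> RecruitSlope | None
    per_frequency_regressions: dict  # label -> RegressionResult (hydropic ears)
    low_freq_regression: RegressionResult | None
    control_reference_threshold: float | None


def run_cohort_analysis(
    config: RunConfig | None = None, ears: list[CohortEar] | None = None
) -> CohortResult:
    """Analyze a (simulated) cohort the way the study analyzes ears.

    Per ear and frequency the median-slope metric is computed; per
    frequency the slope is regressed on threshold across impaired ears;
    per ear the low-frequency slopes and threshold shifts (re the control
    low-frequency mean) are aggregated and regressed against each other.
    """
    cfg = config or RunConfig()
    if ears is None:
        ears = simulate_cohort(
            n_hydropic=cfg.n_hydropic, n_control=cfg.n_control, seed=cfg.seed
        )
    slopes: dict = {}
    for ear in ears:
        for label, series in ear.series.items():
            slopes[(ear.ear_id, label)] = analyze_series(series, cfg)

    labels = list(ears[0].series.keys())
    per_freq: dict = {}
    for label in labels:
        pts = [
            (s.threshold, s.median_slope)
            for ear in ears
            if ear.group == "hydropic" and (s := slopes[(ear.ear_id, label)]) is not None
        ]
        try:
            per_freq[label] = regress_slope_vs_threshold(pts)
        except ValueError as exc:
            log.info("per-frequency regression skipped", extra={"params": {"label": label, "reason": str(exc)}})

    # Control reference: mean low-frequency threshold across control ears.
    control_thr = [
        s.threshold
        for ear in ears
        if ear.group == "control"
        for label in labels
        if (s := slopes[(ear.ear_id, label)]) is not None and s.frequency <= 1020.0
    ]
    ref = float(np.mean(control_thr)) if control_thr else None

    low_freq_reg = None
    if ref is not None:
        pts = []
        for ear in ears:
            agg = aggregate_low_freq(
                [slopes[(ear.ear_id, label)] for label in labels], ref
            )
            if agg is not None:
                pts.append((agg[1], agg[0]))  # (threshold shift, mean slope)
        try:
            low_freq_reg = regress_slope_vs_threshold(pts)
        except ValueError as exc:
            log.info("low-frequency regression skipped", extra={"params": {"reason": str(exc)}})

    return CohortResult(
        ears=ears,
        slopes=slopes,
        per_frequency_regressions=per_freq,
        low_freq_regression=low_freq_reg,
        control_reference_threshold=ref,
    )
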