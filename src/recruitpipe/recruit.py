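"""Response-growth analysis: thresholds, smoothing-spline fits, and the
median-slope recruitment metric with its downstream regression statistics.

A level series (response amplitude or delay vs dB SPL) is fit with a
weighted cubic smoothing spline minimizing

    p * sum_i w_i (y_i - g(L_i))^2  +  (1 - p) * integral g''(L)^2 dL

with smoothing coefficient ``p`` (default 0.005; ``p -> 1`` interpolates,
``p -> 0`` tends to the weighted straight-line fit — note that some other
packages invert this convention).  Weights are the per-level SNR in dB,
floored at zero, and set to zero below a 6 dB SNR criterion.  The fit is
evaluated on a 1-dB grid and differentiated analytically; the recruitment
slope of one ear at one frequency is the median derivative at and above
threshold.  Threshold is the lowest tested level whose SNR meets the
criterion at that level and the next (run-of-2 rule); "no threshold" is a
value, not an error, and propagates as absence through the slope metric and
the regressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .core import ValidationError

__all__ = [
    "LevelSeries",
    "GrowthFit",
    "RecruitSlope",
    "RegressionResult",
    "compute_snr",
    "estimate_threshold",
    "fit_growth_spline",
    "median_slope",
    "regress_slope_vs_threshold",
    "aggregate_low_freq",
    "DEFAULT_SMOOTHING",
    "DEFAULT_SNR_CRITERION",
]

DEFAULT_SMOOTHING = 0.005
DEFAULT_SNR_CRITERION = 6.0

MAGNITUDE_KINDS = frozenset({"anow_magnitude", "cap_p2p"})
DELAY_KINDS = frozenset({"anow_phase_delay", "cap_peak_delay"})


@dataclass(frozen=True)
class LevelSeries:
    """Per-level responses for one frequency in one ear.

    ``response`` is in dB re 1 µV RMS for ``anow_magnitude``, µV for
    ``cap_p2p``, and ms for the delay kinds.  ``noise_floor`` shares the
    response units for magnitude kinds; ``snr`` is in dB.
    """

    frequency: float
    label: str
    levels: np.ndarray
    response: np.ndarray
    measure_kind: str
    noise_floor: np.ndarray | None = None
    snr: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("levels", "response", "noise_floor", "snr"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.measure_kind not in MAGNITUDE_KINDS | DELAY_KINDS:
            raise ValidationError(f"unknown measure_kind {self.measure_kind!r}")
        n = self.levels.size
        if np.any(np.diff(self.levels) <= 0):
            raise ValidationError("levels must be strictly ascending")
        for name in ("response", "noise_floor", "snr"):
            v = getattr(self, name)
            if v is not None and v.shape != (n,):
                raise ValidationError(f"{name} must have one entry per level ({n})")

    @property
    def is_magnitude(self) -> bool:
        return self.measure_kind in MAGNITUDE_KINDS

    def with_snr(self, **kwargs) -> "LevelSeries":
        return compute_snr(self, **kwargs)


def compute_snr(series: LevelSeries) -> LevelSeries:
    """SNR per level as response minus noise floor, both in dB.

    ``anow_magnitude`` responses are already in dB; ``cap_p2p`` responses
    (µV) are converted to dB against their µV noise floor.  Delay-kind
    series have no own SNR (it is inherited from the paired magnitude
    series) and raise.
    """
    if not series.is_magnitude:
        raise ValidationError(
            f"SNR is undefined for delay series ({series.measure_kind}); "
            "attach the paired magnitude series' SNR instead"
        )
    if series.noise_floor is None:
        raise ValidationError("noise_floor is required to compute SNR")
    if series.measure_kind == "anow_magnitude":
        snr = series.response - series.noise_floor
    else:  # cap_p2p, linear µV
        with np.errstate(divide="ignore"):
            snr = 20.0 * np.log10(series.response / series.noise_floor)
        snr = np.where(series.response <= 0, -np.inf, snr)
    return replace(series, snr=snr)


def estimate_threshold(
    series: LevelSeries, criterion: float = DEFAULT_SNR_CRITERION
) -> float | None:
    """Lowest tested level meeting the SNR criterion there and at the next
    tested level (run-of-2 rule); None when no level qualifies."""
    if series.snr is None:
        raise ValidationError("snr must be computed before threshold estimation")
    ok = series.snr >= criterion
    for i in range(ok.size - 1):
        if ok[i] and ok[i + 1]:
            return float(series.levels[i])
    return None


@dataclass(frozen=True)
class GrowthFit:
    """Smoothing-spline fit on a 1-dB grid with its analytic derivative."""

    grid: np.ndarray
    fitted: np.ndarray
    derivative: np.ndarray
    smoothing_coefficient: float
    weights_used: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(np.diff(self.grid), 1.0):
            raise ValidationError("grid spacing must be exactly 1 dB")


def _smoothing_spline(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float
) -> CubicSpline:
    """Weighted natural cubic smoothing spline (Reinsch/Green–Silverman).

    Minimizes ``sum w_i (y_i - g(x_i))^2 + lam * int g''^2`` by solving the
    normal equations ``(W + lam * Q R^-1 Q^T) g = W y`` for the fitted knot
    values; the minimizer is then the natural cubic interpolant of those
    values.  Dense linear algebra — intended for the short level series this
    package fits.
    """
    n = x.size
    h = np.diff(x)
    # Q: n x (n-2), R: (n-2) x (n-2) as in Green & Silverman (1994)
    q = np.zeros((n, n - 2))
    r = np.zeros((n - 2, n - 2))
    for j in range(1, n - 1):
        q[j - 1, j - 1] = 1.0 / h[j - 1]
        q[j, j - 1] = -(1.0 / h[j - 1] + 1.0 / h[j])
        q[j + 1, j - 1] = 1.0 / h[j]
        r[j - 1, j - 1] = (h[j - 1] + h[j]) / 3.0
        if j < n - 2:
            r[j - 1, j] = r[j, j - 1] = h[j] / 6.0
    k = q @ np.linalg.solve(r, q.T)
    g = np.linalg.solve(np.diag(w) + lam * k, w * y)
    return CubicSpline(x, g, bc_type="natural")


def fit_growth_spline(
    series: LevelSeries,
    smoothing: float = DEFAULT_SMOOTHING,
    snr_criterion: float = DEFAULT_SNR_CRITERION,
    weights: np.ndarray | None = None,
) -> GrowthFit:
    """Fit a weighted smoothing spline to a level series.

    Weights default to the per-level SNR in dB floored at 0, zeroed below
    ``snr_criterion``; zero-weight points are excluded from the objective
    (they are provably inert).  The fit and its analytic derivative are
    evaluated on the 1-dB grid spanning the tested level range; beyond the
    outermost weighted points the natural spline is continued linearly (its
    curvature there is zero).
    """
    if not 0 < smoothing < 1:
        raise ValidationError(f"smoothing must lie in (0, 1), got {smoothing}")
    if weights is None:
        if series.snr is None:
            raise ValidationError("series needs snr (or explicit weights) for fitting")
        weights = np.clip(series.snr, 0.0, None)
        weights[series.snr < snr_criterion] = 0.0
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != series.levels.shape or np.any(weights < 0):
            raise ValidationError("weights must be non-negative, one per level")
    active = weights > 0
    if active.sum() < 4:
        raise ValidationError(
            f"need >= 4 levels with nonzero weight to fit a spline, got {int(active.sum())}"
        )
    x, y, w = series.levels[active], series.response[active], weights[active]
    lam = (1.0 - smoothing) / smoothing
    spline = _smoothing_spline(x, y, w, lam)

    grid = np.arange(series.levels[0], series.levels[-1] + 0.5)
    fitted = spline(grid)
    deriv = spline(grid, 1)
    # Linear continuation outside the weighted support (natural spline).
    for edge, sl in ((x[0], grid < x[0]), (x[-1], grid > x[-1])):
        if sl.any():
            d = float(spline(edge, 1))
            fitted[sl] = float(spline(edge)) + d * (grid[sl] - edge)
            deriv[sl] = d
    return GrowthFit(
        grid=grid,
        fitted=fitted,
        derivative=deriv,
        smoothing_coefficient=smoothing,
        weights_used=weights,
    )


@dataclass(frozen=True)
class RecruitSlope:
    """Median-slope recruitment metric for one ear at one frequency."""

    frequency: float
    label: str
    threshold: float
    median_slope: float
    n_grid_points_used: int


def median_slope(
    fit: GrowthFit, threshold: float | None, frequency: float = 0.0, label: str = ""
) -> RecruitSlope | None:
    """Median spline derivative at and above threshold; None propagates."""
    if threshold is None:
        return None
    supra = fit.grid >= threshold
    if not supra.any():
        return None
    return RecruitSlope(
        frequency=frequency,
        label=label,
        threshold=float(threshold),
        median_slope=float(np.median(fit.derivative[supra])),
        n_grid_points_used=int(supra.sum()),
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of the recruitment slope against threshold (or area/shift)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValidationError(f"r_squared must lie in [0, 1], got {self.r_squared}")
        if not self.ci_low <= self.slope <= self.ci_high:
            raise ValidationError("the 95% CI must contain the slope estimate")


def regress_slope_vs_threshold(points: Sequence[tuple[float, float]]) -> RegressionResult:
    """Ordinary least squares of slope on threshold with t-based inference.

    Returns the slope coefficient with its two-sided p-value (slope != 0,
    t distribution on n-2 df) and 95% confidence interval.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 (threshold, slope) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValidationError("degenerate regression: all thresholds are equal")
    res = stats.linregress(x, y)
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n=n,
    )


def aggregate_low_freq(
    slopes: Sequence[RecruitSlope | None],
    control_reference_threshold: float,
    cutoff: float = 1020.0,
) -> tuple[float, float] | None:
    """Average the slope metric and threshold shift across low frequencies.

    ``slopes`` holds per-frequency results for one ear (absent entries are
    skipped); frequencies at or below ``cutoff`` qualify.  The default
    cutoff of 1,020 Hz admits the series labelled "1 kHz", whose actual
    stimulus frequency is 1,020 Hz.  The threshold
    shift is the mean low-frequency threshold minus the caller-supplied
    control-cohort low-frequency mean.  Returns ``(mean_slope, mean_shift)``
    or None when no frequency qualifies.
    """
    qual = [s for s in slopes if s is not None and s.frequency <= cutoff]
    if not qual:
        return None
    mean_slope = float(np.mean([s.median_slope for s in qual]))
    mean_shift = float(np.mean([s.threshold for s in qual])) - control_reference_threshold
    return mean_slope, mean_shift
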