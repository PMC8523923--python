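"""Compound action potential (CAP) averaging and N1/P1 peak picking.

CAP epochs are recorded in alternating polarity; artifact-bearing epochs are
dropped outright (together with their polarity partner, to preserve the
cancellation of the cochlear microphonic in the grand average), the retained
epochs are averaged, and an automated picker locates the N1 trough and the
following P1 peak with sub-sample parabolic refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .condition import (
    CAP_PASSBAND,
    ArtifactReport,
    FilterKernel,
    design_bandpass_fir,
    detect_artifacts_quartile,
    filter_epochs,
)
from .core import EpochMatrix, ValidationError

__all__ = [
    "CapPeaks",
    "reject_artifact_epochs",
    "average_cap",
    "pick_peaks",
    "analyze_cap",
]


@dataclass(frozen=True)
class CapPeaks:
    """N1/P1 amplitudes (µV) and latencies (ms re stimulus onset).

    ``quality_flag`` is ``"good"``, ``"low_snr"`` (|N1| under 3x the
    pre-onset RMS) or ``"no_response"`` (no usable extrema; numeric fields
    are then None).
    """

    n1_latency: float | None
    n1_amplitude: float | None
    p1_latency: float | None
    p1_amplitude: float | None
    quality_flag: str = "good"

    def __post_init__(self) -> None:
        if self.quality_flag == "no_response":
            return
        if self.p1_latency <= self.n1_latency:
            raise ValidationError(
                f"p1_latency ({self.p1_latency}) must exceed n1_latency ({self.n1_latency})"
            )
        if self.peak_to_peak < 0:
            raise ValidationError("peak_to_peak must be >= 0")

    @property
    def found(self) -> bool:
        return self.quality_flag != "no_response"

    @property
    def peak_to_peak(self) -> float | None:
        if not self.found:
            return None
        return self.p1_amplitude - self.n1_amplitude


def reject_artifact_epochs(
    epochs: EpochMatrix, report: ArtifactReport
) -> tuple[EpochMatrix, int]:
    """Drop epochs containing any flagged sample, keeping polarity balance.

    When an epoch is removed, its +/− partner is removed too so the retained
    set still alternates and averages the microphonic to zero.  Returns the
    retained matrix and count.
    """
    bad = np.zeros(epochs.n_epochs, dtype=bool)
    if report.positions.size:
        if report.positions[:, 0].max() >= epochs.n_epochs:
            raise ValidationError("artifact report indexes epochs beyond the matrix")
        bad[np.unique(report.positions[:, 0])] = True
    pair_bad = bad.reshape(-1, 2).any(axis=1)
    keep = np.repeat(~pair_bad, 2)
    if not keep.any():
        raise ValidationError("all epochs flagged as artifacts; nothing to average")
    retained = epochs.copy_with(data=epochs.data[keep], polarity=epochs.polarity[keep])
    return retained, int(keep.sum())


def average_cap(epochs: EpochMatrix) -> np.ndarray:
    """Grand mean across retained alternating epochs (cancels the CM)."""
    return epochs.data.mean(axis=0)


def _refine(wave: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic 3-point interpolation around sample ``i``."""
    if i <= 0 or i >= wave.size - 1:
        return float(i), float(wave[i])
    y0, y1, y2 = wave[i - 1], wave[i], wave[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(i), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    return i + delta, y1 - 0.25 * (y0 - y2) * delta


def pick_peaks(
    waveform: np.ndarray,
    sample_rate: float,
    onset_sample: int = 0,
    n1_window: tuple[float, float] = (0.5, 6.0),
    p1_max_lag: float = 5.0,
) -> CapPeaks:
    """Locate N1 and P1 on an averaged CAP waveform.

    N1 is the most negative local extremum within ``n1_window`` (ms re
    onset); P1 is the most positive local extremum within
    ``(n1_latency, n1_latency + p1_max_lag]``.  Ties go to the earliest
    latency.  A flat or extremum-free window yields a "no response" result
    rather than an error.
    """
    wave = np.asarray(waveform, dtype=float)
    ms = (np.arange(wave.size) - onset_sample) / sample_rate * 1e3
    lo, hi = n1_window
    if ms[-1] < hi or ms[0] > lo:
        raise ValidationError(
            f"waveform ({ms[0]:.2f}-{ms[-1]:.2f} ms) does not span the N1 window {n1_window}"
        )

    n1 = _extremum(wave, ms, lo, hi, mode="min")
    if n1 is None:
        return CapPeaks(None, None, None, None, quality_flag="no_response")
    n1_lat, n1_amp = n1
    p1 = _extremum(wave, ms, n1_lat, n1_lat + p1_max_lag, mode="max", strict_lo=True)
    if p1 is None or p1[1] < n1_amp:
        return CapPeaks(None, None, None, None, quality_flag="no_response")
    p1_lat, p1_amp = p1

    quality = "good"
    pre = wave[: onset_sample] if onset_sample > 0 else wave[ms < lo]
    if pre.size >= 4:
        rms = math.sqrt(float(np.mean(pre**2)))
        if rms > 0 and abs(n1_amp) < 3 * rms:
            quality = "low_snr"
    return CapPeaks(
        n1_latency=float(n1_lat),
        n1_amplitude=float(n1_amp),
        p1_latency=float(p1_lat),
        p1_amplitude=float(p1_amp),
        quality_flag=quality,
    )


def analyze_cap(
    epochs: EpochMatrix,
    kernel: FilterKernel | None = None,
    fence: float | None = 3.0,
    apply_filter: bool = True,
    **pick_kwargs,
) -> tuple[CapPeaks, int]:
    """Full CAP chain: filter, drop artifact epochs, average, pick peaks.

    Returns the peaks and the number of retained epochs.  Unlike the ANOW
    path, artifact-bearing epochs are removed outright (with their polarity
    partners) instead of being down-weighted.
    """
    if apply_filter:
        if kernel is None:
            kernel = design_bandpass_fir(*CAP_PASSBAND, epochs.sample_rate)
        epochs = filter_epochs(epochs, kernel)
    n_kept = epochs.n_epochs
    if fence is not None:
        _, report = detect_artifacts_quartile(epochs, fence=fence)
        epochs, n_kept = reject_artifact_epochs(epochs, report)
    wave = average_cap(epochs)
    peaks = pick_peaks(
        wave, epochs.sample_rate, onset_sample=epochs.onset_sample, **pick_kwargs
    )
    return peaks, n_kept


def _extremum(
    wave: np.ndarray,
    ms: np.ndarray,
    lo: float,
    hi: float,
    mode: str,
    strict_lo: bool = False,
) -> tuple[float, float] | None:
    """Best local extremum in (lo, hi]; None if the window has none."""
    y = wave if mode == "max" else -wave
    inside = (ms > lo) if strict_lo else (ms >= lo)
    inside &= ms <= hi
    idx = np.nonzero(inside)[0]
    idx = idx[(idx > 0) & (idx < wave.size - 1)]
    if idx.size == 0:
        return None
    is_ext = (y[idx] > y[idx - 1]) & (y[idx] >= y[idx + 1])
    cand = idx[is_ext]
    if cand.size == 0:
        return None
    best = cand[np.argmax(y[cand])]  # argmax returns the earliest on ties
    i_ref, amp = _refine(wave, int(best))
    dt = ms[1] - ms[0]
    return float(ms[0] + i_ref * dt), float(amp)
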