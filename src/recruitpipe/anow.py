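"""Auditory Nerve Overlapped Waveform (ANOW) estimation.

Low-frequency tone bursts are presented in alternating polarity.  The
cochlear microphonic follows the stimulus and inverts with polarity, while
phase-locked neural firing does not; averaging each +/− epoch pair therefore
cancels the microphonic and leaves the neural response, whose energy sits at
twice the stimulus frequency.  Each overlapped waveform is fit by weighted
least squares with sinusoids at 2f in cosine and minus-sine phase (binary
weights excise artifact samples without edge splatter); the complex mean of
the per-pair coefficients is the signal and the standard error of that mean
is the noise floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .condition import (
    ANOW_PASSBAND,
    FilterKernel,
    WeightMask,
    design_bandpass_fir,
    detect_artifacts_quartile,
    filter_epochs,
)
from .core import ComplexResponse, EpochMatrix, ValidationError

__all__ = [
    "OverlappedSet",
    "overlap_pairs",
    "fit_sinusoid",
    "fit_second_harmonic",
    "aggregate_response",
    "analyze_anow",
    "phase_delays",
]


@dataclass
class OverlappedSet:
    """Per-pair averaged waveforms with combined weights."""

    waveforms: np.ndarray  # (n_pairs, n_samples)
    weights: np.ndarray  # same shape, binary
    frequency: float  # stimulus frequency (Hz)
    sample_rate: float
    onset_sample: int = 0
    edge_invalid: int = 0

    @property
    def n_pairs(self) -> int:
        return self.waveforms.shape[0]


def overlap_pairs(epochs: EpochMatrix, mask: WeightMask | None = None) -> OverlappedSet:
    """Average consecutive +/− epoch pairs, AND-combining their weights."""
    if epochs.stimulus is None:
        raise ValidationError("epochs must carry their stimulus metadata")
    pairs = epochs.data.reshape(epochs.n_epochs // 2, 2, epochs.n_samples)
    waveforms = pairs.mean(axis=1)
    if mask is None:
        weights = np.ones_like(waveforms)
    else:
        if mask.weights.shape != epochs.data.shape:
            raise ValidationError(
                f"mask shape {mask.weights.shape} does not match epochs {epochs.data.shape}"
            )
        w = mask.weights.reshape(epochs.n_epochs // 2, 2, epochs.n_samples)
        weights = w[:, 0, :] * w[:, 1, :]
    return OverlappedSet(
        waveforms=waveforms,
        weights=weights,
        frequency=epochs.stimulus.frequency,
        sample_rate=epochs.sample_rate,
        onset_sample=epochs.onset_sample,
        edge_invalid=epochs.edge_invalid,
    )


def fit_sinusoid(
    waveform: np.ndarray,
    f: float,
    sample_rate: float,
    weights: np.ndarray | None = None,
    t0_sample: int = 0,
    min_cycles: float = 10.0,
) -> tuple[float, float]:
    """Weighted least-squares sinusoid amplitude estimate at frequency ``f``.

    Solves ``y(t) ≈ a*cos(2*pi*f*t) + b*(-sin(2*pi*f*t))`` over the samples
    with nonzero weight, with ``t`` measured from ``t0_sample``.  Returns
    ``(a, b)`` — the real and imaginary parts of the complex coefficient.
    With uniform weights over an integer number of cycles this equals
    ``2/N`` times the DFT bin at ``f``.
    """
    y = np.asarray(waveform, dtype=float)
    if weights is None:
        sel = np.ones(y.size, dtype=bool)
    else:
        sel = np.asarray(weights) != 0
    n_sel = int(sel.sum())
    duration = n_sel / sample_rate
    if duration * f < min_cycles:
        raise ValidationError(
            f"insufficient weighted support: {duration * 1e3:.2f} ms covers "
            f"{duration * f:.1f} cycles of {f:g} Hz (need >= {min_cycles})"
        )
    t = (np.arange(y.size) - t0_sample)[sel] / sample_rate
    theta = 2 * np.pi * f * t
    design = np.column_stack([np.cos(theta), -np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, y[sel], rcond=None)
    return float(coef[0]), float(coef[1])


def fit_second_harmonic(
    waveform: np.ndarray,
    weights: np.ndarray | None,
    f: float,
    sample_rate: float,
    t0_sample: int = 0,
) -> tuple[float, float]:
    """Least-squares coefficient at twice the stimulus frequency."""
    return fit_sinusoid(waveform, 2 * f, sample_rate, weights=weights, t0_sample=t0_sample)


def aggregate_response(
    coeffs: Sequence[complex] | np.ndarray, analysis_frequency: float
) -> ComplexResponse:
    """Complex mean of per-pair coefficients with an SEM noise floor.

    The noise floor combines the per-axis standard errors of the mean:
    ``sqrt(SEM_real**2 + SEM_imag**2)``.  (The SEM of the magnitudes is not
    used: it is biased upward at low SNR.)
    """
    c = np.asarray(coeffs, dtype=complex)
    if c.ndim != 1 or c.size < 2:
        raise ValidationError(f"need >= 2 coefficients for an SEM, got {c.size}")
    n = c.size
    mean = c.mean()
    sem_r = c.real.std(ddof=1) / math.sqrt(n)
    sem_i = c.imag.std(ddof=1) / math.sqrt(n)
    return ComplexResponse(
        real=float(mean.real),
        imag=float(mean.imag),
        noise_floor=float(math.hypot(sem_r, sem_i)),
        n_contributing=n,
        analysis_frequency=analysis_frequency,
    )


def analyze_anow(
    epochs: EpochMatrix,
    kernel: FilterKernel | None = None,
    fence: float | None = 3.0,
    prefilter: bool = False,
) -> ComplexResponse:
    """Full ANOW chain: flag artifacts, overlap, fit at 2f, aggregate.

    Artifact detection and the weighted fit run on the epochs as given:
    the detector must localize transients, and band-limiting with a long
    linear-phase kernel delocalizes them, while the single-frequency
    least-squares fit is already narrowband (a passband filter would change
    its value only by the kernel's gain at 2f).  Set ``prefilter=True`` to
    band-limit first anyway (600–1,600 Hz), e.g. for recordings with heavy
    out-of-band interference; detection then sees the filtered data.

    The analysis window is the steady-state portion of the burst: onset and
    offset ramps and any filter-invalid edges are zero-weighted.  With
    ``fence=None`` artifact detection is skipped (all weights 1).
    """
    if epochs.stimulus is None:
        raise ValidationError("epochs must carry their stimulus metadata")
    spec = epochs.stimulus
    if prefilter:
        if kernel is None:
            kernel = design_bandpass_fir(*ANOW_PASSBAND, epochs.sample_rate)
        epochs = filter_epochs(epochs, kernel)
    if fence is not None:
        mask, _ = detect_artifacts_quartile(epochs, fence=fence)
    else:
        mask = None
    overlapped = overlap_pairs(epochs, mask)

    weights = overlapped.weights.copy()
    lo = max(overlapped.edge_invalid, epochs.onset_sample + spec.rise_fall_samples)
    hi = min(
        epochs.n_samples - overlapped.edge_invalid,
        epochs.onset_sample + spec.n_samples - spec.rise_fall_samples,
    )
    if hi - lo <= 0:
        raise ValidationError(
            "edge_invalid/ramp exclusion leaves an empty analysis window"
        )
    weights[:, :lo] = 0.0
    weights[:, hi:] = 0.0

    coeffs = [
        complex(*fit_second_harmonic(w, wt, spec.frequency, epochs.sample_rate,
                                     t0_sample=epochs.onset_sample))
        for w, wt in zip(overlapped.waveforms, weights)
    ]
    return aggregate_response(coeffs, analysis_frequency=2 * spec.frequency)


def phase_delays(responses: Sequence[ComplexResponse]) -> np.ndarray:
    """Phase delays (ms) for a level series of 2f responses.

    Phase is unwrapped from the highest level downward (the highest level
    has the best SNR) and converted to delay as ``-phase / (2*pi*2f)``.
    """
    if len(responses) == 0:
        return np.empty(0)
    phases = np.array([r.phase for r in responses])
    f2 = responses[-1].analysis_frequency
    unwrapped = np.unwrap(phases[::-1])[::-1]
    return -unwrapped / (2 * np.pi * f2) * 1e3
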