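"""Otoacoustic emission extraction from averaged microphone frames.

Two emission types are handled:

* SFOAE via the double-evoked method: three interleaved conditions (probe
  alone, suppressor alone, both together) are combined as
  ``probe + suppressor - both``.  Any response linear in the stimuli cancels
  exactly — the stimulus and system distortion drop out — leaving the
  emission component that the suppressor removed.
* DPOAE at 2f1-f2: two primaries at f2/f1 = 1.22 drive the cochlear
  nonlinearity; the component at 2f1-f2 is extracted directly.

Components are estimated per frame with the same least-squares sinusoid
estimator the ANOW path uses (all weights 1); the complex mean across
frames is the emission and the standard error of the mean is the noise
floor, reported in dB SPL re 20 µPa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anow import aggregate_response, fit_sinusoid
from .core import ComplexResponse, ValidationError

__all__ = [
    "OaeFrameSet",
    "double_evoked_residual",
    "extract_tone_component",
    "dpoae_level",
    "DPOAE_RATIO",
]

#: Primary-frequency ratio f2/f1 used for DPOAE stimulation.
DPOAE_RATIO = 1.22


@dataclass
class OaeFrameSet:
    """Repetitions x samples of microphone pressure (Pa) with stimulus info.

    For DPOAE measurements set ``f1``/``f2`` (Hz) and ``l1``/``l2``
    (dB SPL); for SFOAE measurements set ``probe_frequency`` and
    ``suppressor_offset`` (the suppressor sits 50 Hz above the probe).
    ``rise_fall`` (ms) of the tone is discarded from analysis at each end.
    """

    frames: np.ndarray
    sample_rate: float
    f1: float | None = None
    f2: float | None = None
    l1: float | None = None
    l2: float | None = None
    probe_frequency: float | None = None
    suppressor_offset: float = 50.0
    rise_fall: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2:
            raise ValidationError(
                f"frames must be 2-D (repetitions x samples), got ndim={self.frames.ndim}"
            )

    @property
    def n_repetitions(self) -> int:
        return self.frames.shape[0]

    @property
    def dp_frequency(self) -> float:
        """Cubic distortion frequency 2*f1 - f2."""
        if self.f1 is None or self.f2 is None:
            raise ValidationError("f1 and f2 must be recorded for a DPOAE frame set")
        fdp = 2 * self.f1 - self.f2
        if fdp <= 0:
            raise ValidationError(f"2*f1 - f2 must be positive, got {fdp} Hz")
        return fdp


def double_evoked_residual(
    frames_probe: np.ndarray,
    frames_suppressor: np.ndarray,
    frames_both: np.ndarray,
) -> np.ndarray:
    """Per-repetition double-evoked residual ``probe + suppressor - both``.

    All three condition blocks must share the same shape.  Per-repetition
    residuals are retained (rather than a single averaged trace) so the
    downstream component estimate keeps its SEM noise floor.
    """
    fp = np.asarray(frames_probe, dtype=float)
    fs = np.asarray(frames_suppressor, dtype=float)
    fb = np.asarray(frames_both, dtype=float)
    if not (fp.shape == fs.shape == fb.shape) or fp.ndim != 2:
        raise ValidationError(
            f"condition blocks must share one 2-D shape, got {fp.shape}, {fs.shape}, {fb.shape}"
        )
    return fp + fs - fb


def extract_tone_component(
    frames: np.ndarray,
    f: float,
    sample_rate: float,
    rise_fall_ms: float = 0.0,
) -> ComplexResponse:
    """Complex component at ``f`` averaged across frames, with SEM floor.

    Each frame is fit by least squares at ``f`` over its steady-state
    portion (``rise_fall_ms`` trimmed from each end); the per-frame
    coefficients are aggregated exactly as ANOW coefficients are.
    """
    x = np.asarray(frames, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError(f"need >= 2 frames, got shape {x.shape}")
    n = x.shape[1]
    trim = int(round(rise_fall_ms * 1e-3 * sample_rate))
    if 2 * trim >= n:
        raise ValidationError("rise/fall trim leaves no steady-state samples")
    weights = np.zeros(n)
    weights[trim : n - trim] = 1.0
    coeffs = [
        complex(*fit_sinusoid(frame, f, sample_rate, weights=weights)) for frame in x
    ]
    return aggregate_response(coeffs, analysis_frequency=f)


def dpoae_level(frames: OaeFrameSet) -> ComplexResponse:
    """Distortion-product component at 2f1-f2 for a DPOAE frame set."""
    return extract_tone_component(
        frames.frames, frames.dp_frequency, frames.sample_rate, rise_fall_ms=frames.rise_fall
    )
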