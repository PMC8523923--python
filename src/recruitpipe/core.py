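"""Core containers shared across the pipeline.

Units convention: electrode voltages are input-referred microvolts (µV),
microphone pressures are pascals (Pa), stimulus levels are dB SPL, time is
milliseconds relative to stimulus onset, and sample indices are 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ValidationError",
    "ToneBurstSpec",
    "EpochMatrix",
    "ComplexResponse",
    "DB_FLOOR_MIN",
]

#: Clamp for dB conversion of a vanishing noise floor (dB re 1 µV RMS).
DB_FLOOR_MIN = -40.0


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant.

    The message always names the offending field.
    """


@dataclass(frozen=True)
class ToneBurstSpec:
    """Stimulus description for one tone-burst level series entry.

    Parameters
    ----------
    frequency : float
        Stimulus frequency in Hz (the actual frequency, e.g. 480 Hz for the
        series labelled "500 Hz").
    duration : float
        Tone-burst duration in ms.
    rise_fall : float
        Raised-cosine ramp duration in ms (each of onset and offset).
    level : float
        Sound level in dB SPL.
    n_repetitions : int
        Number of presentations; must be even because polarity alternates.
    polarity_start : int
        Polarity of the first presentation, +1 or -1.
    sample_rate : float
        A/D rate in Hz (default 96 kHz).
    """

    frequency: float
    duration: float
    rise_fall: float = 0.0
    level: float = 60.0
    n_repetitions: int = 92
    polarity_start: int = 1
    sample_rate: float = 96000.0

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValidationError(f"frequency must be > 0, got {self.frequency}")
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.rise_fall < 0 or 2 * self.rise_fall > self.duration:
            raise ValidationError(
                f"rise_fall must satisfy 0 <= 2*rise_fall <= duration, got "
                f"rise_fall={self.rise_fall}, duration={self.duration}"
            )
        if self.n_repetitions % 2 != 0 or self.n_repetitions <= 0:
            raise ValidationError(
                f"n_repetitions must be a positive even count, got {self.n_repetitions}"
            )
        if self.polarity_start not in (1, -1):
            raise ValidationError(f"polarity_start must be +1 or -1, got {self.polarity_start}")
        if self.sample_rate < 4 * self.frequency:
            raise ValidationError(
                f"sample_rate must be >= 4*frequency ({4 * self.frequency} Hz), "
                f"got {self.sample_rate}"
            )

    @property
    def n_samples(self) -> int:
        """Samples covered by the burst itself."""
        return int(round(self.duration * 1e-3 * self.sample_rate))

    @property
    def rise_fall_samples(self) -> int:
        return int(round(self.rise_fall * 1e-3 * self.sample_rate))


@dataclass
class EpochMatrix:
    """Repetitions x samples of electrode voltage with alternating polarity.

    ``data`` is a 2-D float array (µV).  ``polarity`` holds one +1/-1 label
    per epoch and must alternate strictly.  ``edge_invalid`` counts samples
    at each end rendered unreliable by FIR filtering (half the kernel).
    """

    data: np.ndarray
    sample_rate: float
    polarity: np.ndarray
    stimulus: ToneBurstSpec | None = None
    onset_sample: int = 0
    edge_invalid: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.polarity = np.asarray(self.polarity, dtype=int)
        if self.data.ndim != 2:
            raise ValidationError(f"data must be 2-D (epochs x samples), got ndim={self.data.ndim}")
        n = self.data.shape[0]
        if n % 2 != 0 or n == 0:
            raise ValidationError(f"data must hold an even, positive number of epochs, got {n}")
        if self.polarity.shape != (n,):
            raise ValidationError(
                f"polarity must have one label per epoch ({n}), got shape {self.polarity.shape}"
            )
        expected = self.polarity[0] * (-1) ** np.arange(n)
        if self.polarity[0] not in (1, -1) or not np.array_equal(self.polarity, expected):
            raise ValidationError("polarity must alternate strictly (+1,-1,+1,...)")
        if not 0 <= self.onset_sample < self.data.shape[1]:
            raise ValidationError(
                f"onset_sample must lie within the epoch [0, {self.data.shape[1]}), "
                f"got {self.onset_sample}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def times(self) -> np.ndarray:
        """Sample times in seconds re stimulus onset."""
        return (np.arange(self.n_samples) - self.onset_sample) / self.sample_rate

    def copy_with(self, **kwargs) -> "EpochMatrix":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ComplexResponse:
    """Complex component at one analysis frequency with an SEM noise floor.

    The signal is the mean of per-waveform complex coefficients (cosine and
    minus-sine amplitudes); the noise floor is the standard error of that
    mean, combined across the two axes: sqrt(SEM_real^2 + SEM_imag^2).
    Voltage responses are in µV, pressure responses in Pa.
    """

    real: float
    imag: float
    noise_floor: float
    n_contributing: int
    analysis_frequency: float

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValidationError(f"noise_floor must be >= 0, got {self.noise_floor}")

    @property
    def magnitude(self) -> float:
        return math.hypot(self.real, self.imag)

    @property
    def phase(self) -> float:
        """Four-quadrant arctangent of imag/real, in (-pi, pi]."""
        return math.atan2(self.imag, self.real)

    @property
    def snr_db(self) -> float:
        """Magnitude over noise floor in dB (RMS conversion cancels)."""
        if self.noise_floor == 0:
            return math.inf
        if self.magnitude == 0:
            return -math.inf
        return 20.0 * math.log10(self.magnitude / self.noise_floor)

    def rms_db(self, ref: float = 1.0, floor_min_db: float = DB_FLOOR_MIN) -> float:
        """RMS magnitude in dB re ``ref`` (sinusoid RMS = amplitude/sqrt(2))."""
        return _db(self.magnitude / math.sqrt(2.0), ref, floor_min_db)

    def noise_floor_rms_db(self, ref: float = 1.0, floor_min_db: float = DB_FLOOR_MIN) -> float:
        return _db(self.noise_floor / math.sqrt(2.0), ref, floor_min_db)

    def spl_db(self, floor_min_db: float = -40.0) -> float:
        """Sound pressure level in dB SPL re 20 µPa (pressure responses)."""
        return _db(self.magnitude, 20e-6, floor_min_db)

    def noise_floor_spl_db(self, floor_min_db: float = -40.0) -> float:
        return _db(self.noise_floor, 20e-6, floor_min_db)


def _db(value: float, ref: float, floor_min_db: float) -> float:
    if value <= 0:
        return floor_min_db
    return max(20.0 * math.log10(value / ref), floor_min_db)
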