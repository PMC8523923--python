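"""Epoch conditioning: linear-phase FIR band-limiting and artifact flagging.

Round-window recordings are band-limited with symmetric (linear-phase) FIR
kernels — 600–1,600 Hz for the ANOW path, 150–1,500 Hz for the CAP path —
and corrected for the filter group delay so filtered features stay aligned
with stimulus onset.  High-amplitude transients are flagged with a pooled
Tukey-fence (quartile) detector on the absolute deviation from the ensemble
median waveform; flagged samples get weight 0, everything else weight 1.
Flags are recorded, never excised: the ANOW fit consumes the weights, while
the CAP path drops whole flagged epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import EpochMatrix, ValidationError

__all__ = [
    "FilterKernel",
    "FilterDesignError",
    "WeightMask",
    "ArtifactReport",
    "design_bandpass_fir",
    "filter_epochs",
    "detect_artifacts_quartile",
    "ANOW_PASSBAND",
    "CAP_PASSBAND",
    "DEFAULT_FENCE",
]

ANOW_PASSBAND = (600.0, 1600.0)
CAP_PASSBAND = (150.0, 1500.0)
#: Tukey fence multiplier on the pooled IQR of deviations.
DEFAULT_FENCE = 3.0
#: Fraction of flagged samples above which a whole epoch is flagged.
EPOCH_FLAG_FRACTION = 0.10


class FilterDesignError(ValueError):
    """Raised when a kernel cannot meet its passband/stopband contract."""


@dataclass(frozen=True)
class FilterKernel:
    """Symmetric FIR kernel with its passband and design metadata."""

    taps: np.ndarray
    passband: tuple[float, float]
    sample_rate: float

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if taps.ndim != 1 or taps.size % 2 == 0:
            raise ValidationError(f"taps must be a 1-D odd-length vector, got shape {taps.shape}")
        if not np.allclose(taps, taps[::-1], rtol=0, atol=1e-12 * max(np.abs(taps).max(), 1)):
            raise ValidationError("taps must be symmetric (linear phase)")

    @property
    def n_taps(self) -> int:
        return self.taps.size

    @property
    def group_delay(self) -> int:
        """Integer group delay in samples ((n_taps - 1) / 2)."""
        return (self.n_taps - 1) // 2

    def response_db(self, freqs) -> np.ndarray:
        """Magnitude response in dB at the given frequencies (Hz)."""
        _, h = signal.freqz(self.taps, worN=np.atleast_1d(np.asarray(freqs, float)),
                           fs=self.sample_rate)
        return 20.0 * np.log10(np.abs(h) + 1e-300)


def design_bandpass_fir(
    low: float,
    high: float,
    sample_rate: float,
    n_taps: int | None = None,
    attenuation_db: float = 45.0,
) -> FilterKernel:
    """Design a linear-phase Kaiser-window bandpass kernel.

    The design targets a flat (±1 dB) response across ``[low, high]`` and
    ``attenuation_db`` of rejection at ``low/2`` and at
    ``min(2*high, 0.9*Nyquist)``.  With ``n_taps=None`` the tap count is
    chosen to honour both; with an explicit ``n_taps`` the transition bands
    are widened to whatever the kernel length affords (passband flatness is
    preserved; stopband edges may move inward).
    """
    nyq = sample_rate / 2.0
    if not 0 < low < high < nyq:
        raise ValidationError(
            f"passband must satisfy 0 < low < high < Nyquist, got ({low}, {high}) at fs={sample_rate}"
        )
    stop_lo = low / 2.0
    stop_hi = min(2.0 * high, 0.9 * nyq)
    want_lo, want_hi = low - stop_lo, stop_hi - high

    beta = signal.kaiser_beta(attenuation_db)
    if n_taps is None:
        width = min(want_lo, want_hi)
        n_taps, _ = signal.kaiserord(attenuation_db, width / nyq)
        n_taps += 1 - n_taps % 2  # odd for integer group delay
    else:
        if n_taps % 2 == 0 or n_taps < 3:
            raise ValidationError(f"n_taps must be odd and >= 3, got {n_taps}")
    # Transition width this kernel length affords at the target attenuation
    # (Kaiser estimate), never narrower than requested.
    afford = (attenuation_db - 7.95) / (2.285 * (n_taps - 1)) / (2 * np.pi) * sample_rate
    trans_lo = max(want_lo, afford)
    trans_hi = max(want_hi, afford)
    cut_lo = low - trans_lo / 2.0
    cut_hi = high + trans_hi / 2.0
    if cut_lo <= 0 or cut_hi >= nyq or trans_lo >= (high - low):
        need, _ = signal.kaiserord(attenuation_db, want_lo / nyq)
        raise FilterDesignError(
            f"{n_taps} taps cannot realize the {low}-{high} Hz passband at "
            f"fs={sample_rate}; try n_taps >= {need + 1 - need % 2}"
        )
    taps = signal.firwin(
        n_taps, [cut_lo, cut_hi], window=("kaiser", beta), pass_zero=False, fs=sample_rate
    )
    return FilterKernel(taps=taps, passband=(low, high), sample_rate=sample_rate)


def filter_epochs(epochs: EpochMatrix, kernel: FilterKernel) -> EpochMatrix:
    """Band-limit every epoch and correct for the filter group delay.

    Convolution uses a centered (same-length) kernel so a symmetric FIR
    introduces no net delay; the half-kernel of samples at each end is
    recorded as invalid in ``edge_invalid``.
    """
    if kernel.sample_rate != epochs.sample_rate:
        raise ValidationError(
            f"sample_rate mismatch: kernel {kernel.sample_rate} Hz vs epochs {epochs.sample_rate} Hz"
        )
    filtered = signal.oaconvolve(epochs.data, kernel.taps[None, :], mode="same", axes=1)
    edge = max(epochs.edge_invalid, kernel.group_delay)
    return epochs.copy_with(data=filtered, edge_invalid=edge)


@dataclass(frozen=True)
class WeightMask:
    """Binary per-sample weights (0 = artifact) with per-epoch flags."""

    weights: np.ndarray
    epoch_flags: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isin(w, (0.0, 1.0)).all():
            raise ValidationError("weights must be binary 0/1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "epoch_flags", np.asarray(self.epoch_flags, dtype=bool))


@dataclass(frozen=True)
class ArtifactReport:
    """Flagged sample positions and the detector state that produced them."""

    positions: np.ndarray  # (k, 2) array of (epoch, sample)
    threshold: float
    epoch_counts: np.ndarray  # flagged samples per epoch

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValidationError(f"detector threshold must be finite, got {self.threshold}")


def detect_artifacts_quartile(
    epochs: EpochMatrix,
    fence: float = DEFAULT_FENCE,
    epoch_flag_fraction: float = EPOCH_FLAG_FRACTION,
) -> tuple[WeightMask, ArtifactReport]:
    """Flag high-amplitude samples with a pooled Tukey fence.

    Each sample's absolute deviation from the pointwise ensemble median
    waveform is pooled across all epochs; samples whose deviation exceeds
    ``Q3 + fence * IQR`` are flagged (weight 0).  An epoch is flagged whole
    when more than ``epoch_flag_fraction`` of its samples are flagged.
    Flag decisions are scale-equivariant: scaling all voltages by a
    constant leaves the flag set unchanged.
    """
    if epochs.n_epochs < 4:
        raise ValidationError(
            f"artifact detection needs >= 4 epochs for meaningful quartiles, got {epochs.n_epochs}"
        )
    median_wave = np.median(epochs.data, axis=0)
    dev = np.abs(epochs.data - median_wave[None, :])
    q1, q3 = np.percentile(dev, [25.0, 75.0])
    thresh = q3 + fence * (q3 - q1)
    flagged = dev > thresh
    weights = np.where(flagged, 0.0, 1.0)
    counts = flagged.sum(axis=1)
    epoch_flags = counts > epoch_flag_fraction * epochs.n_samples
    rows, cols = np.nonzero(flagged)
    report = ArtifactReport(
        positions=np.column_stack([rows, cols]),
        threshold=float(thresh),
        epoch_counts=counts,
    )
    return WeightMask(weights=weights, epoch_flags=epoch_flags), report
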