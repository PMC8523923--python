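"""Synthetic round-window electrophysiology generator.

Produces epoch-resolved electrode recordings, CAP epochs, OAE microphone
frames, and cohort-level amplitude-vs-level series carrying the statistical
structure the analysis pipeline assumes:

* a cochlear microphonic (CM) at the stimulus frequency whose sign follows
  stimulus polarity,
* a phase-locked neural component at twice the stimulus frequency that does
  not invert with polarity (so it survives polarity averaging),
* i.i.d. Gaussian background noise,
* sparse high-amplitude transient artifacts with recorded ground truth,
* cohort growth shapes: compressive growth in control ears versus
  threshold-shifted, steeper ("recruiting") growth in impaired ears that
  converges to the control amplitude at high level.

The neural component is modelled directly as a 2f sinusoid gated by the
stimulus envelope rather than via a spiking model: the downstream analysis
consumes only the second-harmonic component, so this is the minimal faithful
forward model.  A half-wave-rectified mode is available for realism checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .anow import aggregate_response
from .core import EpochMatrix, ToneBurstSpec, ValidationError
from .recruit import LevelSeries

__all__ = [
    "ScenarioConfig",
    "control_scenario",
    "hydropic_scenario",
    "control_amplitude_fn",
    "hydropic_amplitude_fn",
    "gen_anow_epochs",
    "gen_cap_epochs",
    "inject_artifacts",
    "gen_growth_series",
    "simulate_cohort",
    "CohortEar",
    "CONTROL_THRESHOLD_DB",
    "CONTROL_SLOPE_DB_PER_DB",
    "CONVERGENCE_LEVEL_DB",
]

# --- cohort growth-shape constants (amplitudes in dB re 1 µV, peak) -------

#: Control-ear neural threshold (dB SPL); growth is compressive above it.
CONTROL_THRESHOLD_DB = 20.0
#: Compressive control growth rate above threshold (dB response per dB SPL).
CONTROL_SLOPE_DB_PER_DB = 0.33
#: Control-ear amplitude at threshold, dB re 1 µV.
CONTROL_AMP_AT_THRESHOLD_DB = -20.0
#: Level at which impaired growth converges back onto the control curve.
CONVERGENCE_LEVEL_DB = 80.0
#: Impaired ears emerge this far (dB) below the convergence-point amplitude.
EMERGENCE_DROP_DB = 40.0


def _control_amp_db(level: float) -> float:
    return CONTROL_AMP_AT_THRESHOLD_DB + CONTROL_SLOPE_DB_PER_DB * (
        level - CONTROL_THRESHOLD_DB
    )


def control_amplitude_fn(sensitivity_offset_db: float = 0.0) -> Callable[[float], float]:
    """Neural 2f amplitude (µV) vs level for a control ear.

    Zero below threshold, then compressive dB-linear growth
    (``CONTROL_SLOPE_DB_PER_DB`` dB/dB).  ``sensitivity_offset_db`` shifts the
    whole curve along the level axis (per-ear variability).
    """

    def amp(level: float) -> float:
        eff = level - sensitivity_offset_db
        if eff < CONTROL_THRESHOLD_DB:
            return 0.0
        return 10.0 ** (_control_amp_db(eff) / 20.0)

    return amp


def hydropic_amplitude_fn(
    threshold_shift: float, sensitivity_offset_db: float = 0.0
) -> Callable[[float], float]:
    """Neural 2f amplitude (µV) vs level for a threshold-shifted ear.

    The curve is gated at ``CONTROL_THRESHOLD_DB + threshold_shift`` and
    rises dB-linearly to meet the control curve exactly at
    ``CONVERGENCE_LEVEL_DB`` (elevated threshold, steeper-than-normal growth,
    normal high-level response).  The growth rate is coupled to the shift:

        slope = EMERGENCE_DROP_DB / (CONVERGENCE - CONTROL_THRESHOLD - shift)

    so the default +20 dB shift yields 1.0 dB/dB against the control's
    0.33 dB/dB.
    """
    if threshold_shift < 0:
        raise ValidationError(f"threshold_shift must be >= 0, got {threshold_shift}")
    span = CONVERGENCE_LEVEL_DB - CONTROL_THRESHOLD_DB - threshold_shift
    if span <= 0:
        raise ValidationError(
            f"threshold_shift must leave room below the convergence level, got {threshold_shift}"
        )
    slope = EMERGENCE_DROP_DB / span
    amp_at_convergence = _control_amp_db(CONVERGENCE_LEVEL_DB)
    threshold = CONTROL_THRESHOLD_DB + threshold_shift

    def amp(level: float) -> float:
        eff = level - sensitivity_offset_db
        if eff < threshold:
            return 0.0
        if eff >= CONVERGENCE_LEVEL_DB:
            return 10.0 ** (_control_amp_db(eff) / 20.0)
        return 10.0 ** ((amp_at_convergence - slope * (CONVERGENCE_LEVEL_DB - eff)) / 20.0)

    return amp


def _default_cap_amplitude(level: float) -> float:
    """Default N1 amplitude (µV): linear growth above the control threshold."""
    if level < CONTROL_THRESHOLD_DB:
        return 0.0
    return min(0.25 * (level - CONTROL_THRESHOLD_DB), 15.0)


def _default_cap_latency(level: float) -> float:
    """Default N1 latency (ms): shortens with level, floored at 1.5 ms."""
    return max(4.0 - 0.025 * max(level - CONTROL_THRESHOLD_DB, 0.0), 1.5)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic recording scenario.

    ``neural_amplitude_fn`` maps level (dB SPL) to the 2f neural amplitude
    in µV; ``cap_n1_amplitude_fn``/``cap_n1_latency_fn`` give the CAP N1
    amplitude (µV) and latency (ms).  ``artifact_scale`` is a multiple of
    ``noise_sigma``.  Generation is bit-reproducible given ``seed``.
    """

    cm_amplitude: float = 10.0
    neural_amplitude_fn: Callable[[float], float] = field(
        default_factory=control_amplitude_fn
    )
    cap_n1_amplitude_fn: Callable[[float], float] = _default_cap_amplitude
    cap_n1_latency_fn: Callable[[float], float] = _default_cap_latency
    noise_sigma: float = 3.0
    artifact_rate: float = 0.0
    artifact_scale: float = 50.0
    threshold_shift: float = 0.0
    seed: int = 0
    rectified_neural: bool = False

    def __post_init__(self) -> None:
        if self.cm_amplitude < 0:
            raise ValidationError(f"cm_amplitude must be >= 0, got {self.cm_amplitude}")
        if self.noise_sigma < 0:
            raise ValidationError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.artifact_rate < 0.2:
            raise ValidationError(
                f"artifact_rate must lie in [0, 0.2), got {self.artifact_rate}"
            )
        if self.artifact_scale < 0:
            raise ValidationError(f"artifact_scale must be >= 0, got {self.artifact_scale}")


def control_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """Control-ear scenario: compressive growth, no threshold shift."""
    kwargs = dict(
        neural_amplitude_fn=control_amplitude_fn(),
        threshold_shift=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def hydropic_scenario(threshold_shift: float = 20.0, seed: int = 0, **overrides) -> ScenarioConfig:
    """Impaired-ear scenario: threshold shift with recruiting growth."""
    kwargs = dict(
        neural_amplitude_fn=hydropic_amplitude_fn(threshold_shift),
        threshold_shift=threshold_shift,
        seed=seed,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def _envelope(spec: ToneBurstSpec, n_samples: int) -> np.ndarray:
    """Raised-cosine gated stimulus envelope over the epoch."""
    env = np.zeros(n_samples)
    n_burst = min(spec.n_samples, n_samples)
    env[:n_burst] = 1.0
    n_ramp = spec.rise_fall_samples
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[n_burst - n_ramp : n_burst] = ramp[::-1]
    return env


def gen_anow_epochs(spec: ToneBurstSpec, scenario: ScenarioConfig) -> EpochMatrix:
    """Generate alternating-polarity epochs for ANOW analysis.

    Each epoch is CM (sign follows polarity) + neural 2f component (sign
    polarity-invariant, phase-locked to onset) + Gaussian noise, plus
    injected artifacts when ``scenario.artifact_rate > 0``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate
    env = _envelope(spec, n)
    cm = scenario.cm_amplitude * np.sin(2 * np.pi * spec.frequency * t) * env
    amp = scenario.neural_amplitude_fn(spec.level)
    if scenario.rectified_neural:
        # Half-wave-rectified CM surrogate: keeps strong even harmonics.
        raw = np.maximum(np.sin(2 * np.pi * spec.frequency * t), 0.0)
        raw -= raw.mean()
        neural = amp * raw / max(np.abs(raw).max(), 1e-30) * env
    else:
        neural = amp * np.cos(2 * np.pi * 2 * spec.frequency * t) * env
    pol = spec.polarity_start * (-1) ** np.arange(spec.n_repetitions)
    data = pol[:, None] * cm[None, :] + neural[None, :]
    if scenario.noise_sigma > 0:
        data = data + rng.normal(0.0, scenario.noise_sigma, size=data.shape)
    epochs = EpochMatrix(
        data=data, sample_rate=spec.sample_rate, polarity=pol, stimulus=spec, onset_sample=0
    )
    if scenario.artifact_rate > 0:
        epochs, _ = inject_artifacts(
            epochs,
            rate=scenario.artifact_rate,
            scale=scenario.artifact_scale,
            sigma=scenario.noise_sigma,
            seed=scenario.seed + 1,
        )
    return epochs


def gen_cap_epochs(
    spec: ToneBurstSpec, scenario: ScenarioConfig, silence_ms: float | None = None
) -> EpochMatrix:
    """Generate alternating-polarity CAP epochs.

    Each epoch holds a stereotyped compound action potential — a negative
    lobe (N1) at ``cap_n1_latency_fn(level)`` followed by a positive lobe
    (P1) — that does not invert with polarity, a CM tone that does, noise,
    and an appended silence interval (default equal to the burst duration,
    mirroring the interleaved-silence presentation; the inter-pair interval
    is a free parameter).
    """
    rng = np.random.default_rng(scenario.seed)
    if silence_ms is None:
        silence_ms = spec.duration
    n = int(round((spec.duration + silence_ms) * 1e-3 * spec.sample_rate))
    t_ms = np.arange(n) / spec.sample_rate * 1e3
    env = _envelope(spec, n)
    t = np.arange(n) / spec.sample_rate
    cm = scenario.cm_amplitude * np.sin(2 * np.pi * spec.frequency * t) * env

    a = scenario.cap_n1_amplitude_fn(spec.level)
    cap = np.zeros(n)
    if a > 0:
        tau = scenario.cap_n1_latency_fn(spec.level)
        cap = -a * _gauss(t_ms, tau, 0.35) + 0.7 * a * _gauss(t_ms, tau + 1.2, 0.5)
    pol = spec.polarity_start * (-1) ** np.arange(spec.n_repetitions)
    data = pol[:, None] * cm[None, :] + cap[None, :]
    if scenario.noise_sigma > 0:
        data = data + rng.normal(0.0, scenario.noise_sigma, size=data.shape)
    epochs = EpochMatrix(
        data=data, sample_rate=spec.sample_rate, polarity=pol, stimulus=spec, onset_sample=0
    )
    if scenario.artifact_rate > 0:
        epochs, _ = inject_artifacts(
            epochs,
            rate=scenario.artifact_rate,
            scale=scenario.artifact_scale,
            sigma=scenario.noise_sigma,
            seed=scenario.seed + 1,
        )
    return epochs


def _gauss(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def inject_artifacts(
    epochs: EpochMatrix, rate: float, scale: float, sigma: float, seed: int
) -> tuple[EpochMatrix, np.ndarray]:
    """Displace a random sample subset by ±scale·sigma; return ground truth.

    Exactly ``floor(rate * data.size)`` distinct samples are displaced.
    Returns the corrupted matrix and an ``(k, 2)`` integer array of
    (epoch, sample) positions for detector validation.
    """
    if not 0 <= rate < 0.2:
        raise ValidationError(f"artifact_rate must lie in [0, 0.2), got {rate}")
    k = int(rate * epochs.data.size)
    if k == 0:
        return epochs.copy_with(data=epochs.data.copy()), np.empty((0, 2), dtype=int)
    rng = np.random.default_rng(seed)
    flat = rng.choice(epochs.data.size, size=k, replace=False)
    signs = rng.choice([-1.0, 1.0], size=k)
    data = epochs.data.copy()
    rows, cols = np.unravel_index(flat, epochs.data.shape)
    data[rows, cols] += signs * scale * sigma
    locs = np.column_stack([rows, cols])
    order = np.lexsort((cols, rows))
    return epochs.copy_with(data=data), locs[order]


# --- cohort-level generation ----------------------------------------------

#: Steady-state sample count backing the coefficient-noise model
#: (33.3 ms at 96 kHz).
DEFAULT_N_SAMPLES = 3200
DEFAULT_N_PAIRS = 46


def gen_growth_series(
    scenario: ScenarioConfig,
    levels: Sequence[float],
    frequency: float = 480.0,
    label: str | None = None,
    n_pairs: int = DEFAULT_N_PAIRS,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> LevelSeries:
    """Simulate a per-level ANOW magnitude series at the coefficient level.

    For each level the per-pair complex 2f coefficient is the injected
    amplitude plus complex Gaussian estimation noise whose per-axis scale,
    ``noise_sigma * sqrt(2 / n_samples)``, matches what the least-squares
    sinusoid fit would see on ``n_samples`` of raw noise.  Coefficients are
    aggregated exactly as the epoch-level pipeline aggregates them (complex
    mean + SEM noise floor), so noise floors inherit the 1/sqrt(n_pairs)
    scaling of the full analysis.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 1 or np.any(np.diff(levels) <= 0):
        raise ValidationError("levels must be a strictly ascending 1-D sequence")
    rng = np.random.default_rng(scenario.seed)
    sigma_c = scenario.noise_sigma * math.sqrt(2.0 / n_samples)
    resp_db = np.empty(levels.size)
    floor_db = np.empty(levels.size)
    for i, level in enumerate(levels):
        amp = scenario.neural_amplitude_fn(float(level))
        coeffs = np.full(n_pairs, amp, dtype=complex)
        if sigma_c > 0:
            coeffs = coeffs + sigma_c * (
                rng.standard_normal(n_pairs) + 1j * rng.standard_normal(n_pairs)
            )
        resp = aggregate_response(coeffs, analysis_frequency=2 * frequency)
        resp_db[i] = resp.rms_db()
        floor_db[i] = resp.noise_floor_rms_db()
    series = LevelSeries(
        frequency=frequency,
        label=label or f"{frequency:g} Hz",
        levels=levels,
        response=resp_db,
        noise_floor=floor_db,
        measure_kind="anow_magnitude",
    )
    return series.with_snr()


@dataclass(frozen=True)
class CohortEar:
    """One simulated ear: its series per frequency plus ground truth."""

    ear_id: str
    group: str  # "control" or "hydropic"
    threshold_shift: float
    sensitivity_offset_db: float
    series: dict  # frequency label -> LevelSeries


def simulate_cohort(
    n_hydropic: int = 18,
    n_control: int = 8,
    seed: int = 0,
    levels: Sequence[float] | None = None,
    low_freqs: Sequence[float] = (300.0, 480.0, 720.0, 1020.0),
    high_freqs: Sequence[float] = (8000.0, 12000.0),
    shift_range: tuple[float, float] = (10.0, 30.0),
    sensitivity_jitter_db: float = 4.0,
    noise_sigma: float = 3.0,
) -> list[CohortEar]:
    """Simulate a study cohort of control and threshold-shifted ears.

    Hydropic ears draw a low-frequency threshold shift uniformly from
    ``shift_range``; the generator couples the shift to steeper growth
    converging on the control curve at 80 dB SPL.  At the high frequencies
    no shift is applied (both groups use the control shape), reproducing
    the low-frequency/high-frequency dissociation.  Every ear additionally
    draws a small overall sensitivity offset so that measured thresholds
    vary within groups.
    """
    if levels is None:
        levels = np.arange(10.0, 81.0, 5.0)
    rng = np.random.default_rng(seed)
    ears: list[CohortEar] = []
    for i in range(n_hydropic + n_control):
        group = "hydropic" if i < n_hydropic else "control"
        offset = float(rng.uniform(-sensitivity_jitter_db, sensitivity_jitter_db))
        shift = float(rng.uniform(*shift_range)) if group == "hydropic" else 0.0
        series: dict = {}
        for freq in list(low_freqs) + list(high_freqs):
            shifted = group == "hydropic" and freq <= 1020.0
            fn = (
                hydropic_amplitude_fn(shift, sensitivity_offset_db=offset)
                if shifted
                else control_amplitude_fn(sensitivity_offset_db=offset)
            )
            sc = ScenarioConfig(
                neural_amplitude_fn=fn,
                noise_sigma=noise_sigma,
                threshold_shift=shift if shifted else 0.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            series[f"{freq:g}"] = gen_growth_series(sc, levels, frequency=freq)
        ears.append(
            CohortEar(
                ear_id=f"{group[:3]}{i:02d}",
                group=group,
                threshold_shift=shift,
                sensitivity_offset_db=offset,
                series=series,
            )
        )
    return ears
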