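# Methods

This note documents the models, numerical choices and limitations behind
`recruitpipe`, in the spirit of a package methods appendix.  Units
throughout: electrode voltages in input-referred µV (amplifier gain and the
hardware analog filter are treated as already removed), pressures in Pa
(dB SPL re 20 µPa), levels in dB SPL, latencies in ms re stimulus onset,
sample indices 0-based, default sampling rate 96 kHz.

## Signal model and ANOW estimation

An epoch is modelled as

    x_k(t) = s_k · CM(t) + N(t) + ε_k(t),    s_k = ±1 alternating,

where CM follows the stimulus at frequency f and inverts with polarity,
the neural component N is phase-locked to stimulus onset and concentrated
at 2f (neural excitation rides one phase of a low-frequency tone, so the
polarity-averaged response contains predominantly even harmonics), and ε is
i.i.d. Gaussian.  Averaging consecutive +/− pairs cancels CM exactly for
exact pairing; this is enforced structurally (epochs must alternate
strictly, odd counts are rejected).

The 2f component of each overlapped waveform is estimated by weighted
least squares on the two-column design [cos(2π·2f·t), −sin(2π·2f·t)] over
the steady-state analysis window (onset/offset ramps and any
filter-invalidated edges are zero-weighted).  With uniform weights and an
integer number of cycles this estimator equals 2/N times the DFT bin, but
unlike an FFT it accepts arbitrary binary weights without edge splatter,
which is how artifact samples are excised.  A fit requires at least 10
weighted cycles of 2f.

Per-measurement aggregation: signal = complex mean of the per-pair
coefficients; noise floor = √(SEM_real² + SEM_imag²).  The SEM of the
*magnitudes* is deliberately not used — it is biased upward at low SNR
because magnitude is a folded quantity.  Reported dB values use the RMS
convention (amplitude/√2) re 1 µV; a vanishing floor is clamped at
−40 dB re 1 µV RMS for reporting.  OAE components reuse the identical
estimator and aggregation in Pa, reported as 20·log10(amplitude/20 µPa).

Phase is atan2(imag, real) in (−π, π], with time origin at stimulus onset.
Phase delays for level series are −unwrapped phase/(2π·2f), unwrapping from
the highest level downward (best SNR anchors the branch).

## Conditioning: FIR kernels and artifact flagging

Band-limiting uses symmetric (linear-phase) Kaiser-window FIR kernels —
600–1,600 Hz for the ANOW path, 150–1,500 Hz for the CAP path — applied
with centered convolution so the integer group delay (n_taps−1)/2 is
corrected exactly; the half-kernel at each end is recorded as invalid.
With an unspecified tap count the kernel is sized to hold the passband
within ±1 dB and provide ≥ 40 dB (design target 45 dB) at low/2 and at
min(2·high, 0.9·Nyquist); with an explicit tap count the transition bands
widen to what the length affords, preserving passband flatness first
(the 150 Hz edge needs ≈ 4,100 taps at 96 kHz for the full stopband
contract; 1,025 taps keep the passband flat but relax the low-side stop).

Artifacts are flagged by a pooled Tukey fence: per-sample absolute
deviation from the pointwise ensemble median waveform, pooled over all
epochs; samples with deviation > Q3 + 3·IQR are flagged (fence
configurable).  The detector is scale-equivariant and needs ≥ 4 epochs.
An epoch is flagged whole when > 10% of its samples are flagged (a decided
constant).  Flag handling differs by path, mirroring the two measurement
styles: the ANOW fit keeps flagged samples at weight 0; the CAP average
drops any epoch containing a flagged sample, together with its polarity
partner so the retained set still cancels CM.  With fence 3 the Gaussian
false-flag tail (~2.7·10⁻⁴ per sample) discards a substantial fraction of
clean CAP pairs; this only reduces the effective repetition count and the
fence can be raised where that matters.

**Ordering decision.**  `analyze_anow` runs artifact detection and the 2f
fit on the epochs *as given*, band-limiting only on request (`prefilter`).
A 1,025-tap kernel spreads a one-sample transient over ~1 ms, after which
binary sample weights can no longer excise its energy — masking then
provides no benefit over not masking, defeating the stated purpose of the
weights.  The single-frequency least-squares fit is itself narrowband, so
omitting the bandpass changes the estimate only by the kernel's gain at 2f
(≈ 1 in the passband).  Detection before smearing restores the intended
behaviour: under 1% single-sample corruption at 50× the noise σ, the
masked estimate tracks the clean run to ~0.01 dB while the unmasked
estimate errs by ~0.5 dB.

## CAP peak picking

N1 is the most negative local extremum in a configurable window (default
0.5–6.0 ms post onset, guinea-pig-appropriate); P1 is the most positive
local extremum within 5 ms after N1.  Ties take the earliest latency.
Three-point parabolic interpolation refines both latency and amplitude
below sample resolution.  A flat or extremum-free window returns a
distinct "no response" value rather than an error; a pick with |N1| below
3× the pre-onset RMS is flagged low-quality.  Peak-to-peak (P1 − N1) is the
amplitude measure fed to growth analysis; peak delay is the N1 latency.

## Growth fits and the recruitment slope

A level series is fit with a weighted natural cubic smoothing spline
minimizing

    p · Σᵢ wᵢ (yᵢ − g(Lᵢ))²  +  (1 − p) · ∫ g″(L)² dL,

p = 0.005 by default.  **Convention warning:** p → 1 interpolates and
p → 0 tends to the weighted straight line here; some other spline
packages attach the roughness weight to p instead, inverting the meaning.
Weights are the per-level SNR in dB floored at zero (negative SNRs would
otherwise be negative weights), and exactly zero below the 6 dB criterion;
zero-weight points are excluded from the objective, making them provably
inert.  At least 4 weighted levels are required.  The solver forms the
Reinsch/Green–Silverman normal equations (W + λ·Q R⁻¹ Qᵀ)g = W y with
λ = (1−p)/p and densifies via the natural cubic interpolant of the fitted
knot values — the exact minimizer.  The fit and its analytic derivative
are evaluated on the 1-dB grid over the tested range; beyond the outermost
weighted level the natural spline is continued linearly (its curvature
vanishes there).  The test suite checks the solver against scipy's
independent `make_smoothing_spline` on the same objective.

Threshold is the lowest tested level whose SNR meets the criterion at that
level *and the next tested level* (run-of-2; an operationalization chosen
to reject one-level noise excursions).  "No threshold" is a value, not an
error, and propagates as absence: no threshold ⇒ no slope ⇒ no regression
point.  The recruitment slope is the median of the spline derivative over
grid points at and above threshold (midpoint convention for even counts);
units are dB/dB for ANOW series (dB response vs dB SPL) and µV/dB for CAP
peak-to-peak — cross-kind comparisons are made by frequency only, never by
mixing units.  Slope-vs-threshold relations use ordinary least squares
with two-sided t-tests (n−2 df) and t-based 95% CIs.  Low-frequency
aggregation takes unweighted means over frequencies ≤ 1,020 Hz (the series
labelled "1 kHz" has actual frequency 1,020 Hz), with threshold shift
referenced to the caller-supplied control-cohort mean.

## Synthetic generator

`synthgen` emulates exactly the structure the analysis assumes: a
polarity-following CM sinusoid, a polarity-invariant 2f neural sinusoid
gated by the raised-cosine stimulus envelope (a spiking model is
unnecessary because the analysis consumes only the 2f line; a half-wave
rectified mode exists for realism checks), Gaussian noise, and
single-sample transients of ±scale·σ at recorded ground-truth positions.
CAP epochs carry a stereotyped biphasic wave (negative Gaussian lobe at
the level-dependent latency, 0.7-amplitude positive lobe 1.2 ms later;
the two lobes have equal area so the complex has no DC component) plus an
appended silence interval, default equal to the burst duration — the
inter-pair interval is left a free parameter because the nominal
repetition-rate arithmetic does not pin it down.

Cohort growth shapes (amplitudes in dB re 1 µV):

* **Control:** zero below 20 dB SPL, then compressive growth at
  0.33 dB/dB from −20 dB re 1 µV, reaching ≈ 0.98 µV at 80 dB SPL.
* **Impaired ("hydropic"):** gated at (20 + shift) dB SPL, rising
  dB-linearly to meet the control curve exactly at 80 dB SPL with slope
  40/(60 − shift) dB/dB — the default +20 dB shift gives 1.0 dB/dB.
  Larger shifts are thus intrinsically coupled to steeper growth, the
  recruitment phenotype: elevated threshold, faster-than-normal growth,
  normal high-level response.

Defaults mirror the measurement protocol: 92 repetitions (46 pairs) of
33.3 ms bursts for ANOW at 300/480/720/1,020 Hz (labelled 300/500/700/
1,000 Hz; computation uses actual frequencies), 128 repetitions of 13.9 ms
bursts for CAP, levels 10–80 dB SPL in 5 dB steps, CM 10 µV, noise σ
3 µV (which puts the 46-pair noise floor near −42 dB re 1 µV RMS, giving
control ears a detected threshold of ~20 dB SPL).  Cohorts default to 18
impaired + 8 control ears; each ear draws a ±4 dB overall sensitivity
offset and impaired ears draw their shift uniformly from 10–30 dB.
`gen_growth_series` simulates at the coefficient level (injected amplitude
plus complex Gaussian estimation noise of per-axis scale σ·√(2/N),
aggregated by the same code as the epoch-level chain), which preserves the
noise-floor statistics of the full pipeline at a fraction of the cost.

What the generator does **not** emulate: cochlear mechanics (no traveling
wave, compression is imposed on the amplitude function, not emergent),
realistic CAP morphology changes with level, correlated or non-Gaussian
physiological noise, line interference, middle-ear acoustics, or drifting
electrode impedance.  Passing tests therefore demonstrate correctness of
the *analysis* under its stated assumptions, not robustness to every
failure mode of real recordings.

## Numerical choices and degenerate inputs

* Validation errors name the offending field; structural invariants
  (alternating polarity, even counts, ascending levels, binary weights)
  are enforced at construction.
* Quartiles via linear-interpolation percentiles; detector threshold is a
  single pooled fence, so flags are exactly scale-equivariant.
* Identical coefficients give SEM 0; dB conversion clamps at −40 dB.
* Peak picking on ties takes the earliest extremum; plateaus count their
  leading edge; windows not spanned by the waveform are errors, empty
  windows are "no response".
* Degenerate regressions (all-equal thresholds, n < 3) raise; cohort
  drivers treat a degenerate per-frequency regression as absent rather
  than fabricating a result.
* All generation and analysis is bit-reproducible given seeds; archives
  and results tables are byte-stable for identical config + input, and
  every output names the config hash that produced it.

## Problem sizes used in validation

The simulation-based tests and the acceptance script use 200 seeded
repetitions for stochastic properties (artifact robustness, noise-floor
scaling, spline recovery, cohort contrast, CAP accuracy), 50 random cases
for estimator/DFT equivalence, and 1,000 replicates for the regression
null-calibration KS check; cohort simulations use the coefficient-level
generator at the study's 26-ear, 4+2-frequency, 15-level geometry.  These
sizes give Monte-Carlo error comfortably below every asserted margin.
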