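# recruitpipe

Analysis pipeline for quantifying **response recruitment** — abnormally
rapid growth of auditory-nerve response amplitude with sound level, such
that an ear with elevated thresholds reaches normal response amplitudes at
high levels — from round-window electrophysiology in small-animal models of
low-frequency hearing loss (endolymphatic hydrops, outer-hair-cell
dysfunction).  It is written for auditory neuroscientists who record
epoch-resolved evoked potentials and want a tested, scriptable
implementation of the full measurement chain.

## What it computes

**ANOW (Auditory Nerve Overlapped Waveform).**  Low-frequency tone bursts
are presented in alternating polarity.  The cochlear microphonic (CM)
follows the stimulus and inverts with polarity; phase-locked neural firing
does not.  Averaging each +/− epoch pair cancels the CM, and the neural
response concentrates at twice the stimulus frequency.  Each overlapped
waveform is fit by weighted least squares,

    y(t) ≈ a·cos(2π·2f·t) + b·(−sin(2π·2f·t)),

with binary per-sample weights (0 at samples flagged by a quartile/Tukey
artifact detector, 1 elsewhere).  The complex mean of the per-pair
coefficients (a, b) is the signal; the standard error of that mean,
√(SEM_a² + SEM_b²), is the noise floor.  Magnitude = √(a²+b²), phase =
atan2(b, a).

**CAP (compound action potential).**  Alternating-polarity epochs are
band-limited (150–1,500 Hz linear-phase FIR, group-delay corrected),
artifact-bearing epochs are dropped with their polarity partners, and an
automated picker locates the N1 trough and following P1 peak with
parabolic sub-sample refinement.

**OAEs.**  Stimulus-frequency emissions via the double-evoked residual
(probe + suppressor − both, which cancels anything linear in the stimuli)
and distortion products at 2f1−f2 (f2/f1 = 1.22), extracted with the same
least-squares estimator and SEM noise-floor convention, in dB SPL.

**Recruitment metric.**  Per frequency and ear, response vs level is fit
with a weighted cubic smoothing spline (coefficient p = 0.005 in the
p·misfit + (1−p)·roughness convention; weights = SNR in dB, zeroed below
the 6 dB criterion), interpolated at 1-dB spacing and differentiated; the
**median derivative at and above threshold** (threshold = lowest level with
SNR ≥ 6 dB at that level and the next) is the slope metric.  Cohort-level
statistics regress this slope on threshold (OLS with t-based p-values and
95% CIs) per frequency, and aggregate slopes and threshold shifts across
low frequencies (≤ 1 kHz).

A seeded synthetic generator (`recruitpipe.synthgen`) produces epochs,
CAP trains, OAE frames and whole cohorts with the statistical structure
the pipeline assumes (CM, 2f neural component, Gaussian noise, sparse
transients with ground truth, compressive control vs threshold-shifted
recruiting growth), so every stage is testable without animal data.

## Worked example

Simulate one control-ear recording (480 Hz tone burst, 70 dB SPL, 92
alternating-polarity repetitions at 96 kHz) and extract the ANOW response:

```
$ recruitpipe simulate --seed 1 --level 70 --out demo_arc
$ recruitpipe anow demo_arc
{
  "analysis_frequency_hz": 960.0,
  "magnitude_uv": 0.6784575998407474,
  "rms_db_re_1uv": -6.379845723816189,
  "phase_rad": -0.0070218260641837105,
  "noise_floor_rms_db": -40.0,
  "n_pairs": 46,
  "config_hash": "2cf39325ec93"
}
```

The 46 overlapped pairs yield a second-harmonic (960 Hz) component of
0.68 µV — the generator injected 0.67 µV at this level — about 34 dB above
the SEM noise floor (clamped at −40 dB re 1 µV RMS).

Run the full cohort pipeline (18 threshold-shifted ears, 8 controls) and
inspect the per-frequency slope-vs-threshold regressions:

```
$ recruitpipe all --seed 1 --out demo_out
$ head -3 demo_out/regressions.csv
# config_hash: 9539ed690256
name,slope,intercept,r_squared,p_value,ci_low,ci_high,n
slope_vs_threshold_300,0.0252348958,-0.2937283057,0.6885913566,2.04362831e-05,0.01624111015,0.03422868145,18
```

At 300 Hz, ears with higher thresholds grow steeper (0.025 dB/dB of
recruitment slope per dB of threshold, R² = 0.69, p = 2e−5 across 18
ears) — the recruitment signature.  The same tables report each ear's
level series and median slopes; at the high frequencies, where the
generator applies no threshold shift, the regressions are null.

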