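# Methods

This note records the models, numerical choices and limitations behind each
stage of the pipeline, in the order data flows through it.

## Signal ingest and artifact handling

ECG and finger-pressure waveforms are expected at 200 Hz (any rate ≥ 100 Hz
is accepted).  R peaks are found by a band-pass (5–25 Hz, zero-phase) energy
envelope with a 250-ms refractory period and an adaptive threshold at 15 %
of the median candidate height; each candidate is then refined to the local
maximum of the raw signal within ±100 ms, so reported beat times coincide
with R-wave maxima to within one sample.  The detector is deliberately
simple: the contract (≥ 99.5 % sensitivity, zero false positives at ≥ 20 dB
SNR on synthetic records, ±1 sample timing) is normative, not the algorithm.

Manual expert beat editing is replaced by a declared `CleaningPolicy`:
intervals outside 300–2000 ms or deviating from the 11-beat local median by
more than 25 % are *deviant*.  A beat flanked by two deviant intervals (the
short-then-compensatory ectopic signature) is labelled premature or
artifact; an isolated deviant interval (e.g. a missed beat) is excluded
without condemning its endpoint beats.  Both neighbouring intervals of a
labelled beat leave the normal-to-normal (N-N) series.  The rule is a
deterministic function of the beat times, hence idempotent, and never
overwrites labels already present.  Recordings with more than 20 % invalid
intervals are rejected outright, mirroring an expert's discretion to discard
a session.  Default replacement mode is drop-with-gap; an interpolate mode
re-estimates removed beat values from neighbours, which for the linear
resampler yields the identical uniform series and only matters for
beat-domain consumers such as DFA.

Beat-wise pressures: SBP_i is the maximum of the pressure wave in
(t_i, t_i + 0.6·NN] — the systolic peak trails the R wave by the
pulse-transit delay — and DBP_i the minimum preceding that maximum in the
same window.  Flat (non-pulsatile) windows flag the beat rather than
producing values.  QRS amplitude is the R-peak value minus the median of a
140–60 ms pre-QRS segment; the short lever arm keeps slow baseline drift
(0.5 mV at 0.05 Hz) below a 2 % amplitude error while staying clear of the
P wave.

## Frequency-domain indices

Beat-indexed series (N-N ms, DBP mmHg, QRS amplitude mV) are linearly
interpolated onto a 10-Hz grid and decimated to 5 Hz by taking every second
sample, with no anti-alias filter — tachogram content above 2.5 Hz is
physiologically absent, and this mirrors the interpolate-then-resample
description the procedure follows.  The Welch periodogram uses 240-s Hann
windows with 90 % overlap (24-s hop; a 600-s series yields 16 windows and a
1/240 ≈ 0.00417 Hz grid, ≥ 8 lines inside the VLF band) and per-window
linear detrending (switchable to mean removal); one-sided densities are
normalised so the integral equals the variance of the detrended series.

The broadband smoother replaces each line by a centred moving average whose
odd order rises linearly with frequency from 3 at 0.005 Hz to 11 at
0.40 Hz (rounded to the nearest odd integer, symmetric shrinking windows at
the grid edges).  The schedule is the package's own interpretation of an
"order increasing from 3 to 11 with frequency" smoother; it preserves
non-negativity and total power to within ~2 %.  Band powers are trapezoidal
integrals with interpolated band edges over VLF 0.005–0.04, LF 0.04–0.15 and
HF 0.15–0.40 Hz; LF is also computed for the DBP spectrum.  Log values use
base 10, consistent with resting HF powers of ~700 ms² ↔ log HF ≈ 2.85.

The EDR breathing rate is the power-weighted mean frequency (spectral
centroid) of the smoothed QRS-amplitude spectrum within 0.10–0.50 Hz;
the centroid is robust for broad respiratory peaks, and an argmax option is
provided.  A configurable analysis-start offset (default 0 s) can discard an
initial orthostatic transient after a posture change.

## DFA1

The short-term scaling exponent integrates the mean-removed N-N series,
tiles it into non-overlapping boxes of n beats for every n in 4..16
(trailing partial boxes discarded), removes a linear trend per box, pools
squared residuals into F(n), and takes the unweighted least-squares slope of
log F against log n.  The lower bound 4 is the smallest box for which linear
detrending is non-degenerate; 16 is the canonical upper bound of the
short-term exponent.  A caveat worth stating: over this finite box range the
estimator does not reach asymptotic exponents.  For uncorrelated input the
exact expectation E[F²(n)] = tr(MΣM)/n (Σ_ij = min(i, j), M the
linear-detrend projector) gives a log-log slope of 0.583, not 0.5; 1/f and
Brownian inputs sit essentially on their asymptotes (1.00, 1.50) at these
scales.  Empirical alpha1 values should therefore be compared against
like-range references, which is how the index is used in practice.

## Normalization and delta scores

Linear-scale indices (HR, SV, CO, TPR, SBP, DBP, DFA1, EDR) are expressed as
percent of the subject's supine pre-bed-rest baseline (baseline ≡ 100 %);
frequency-domain powers and LF/HF are log₁₀ differences from baseline
(baseline ≡ 0), since band powers need a log transform for normality and
LF/HF is itself reported on the log scale.  Delta scores are
Δ = value(R+10) − value(BDC−7) per subject, posture and index, so negative
values are declines from baseline (the convention that makes a post-bed-rest
supine SBP fall read −17 mmHg).  Missing baselines or incomplete
before/after pairs raise named errors; no rows are dropped silently.
The helper CO = HR·SV/1000, MAP = DBP + (SBP − DBP)/3, TPR = 80·MAP/CO
supports synthetic cohorts when no impedance-cardiography values exist.

## Mixed models and multiplicity

Both designs — normalized supine time courses (Time × Group, Time levels
HDT2/HDT28/HDT56/R+10; the baseline itself is the reference level
100 %/0) and postural-test delta scores (Posture × Group) — are Gaussian
linear mixed models with a subject random intercept, parametrised by cell
means so every contrast is a plain linear combination of coefficients.
With subjects as independent blocks the REML log-likelihood, its gradient
and the variance-component Fisher information all have closed forms
(Sherman–Morrison), which keeps a fit below a millisecond-scale cost and
makes the Satterthwaite machinery exact at the optimum:
ν(c) = 2(c′Ĉc)²/Var(c′Ĉc) with the analytic gradient of c′Ĉc against
(σ²_subject, σ²_resid) and the inverse REML information.  Multi-row Wald
tests combine per-eigencontrast ν values into a denominator df the way
lmerTest does.  A subject variance estimated at the REML boundary (expected
occasionally at n = 23) is reported as such, and contrasts fall back to the
ordinary least-squares model with classical residual df.

Follow-up contrasts are gatekept: per-group vs-baseline and between-group
contrasts run when the Group factor or the interaction is significant;
groups are pooled when only Time is significant; with no significant
omnibus term the contrasts are still computed but flagged `gated` and kept
out of the correction family.  The postural family comprises the four
non-zero tests (each group × posture delta vs 0), supine-vs-sitting within
group and CTRL-vs-TRAIN within posture.  Families are deliberately small —
one per outcome index per model, matching per-panel significance marking —
and corrected with the Hochberg step-up procedure
(adj_i = min_{j≥i} (m−j+1)p_(j), capped at 1).  Between-group contrasts
assume a single homoscedastic residual variance, the standard choice for
this model class.  Residual diagnostics are emitted as plots
(`diagnostics.residuals_vs_fitted`) for visual inspection only.

## Synthetic data

`generate_rr` is an integral pulse frequency modulation (IPFM) generator:
an instantaneous interval signal rr(t) = mean R-R + Σ modulations is
inverted to a rate and integrated on a 200-Hz grid, emitting a beat per
unit area.  IPFM was chosen over AR interval models because it produces
beat *times*, which the waveform synthesis and the interpolation step need.
Modulations are band-limited Gaussian processes (4th-order band-pass
magnitude shape, synthesised spectrally) or pure tones.  A component's
configured variance is defined as the *realized* N-N band variance as the
spectral chain measures it: the two deterministic attenuations of that
chain — interval averaging over one beat in the IPFM loop (amplitude
sinc(fT)) and the linear-interpolation resampler (amplitude sinc²(fT)) —
are pre-compensated per spectral line, and each realisation is scaled so
its in-band variance matches the configuration exactly.  Configurations
that drive the instantaneous rate to zero raise an infeasibility error.

ECG synthesis places Gaussian P-Q-R-S-T waves at the beat times with the R
amplitude multiplied by (1 + depth·sin(2π f_resp t)), default respiratory
rate 0.27 Hz so the HF modulation stays inside the HF band; additive
Gaussian noise is set by SNR relative to the clean signal power.  Pressure
synthesis draws one cosine-interpolated pulse per beat (diastolic trough
10 % and systolic peak 35 % into the beat) so window extraction recovers
the per-beat SBP/DBP targets within 1 mmHg.

The cohort generator emulates the study grid — 11 + 12 subjects, five
timepoints, supine throughout with sitting only at the pre/post postural
tests — as baseline mean (posture-specific, defaulting to the bundled
cohort summary's pre-bed-rest values) + subject intercept + configured
group×time×posture effect + residual noise, on the log₁₀ scale for
frequency-domain indices, with the printed between-subject SD split evenly
between intercept and residual (ICC 0.5).  The ground-truth effect table is
returned alongside for recovery tests.

What the generator does *not* emulate: baroreflex closed-loop coupling
between pressure and intervals, non-stationarity within a session,
measurement-device drift, or missing sessions.  Passing tests therefore
demonstrate correctness of the estimators and calibration of the inference
under the declared stochastic model, not robustness to every feature of
real recordings.

## Problem sizes and seeds

Simulation-based checks use 10-min (600-s) records, 20 seeds for spectral
recovery, 50 seeds × 600 beats for the DFA references, 2000 null and 500
effect cohorts for type-I error and coverage — sizes at which the
Monte-Carlo error of each check is comfortably below its tolerance.  All
generators take explicit seeds (package default 20151123) and identical
seeds give byte-identical outputs.
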