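# hdtcardio

Cardiovascular-autonomic analysis of long-duration head-down-tilt (HDT)
bed-rest studies — the ground analog of weightlessness in which healthy
volunteers lie at −6° for weeks while hemodynamics and autonomic cardiac
control decondition.

The package turns raw single-lead ECG and finger arterial-pressure waveforms
(200 Hz, ~10-min sessions), or pre-extracted beat tables, into the standard
autonomic index set and runs the study-design statistics on top:

1. **Ingest** (`beats`) — R-peak detection, rule-based artifact/ectopic
   labelling (replacing manual editing), beat-wise SBP/DBP and QRS-amplitude
   extraction; CSV and minimal WFDB-style readers.
2. **Spectra** (`spectral`) — tachogram/DBP series linearly interpolated at
   10 Hz and resampled at 5 Hz; Welch periodogram with 240-s Hann windows at
   90 % overlap; broadband smoothing whose moving-average order rises from 3
   to 11 with frequency; band powers VLF (0.005–0.04 Hz), LF (0.04–0.15 Hz),
   HF (0.15–0.40 Hz), the LF/HF sympathovagal-balance ratio, the DBP LF
   power, and the breathing rate as the spectral centroid of the ECG-derived
   respiration (EDR) signal.
3. **Fractal** (`fractal`) — short-term detrended fluctuation exponent DFA1
   over box sizes 4–16 beats.
4. **Normalization** (`normalize`) — supine time courses as percent of the
   pre-bed-rest baseline (linear indices) or log₁₀ difference from baseline
   (frequency-domain indices), and postural-test **delta scores**
   Δ = value(R+10) − value(BDC−7) per subject, group and posture.
5. **Inference** (`stat_models`, `mixedlm`) — two-factorial random-intercept
   linear mixed models fitted by REML; follow-up contrasts (including
   non-zero contrasts on delta scores) with Satterthwaite denominator
   degrees of freedom, gatekept behind Type-III omnibus tests; Hochberg
   step-up correction within small per-outcome families (α = 0.05,
   two-sided).
6. **Synthesis** (`synthetic`) — an IPFM beat generator with band-limited
   autonomic modulations, PQRST/pressure waveform synthesis, and a
   multi-subject cohort simulator with known fixed and random effects, so
   every stage is verifiable against ground truth.

The model at the core of the inference layer is

    y_ij = μ + Time_j + Group_g + (Time×Group)_gj + b_i + ε_ij,
    b_i ~ N(0, σ²_subject),  ε_ij ~ N(0, σ²_resid),

estimated by REML, with contrast tests t = c′β̂ / √(c′Ĉc) referred to a
t-distribution on Satterthwaite degrees of freedom
ν = 2(c′Ĉc)² / Var(c′Ĉc).

## Worked example

`examples/04_postural_deltas.py` computes the postural-test delta scores
from the bundled bed-rest cohort summary table (23 young men, 60-day HDT,
11 controls vs 12 jump-training):

```
SBP    CTRL   supine     129.5   112.5   -17.0 mmHg
SV     TRAIN  supine     101.6    94.6    -7.0 mL
```

The −17 mmHg is the post-bed-rest supine hypotension seen only without the
exercise countermeasure; stroke volume falls 5–7 mL in every group and
posture.  `examples/01_single_recording.py` runs the full signal chain on a
synthetic session and prints, for configured LF/HF modulation variances of
300/700 ms² and a 0.27-Hz respiratory modulation:

```
HR     58.7 bpm      SBP  129.4 mmHg   DBP  70.5 mmHg
VLF   198.8 ms^2     LF   561.9 ms^2   HF  638.9 ms^2
LF/HF  0.88          DFA1  0.59    EDR  0.27 Hz
```

The other examples cover the spectral chain in isolation, DFA on reference
noises, and mixed-model inference on a simulated cohort with an injected
group×time effect.

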