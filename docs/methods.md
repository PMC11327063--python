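# Methods

## The problem

Respiration modulates heart rate through vagal control of the sinoatrial
node — respiratory sinus arrhythmia (RSA): heart rate rises on inhalation
and falls on exhalation.  The modulation shows up in the heart-rate
spectrum as a narrow component at the breathing frequency, so breathing
rate can in principle be read off a time–frequency analysis of heart rate
alone, without the ECG waveform — which matters because heart rate is
available from pulse oximeters and wrist PPG sensors that never see an ECG.

The difficulty is that the high-frequency band (0.15–0.40 Hz) also carries
non-respiratory components — movement, arousals, autonomic transients —
that can briefly out-power the RSA line.  A per-slice maximum-power rule
("Max-Power EDR") follows whatever is strongest and therefore jumps to
these transients.  The extractor implemented here (scEDR, spectral-
continuity EDR) instead exploits a structural asymmetry: the RSA component
is present whenever the subject breathes, while competing components are
intermittent.  The longest-lasting continuous spectral track is therefore
the breathing component.

## Pipeline

1. **Heart rate** (`preprocessing`).  R peaks are detected with a
   Pan-Tompkins-style detector (5–25 Hz band-pass, squared derivative,
   150 ms integration, adaptive threshold, 270 ms refractory).
   Instantaneous heart rate HR = 60/ΔRR is placed at interval midpoints
   and resampled to a uniform 20 Hz grid (one sample per 50 ms analysis
   slice).  Intervals outside 0.27–3 s are artifacts, bridged by the
   interpolation of their neighbours rather than deleted, which preserves
   the uniform grid the wavelet transform needs.

   The gridding interpolant is a modified Akima cubic.  Two failure modes
   were weighed: an unconstrained spline overshoots around artifacts and
   injects spurious spectral content into the search band, while strictly
   monotone schemes (PCHIP) clip every extremum of a ~0.3 Hz oscillation
   sampled at ~1.2 Hz beat rate — measured 1.11 bpm peak deviation on an
   integrate-and-fire oracle versus 0.71 bpm for modified Akima, whose
   overshoot on the same data is negligible.

2. **Gold standard** (`preprocessing`).  Nasal-pressure flow crests mark
   breaths; BR = 60/(crest–crest interval).  The flow is low-passed at
   1 Hz (zero-phase) before peak picking because a breathing crest is
   locally flat and raw sensor noise otherwise jitters the detected crest
   by hundreds of milliseconds; each crest is then refined sub-sample by a
   parabolic fit.  Crest prominence is 25 % of the signal's interquartile
   range, evaluated in a 10-s window so a flat apnea stretch cannot borrow
   prominence from distant troughs.  Crest intervals longer than 7.5 s
   (below 8 breaths/min) are read as pauses, not slow breaths, and
   bridged.

3. **Time–frequency analysis** (`morse`).  Generalized Morse wavelet,
   frequency-domain form a·ω^β·e^(−ω^γ) for ω > 0, with γ = 3 (Gaussian-
   like envelope) and β = 90; the time-bandwidth product γβ = 270 buys the
   frequency resolution needed to separate breathing from its neighbours
   at the cost of ~10 s time resolution.  The transform is exact per
   frequency bin: the analytic filter is rescaled so its modal frequency
   (β/γ)^(1/γ) sits at each requested frequency (0.05–0.45 Hz in 0.02 Hz
   steps; 50 ms slices) and applied by FFT multiplication — no dyadic
   scale discretization.  Normalization is "bandpass" (filter peak = 2),
   so a unit tone at a bin yields a unit-magnitude coefficient, making
   ridge powers comparable across frequencies.  Slices within 1.5 wavelet
   e-folding times (√(βγ)/2πf) of either record edge are flagged invalid
   per frequency (cone of influence) and produce no peaks.

4. **Peak extraction** (`edr`).  Per slice, local power maxima inside the
   breathing search band 0.15–0.45 Hz; a peak is significant if it
   reaches 20 % of the slice's maximum power over the wider 0.05–0.45 Hz
   spectrum.  Taking the threshold maximum over the wider band lets a
   strong low-frequency component suppress insignificant ripple in the
   breathing band without ever removing the breathing ridge itself.

5. **Track building** (`edr`).  Peaks of adjacent slices are linkable when
   their frequencies differ by at most one bin (0.02 Hz — physiological
   breathing drift over 50 ms is orders of magnitude smaller) and at most
   40 peak-less slices (2 s) intervene.  Tracks are extracted by
   successive longest-chain extraction: a forward dynamic program over the
   linking relation finds the chain of maximal duration (end − start + 1,
   internal gaps included), removes its peaks, and repeats.  An eager
   nearest-frequency linker was evaluated first and rejected: on 10–15 %
   of small random peak fields it falls short of the true longest chain,
   because a span-maximal chain may legally zig-zag between neighbouring
   bins or ride out a gap where an eager linker commits early.  With the
   dynamic program the longest track is span-optimal by construction,
   which the test suite verifies against an independent brute-force
   longest-path oracle.  Records are processed whole: the chain extraction
   is linear in the number of peaks per pass and peak lists are small, so
   no windowing is needed.

6. **Track selection and apnea rejoining** (`edr`).  The longest track
   wins; equal durations are broken by higher mean peak power.  When the
   winning track ends (apnea — the RSA component genuinely vanishes — or
   dropout), the candidate track starting within 60 s whose first
   frequency is closest to the last valid frequency is appended, and the
   process repeats.  Slices not covered by any appended track hold the
   last valid frequency and are flagged `gap-bridged` in the output's
   per-sample confidence channel; slices backed by an actual peak are
   `tracked`.  BR(t) = 60·f(t).

7. **Reconstruction** (`morse.inverse_cwt_band`).  A breathing-analogue
   waveform is recovered by summing the real parts of coefficients within
   ±0.015 Hz of the selected ridge, per slice, scaled by the included
   bins' filter gains at the center frequency so a pure tone is recovered
   at its true amplitude.  Restricting the inversion to the ridge window
   (rather than the whole HF band) excludes the non-respiratory
   parasympathetic content of that band.

8. **Evaluation** (`evaluate`).  Both rates are averaged per 30-s scored
   epoch (half-open windows aligned to the hypnogram); error =
   |BR_EDR − BR_pressure|, %error = 100·error/BR_pressure.  Stage
   summaries report mean ± sample SD and epoch counts; gap-bridged samples
   are included by default (a switch excludes them) so noisy stretches
   count against the method.  The four-panel report mirrors the standard
   visual check: 2-s moving-average HR, both breathing rates, hypnogram
   with REM onsets (solid) and offsets (dotted), and per-epoch %error
   against a 5 % reference line.

9. **Autonomic metrics** (`autonomic`).  Band powers use the standard HRV
   bands (VLF 0.004–0.05, LF 0.05–0.15, HF 0.15–0.40 Hz) integrated from
   the wavelet PSD over a 90-s window centered on each epoch, on an
   extended fine grid (0.004–0.45 Hz, 0.002 Hz steps).  Wavelet power is
   converted to a one-sided PSD estimate by dividing each bin by its
   filter's equivalent noise bandwidth factor; without this correction a
   constant-Q wavelet bank tilts flat spectra by a factor proportional to
   frequency.  After correction, white noise yields LF/HF equal to the
   bandwidth ratio 0.10/0.25 = 0.4, which the tests verify by Monte
   Carlo.  Bands are summed over half-open bins, so power is exactly
   additive across adjacent bands.  A 30-s epoch holds at most a fraction
   of a VLF cycle; VLF values are therefore partial-cycle estimates and
   the ratios are the robust quantities.

10. **REM0 restaging** (`autonomic`).  Per-epoch variability is the
    within-epoch SD (of heart rate, and of EEG global field power — the
    across-channel SD at each sample).  Thresholds are the 95th percentile
    of the eyes-closed-wake baseline epochs (statistic and percentile are
    configurable; the restaging rule's provenance fixes only the logic,
    not the statistic).  Rule: HR variability at or below threshold keeps
    the expert label; above it, high GFP variability relabels the epoch
    REM0, low GFP variability relabels it REM; epochs needing a GFP
    verdict without GFP data are left unchanged and flagged.

## The simulator and what it does (not) show

`scedr.simulate` generates records with known ground truth:

- HR(t) = baseline + a(t)·sin(2π∫f_BR dt) + interferers + LF drift
  (+ optional white noise); the RSA term's instantaneous frequency equals
  the commanded breathing trajectory exactly and is zeroed inside apnea
  windows.  Defaults: 70 bpm baseline, 2 bpm RSA depth (a free parameter
  chosen as typical of resting adults — real modulation depths are
  subject- and age-dependent), breathing at 15 bpm within the 9–27 bpm
  representable band.
- Flow = sin of the same breathing phase, flat plus a 1 % noise floor in
  apnea; crest times are bookkept as ground truth.
- ECG: integrate-and-fire beats (a beat fires when ∫HR/60 dt crosses an
  integer, so reciprocal R-R intervals encode HR(t) exactly) with an 80 ms
  raised-cosine QRS of 1 mV on a 1 % noise floor.
- Stage-programmed records: per-stage RSA and LF-drift amplitudes (deep
  NREM: strong RSA, weak LF; REM/REM0: the reverse) and transient
  interferers (30 s, 2× local RSA amplitude, ≥ 2 bins off the breathing
  frequency) placed preferentially in REM epochs.
- The default robustness interferer sits ≥ 2 bins from the true frequency
  at twice the RSA amplitude — strong enough to capture the Max-Power
  baseline while leaving the RSA track intact (its power stays above the
  20 % threshold), which is precisely the regime where continuity beats
  power.

Everything is deterministic given the scenario seed.

What the simulator does **not** emulate: realistic ECG morphology (P/T
waves, ectopic beats), amplitude-modulated or non-sinusoidal RSA,
frequency-dependent RSA attenuation, movement artifacts beyond additive
sinusoidal transients, or realistic EEG.  Passing tests therefore
demonstrate the algorithm's behaviour under its stated signal model —
continuity beats power selection under transient interference — not
clinical-grade accuracy on real polysomnography, which requires real
recordings.

## Numerical choices and degenerate inputs

- Morse filter evaluated in the log domain (β = 90 overflows ω^β).
- Link/threshold comparisons carry a 1e-9 absolute epsilon so one-bin
  jumps at exact tolerance are linkable despite float rounding.
- Equal-span and equal-jump ties in chain extraction are broken
  first-come and counted; only ties during the first (longest) extraction
  can affect the selected track, so only those are reported.
- Flat or empty ECG → `NoBeatsError`; no significant peaks and no prior
  track → `NoRespiratoryComponentError`; an empty reconstruction band
  names the offending slice.
- Analysis problem sizes used by the test suite and acceptance script
  (10–20 min records, 20 Hz grids, 21–224 frequency bins) keep every run
  in seconds while leaving ≥ 16 interior epochs per record; they are
  scaled-down study conditions, not algorithmic limits.

## Known limitations

- Track extraction is O(total peaks × gap window) per extracted track;
  whole-night records with heavy scatter produce many transient tracks
  and would benefit from consolidating the remainder extraction — not
  needed at the record lengths exercised here.
- Rejoining is forward-only: slices before the first track hold its first
  frequency backwards.
- The EDF writer emits plain EDF (16-bit, one-second records) without
  EDF+ annotations; reading requires `mne` (optional extra `scedr[edf]`).
- The REM0 thresholding statistic (within-epoch SD, 95th percentile) is a
  reference default; the underlying restaging literature leaves the exact
  statistic open, so both are configuration.
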