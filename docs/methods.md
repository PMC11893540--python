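# Methods

This note documents the models, conventions and design choices behind
`gammasleep`: the synthetic-night generator, the preprocessing chain, the
two outcome constructions (40 Hz spectral power and time-domain SSVEP
amplitude) with their signal-to-noise ratios, the sleep-quality metrics,
and the statistical battery. It states what the synthetic data do and do
not emulate, and therefore what passing tests do and do not show about
real recordings.

## The measurement problem

A 40 Hz square-wave light flicker (50 % duty cycle) delivered through
closed eyelids drives a steady-state visually evoked potential (SSVEP) at
the stimulation frequency over occipito-parietal cortex. The analysis must
establish that 40 Hz EEG activity during stimulation (i) exceeds the
matched unstimulated baseline, and (ii) is stimulus-locked rather than
myogenic, ocular or electrical in origin. Two complementary outcome
constructions address this:

* **PSD40** — the power spectral density at exactly 40 Hz, from per-epoch
  Hamming periodograms averaged per condition × stage, in dB re 1 V²/Hz.
  Its SNR divides the 40 Hz power by the mean power in the flanking bands
  [38, 39.5] ∪ [40.5, 42] Hz, correcting for the individual 1/f shape.
* **SSVEPamp** — the peak-to-trough amplitude of the average of 25 ms
  segments (one flicker cycle each) time-locked to the LED-ON edge. Brain
  or muscle activity not phase-locked to the flicker averages towards zero;
  only stimulus-locked components survive. Its SNR compares the true
  averaged amplitude to a within-segment sample-shuffle null.

Electrical pickup from the LED drive is the one artifact that *is*
stimulus-locked and would survive evoked averaging. Two controls expose
it: a covered-LED control night in which the drive circuit runs all night
with no light reaching the eyes (any time-locked structure in that average
is electrical), and linear interpolation of the samples around every LED
on/off edge, which removes a brief electrical transient while leaving the
SSVEP extrema — at the quarter-cycle phases, away from the edges —
untouched.

## Synthetic nights

The generator (`gammasleep.synth`) renders full PSG sessions: six ROI
channels (O1, Oz, O2, PO3, POz, PO4), two mastoids (A1, A2), two EOG and
two chin-EMG channels.

**Stimulation schedule.** Experimental nights are closed-loop: the light
turns on at the first N3 epoch with a 300 s raised-cosine illuminance ramp
(`I(t) = ½(1 − cos πt/300)`, so `I(150 s) = 0.5`), fades out over 5 s at
any W or N1 epoch, and restarts (with a fresh ramp) once six consecutive
epochs scored neither W nor N1 have elapsed. The 40 Hz flicker runs
throughout fades; only the illuminance envelope ramps. A hypnogram with no
N3 yields an all-off schedule flagged `never_triggered`. Control nights
run the LED circuit for the whole recording with zero illuminance
(covered LEDs). Awake sessions (`wake_session=True`) stimulate
continuously at the target level from the first sample. The LED drive is
phase-locked to the sample clock in whole 25 ms cycles; the sampling rate
must be an integer multiple of 40 Hz so one cycle is an integer number of
samples.

**Evoked response.** During visible stimulation the ROI channels receive a
40 Hz sinusoid (optional second harmonic via `harmonic_ratio`, default 0)
starting at phase 0 on each LED-ON edge, scaled by the per-stage
peak-to-trough amplitude and the instantaneous illuminance. The waveform
is normalised on the sampled cycle grid so that the *sampled* peak-to-
trough equals the configured amplitude exactly — parameter-recovery tests
then have an exact target. Stage amplitude defaults (W 0.96, N2 0.08,
N3 0.07, REM 0.09 µV peak-to-trough) follow published per-stage medians
for this paradigm; they are descriptive defaults, not mechanistic claims.

**Background model.** Each channel carries independent noise with two
components, both scaled by a stage-dependent broadband factor (W 3.0,
N1 1.4, N2 1.2, N3 1.05, REM 1.0 — wakefulness carries muscle tone and
alertness power):

* a 1/f^β aperiodic component (β = 1.8, 2 µV rms per channel, flattened
  below the 0.16 Hz acquisition high-pass), and
* a white instrument/myogenic floor (1.3 µV rms per channel).

Stage-signature oscillations (posterior alpha 10 Hz in W, theta in N1/REM,
spindle-band 13 Hz and delta 1.5 Hz in N2, slow oscillation 0.8 Hz in N3)
are shared across EEG channels with group gains (mastoids 0.35) and a slow
random amplitude envelope.

Two deliberate departures from physiological amplitude scales matter for
interpretation:

1. *Broadband levels are set low* (a few µV rather than tens of µV).
   The peak-to-trough of an averaged waveform is an extreme statistic: its
   upward noise bias scales with the processed fast-noise σ divided by
   √n_segments. Recovering sleep-stage SSVEP amplitudes of ~0.07 µV within
   10 % at ~10⁵ segments — the package's stated recovery tolerance —
   requires processed fast noise ≲ 1 µV. At fully physiological noise the
   same estimator would need millions of segments per bin.
2. *Oscillation amplitudes are sub-physiological* (e.g. slow waves 10 µV
   rather than 50–100 µV). The shuffled-segment null destroys
   within-segment sample ordering; smooth low-frequency content inflates
   the shuffled variance while contributing little roughness to the true
   average, dragging the control-condition shuffle SNR below 1. In real
   recordings broadband myogenic/instrument noise is itself much larger,
   which keeps the null near 1; with the generator's reduced broadband
   floor, realism in the *ratio* of broadband to rhythmic power is what
   the null calibration needs, and that ratio is preserved by scaling both
   down together.

Consequently: passing tests show the *pipeline* is correct and calibrated
(nulls near 1, recovery unbiased, contrasts in the designed direction);
absolute dB levels sit several dB below published values for real sleep
EEG, and test results do not by themselves certify behaviour at fully
physiological noise amplitudes.

**Sampling rate.** Default 600 Hz. With the fixed 0.16–300 Hz analysis
band, a rate of 600 Hz puts the 300 Hz edge at Nyquist: the low-pass
branch of the filter is vacuous (the implementation then applies the
high-pass alone and logs it), and the processed noise stays white at the
sample level. At 1000 Hz the 300 Hz low-pass leaves adjacent samples
correlated, which the within-segment shuffle null whitens away — the
control shuffle SNR then sits systematically below 1, a property of the
estimator, not of the data. Clinical PSG systems commonly digitise near
500 Hz, where the same near-Nyquist regime holds; 600 Hz is the closest
multiple of 40. Any multiple of 40 Hz remains a valid setting.

**Hypnogram.** Semi-Markov dynamics: per-stage minimum bout lengths with
geometric tails and a jump matrix between stages, starting in W. Bout and
jump parameters were set so that 8 h nights average TST ≈ 432 min,
WASO ≈ 46 min, %N2 ≈ 55, %N3 ≈ 18, %REM ≈ 20 of total sleep time — the
healthy-young-sleeper profile this paradigm reports. Nights are redrawn
(deterministically, bounded) in the rare case no N3 occurs, so the
stimulation trigger always fires. Scoring certainty is Beta(10, 2)
(mode 0.9), so the < 50 % certainty rejection rule is exercised on a few
epochs per night. First-order Markov dynamics with a user transition
matrix are available for tests; ultradian cycling beyond first-order
structure is not modelled.

**Artifacts.** Poisson-scheduled EMG bursts (30 µV on EMG, 3 µV leak into
ROI), ocular deflections (120 µV on EOG, 4 µV ROI leak) and rare gross
movements (> 1 mV on all channels, exercising the amplitude rejection
rule). The optional electrical LED artifact is a biphasic ±A transient
(default width 2 ms) at every on/off edge while the circuit is active —
including control nights. Its coupling gains differ per electrode group
(ROI 1.0, mastoids 0.5, EOG 1.5, EMG 1.2, ±10 % per-channel jitter):
with identical coupling the artifact would cancel exactly under mastoid
re-referencing and the control analyses would be vacuous; heterogeneous
pickup is the physically realistic case.

## Preprocessing conventions

Zero-phase 4th-order Butterworth band-pass (0.16–300 Hz,
forward–backward); bad channels flagged when flat (variance < 0.01 µV²)
or when the robust z-score of log-variance within the ROI group exceeds 5
(median/MAD, MAD floored at 0.05 log-units so near-identical variances are
not hypersensitive; mastoids are exempt from the outlier rule since the
reference pair has a legitimately different variance scale). Processed
signal = mean(ROI) − mean(A1, A2). Epochs are half-open 30 s windows,
0-based. Rejection: peak-to-peak > 1 mV, certainty < 0.5, or visible
stimulation < 25 s — the last only in the experimental condition (in the
control night the LEDs are covered, so the rule, whose purpose is to
guarantee stimulated data, is vacuous there). Rejection depends only on
each epoch's own data, hence idempotent; segments inherit their parent
epoch's flag. Bin routing: control bins from session 2; experimental W
from session 1 (awake stimulation block); experimental N2/N3/REM from
session 3; N1 enters no bin.

## Spectral conventions

Single Hamming taper over the full 30 s epoch (no Welch sub-segmentation):
the 1/30 Hz resolution is what places bins at exactly 40, 39.5 and 40.5 Hz
and fills the flanking bands (46 bins in [38, 39.5], bounds inclusive).
Density scaling; µV converted to V before the logarithm, so powers are dB
re 1 V²/Hz. Zero-power bins are floored at −400 dB and logged. Averaging
across epochs happens on the linear power scale (averaging dB values would
bias low); `extract_psd40` returns the bin at exactly 40 Hz and refuses to
interpolate. The neighbour-band SNR is computed on the linear scale: a
literal ratio of dB values would invert the intended ordering for
negative-dB spectra and contradict the interpretation that SNR ≤ 1 means
"no distinguishable 40 Hz activity" — the linear reading is the one
consistent with that interpretation and with near-1 null behaviour.

## SSVEP conventions

Segments are contiguous, non-overlapping, one per flicker cycle, locked to
LED-ON edges; in experimental data only cycles at full visible illuminance
qualify (fade-in/fade-out excluded); in control data the electrical clock
defines the edges. Segments with range > 100 µV are rejected (strict
inequality: exactly 100 µV is kept). The amplitude is max − min of the raw
averaged waveform — no sinusoid fitting or smoothing. The shuffle null
permutes the sample order within every segment independently, with fresh
permutations on each of the 100 repeats, under one seeded generator; an
all-constant segment set makes the null degenerate and raises. The
interpolation control replaces samples strictly inside ±window/2 of every
edge with the line between the boundary samples; the window must exceed
the artifact width (with a sample to spare at coarse sampling rates —
tests use 7 ms at 600 Hz for a 2 ms artifact) and stay below the 12.5 ms
half cycle so windows cannot overlap.

## Sleep metrics

Epoch unit 0.5 min. TST = 0.5 × #{N1, N2, N3, REM}. WASO counts W epochs
strictly between the first and last sleep epoch — wake before sleep onset
is sleep-onset latency; wake after the final sleep epoch counts towards
neither (the definition is read literally). REM latency is referenced to
sleep onset (first non-W epoch), the conventional choice. Stage
percentages are of TST and sum to 100 exactly when TST > 0; an all-wake
night returns TST = WASO = 0 with latencies flagged None. GSQS items are
consumed as already-keyed 0/1 responses (the copyrighted item text is not
embedded); the sum ranges 0 (perfect) to 14 (poor).

## Statistics

Pairwise contrasts are gated: Shapiro–Wilk on the pair differences
(α = .05) and a 3×IQR outlier screen route to the paired t-test (effect:
Cohen's d_z = mean(d)/sd(d), CI by noncentral-t inversion) or the Wilcoxon
signed-rank test (effect: matched-pairs rank-biserial r, CI by normal
approximation of the signed-rank statistic). Constant differences make
Shapiro–Wilk undefined; normality is then n/a and the test degenerates to
p = 1 with zero effect, flagged. The four-stage contrast gates
additionally on Mauchly sphericity: the parametric branch runs a one-way
repeated-measures ANOVA with classical η² = SS_stage/(SS_stage+SS_error)
and Tukey post-hocs on the repeated-measures error term (studentized
range with MS_error and its df — the independent-groups Tukey would be
wrong here); the nonparametric branch runs Friedman with Kendall's
W = χ²/(n(k−1)) and pairwise signed-rank post-hocs under Bonferroni–Holm.
Which correction applied is recorded in the result flags. η² and W CIs are
bootstrap percentile intervals over subjects (2000 resamples, seeded).

Assumption-gated two-stage procedures have a mildly distorted level: under
a true null the gated paired comparison rejects at ≈ 0.051 rather than
0.050 (the t-branch conditions on "looks normal", the Wilcoxon branch on
"looks non-normal"). This pre-testing distortion is a property of the
published procedure itself, reproduced faithfully rather than corrected.

`power_simulation` draws N(d, 1) differences and evaluates the paired t
vectorised; tails, α and the n grid are parameters. The closed form
`paired_t_power` (noncentral t) is the cross-check. No attempt is made to
reproduce any particular published sample-size derivation, whose test
family and multiplicity assumptions are not stated; the simulator exposes
them instead.

## Problem sizes and numerical choices

Tests and the acceptance script size their simulations for a single CPU:
null calibration uses 20 seeded 24-min control nights; parameter recovery
uses one long stimulated night (~5 h, ≥ 2×10⁵ segments per sleep-stage
bin) plus a 25 min awake block; the type-I calibration runs 60 000
simulated null experiments (n = 30) and the power check 50 000. These are
the package's chosen operating points; all scale up by configuration.
Other numerics: EDF export is 16-bit with per-channel physical ranges
(quantisation step (max−min)/65535); flat channels get a ±1 µV dummy
range; the LED duty cycle rounds to whole samples (8/15 at 600 Hz);
p-values are capped at 1; the dB floor is −400.

## Limitations

The generator is a calibration instrument, not a cortical model: no
ultradian architecture beyond first-order bouts, no evoked-response
latency or phase dispersion across subjects, no eyelid-transmission
photometry, no circadian modulation, and noise amplitudes deliberately
below physiological scale (see above). Harmonic content of the SSVEP is
off by default. The statistics module covers the paired/four-level designs
used here, not general factorial models.
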