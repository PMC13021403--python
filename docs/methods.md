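# Methods

This note documents the models, algorithms and numerical choices behind
`prosodiff`, the assumptions they rest on, and what the synthetic-data
validation does and does not demonstrate about real recordings.

## Signal conventions

Audio is mono, full-scale float in [−1, 1]; times are seconds with
half-open intervals `[start, end)`; sample 0 is t = 0. Every recording
is peak-normalised to 99% of full scale before analysis, so all level
measures are *relative to the recording's own peak*. Absolute dB SPL
would require a microphone calibration the data do not carry; an
optional calibration offset can be added, and within-speaker BEF−AFT
differences are unaffected by it either way. Undefined quantities are
always NaN, never a silent zero.

## Pause marking and timing

Short-time intensity (RMS over 30 ms windows, 10 ms hop, in dB) is
thresholded at 25 dB below the utterance's peak frame intensity —
relative to the peak, so segmentation is exactly invariant to global
gain. Runs of silent windows become pause *spans* covering the union of
their windows, which recovers boundaries at hop resolution without the
window-length bias that labelling hop slots incurs. Internal silent
spans shorter than `min_pause_s` (0.25 s) are absorbed into speech;
speech gaps shorter than `min_speech_s` (0.10 s) merge into the
surrounding pause. Leading/trailing silence is labelled pause but never
counted in pause statistics. The 0.25 s / 0.10 s / 25 dB defaults are
conventional for read speech and are configurable; they are declared
choices, not values recovered from any reference analysis.

Speaking rate counts syllable nuclei — voiced intensity peaks inside
speech intervals with at least 2 dB prominence and 0.1 s separation —
divided by the span from the first to the last speech interval (pauses
included). An articulation-rate variant divides by speech time only.
When a transcript with a known syllable count is available, that count
can be supplied directly to `speaking_rate`.

## f0 tracking

An autocorrelation tracker: per 10 ms frame (frame length 2.5 periods
of the 60 Hz floor), the normalised autocorrelation is searched in the
lag band [1/ceiling, 1/floor] (defaults 60–500 Hz for a mixed-gender
cohort). Peak *selection* uses the raw biased estimator, whose
short-lag preference guards against subharmonics; the voicing
*decision* applies the 0.45 threshold to the lag-corrected value so
low-f0 frames are not penalised by the estimator's triangular bias.
Frames more than 35 dB below the loudest frame, or riding an amplitude
ramp steeper than 10 dB between the frame's first and last third
(syllable onsets at pause edges — these lock onto fractional-period
peaks), are unvoiced. Lag is refined by parabolic interpolation; the
voiced contour is median-filtered (5 points, run over the voiced
subsequence so run-edge spikes still have valid neighbours). A second
pass narrows the band to [0.55, 1.8] × the first pass's median voiced
f0 — the standard guard against locking onto a vocal-tract resonance
or an octave when the search band is much wider than the speaker's
range; read speech rarely exceeds ±8 st around its median, which this
band accommodates. The refinement can be disabled (`refine=False`).

f0 statistics: minimum and maximum are the extrema of the cleaned
contour (the literal reading of "minimum, maximum"; a robust 5th/95th
percentile variant sits behind `robust_f0_extrema`); range is
`12·log2(max/min)` semitones and is by construction consistent with
the reported extrema; level (mean) and standard deviation are in Hz.
Standard deviations of frame-wise quantities are population (n)
standard deviations throughout the feature layer; group summaries in
the statistics layer use the sample (n−1) convention.

## Loudness

RMS over non-overlapping 20 ms windows within speech intervals only,
expressed in dB; level is the mean and variability the standard
deviation of the per-window dB values. Windows snap to a global grid
(multiples of 20 ms from t = 0) so measurements are stable under
silence padding. "Signal elongations" are taken as the waveform's
sample amplitudes.

## Formants

Analysis at 10 kHz (polyphase resampling), pre-emphasis 0.97, 25 ms
Hamming windows at voiced frames, order-12 autocorrelation LPC, root
solving. Roots qualify as formant candidates when their frequency lies
in [90, 4500] Hz and their bandwidth is at most `min(700, f/2)` — an
absolute cap plus a minimum-Q requirement. The simpler "bandwidth
≤ 400 Hz" rule was rejected after synthetic validation: it admits
spurious broad sub-F1 roots (e.g. 430 Hz with a 399 Hz bandwidth) while
rejecting genuine F3 roots whose estimated bandwidths inflate under
pre-emphasis. A harmonic-richness gate (at least four spectral peaks
within 45 dB of the frame maximum) rejects line spectra such as pure
tones, whose LPC roots are phantoms; the per-frame tracks are lightly
median-smoothed (5 points) and levels are means over frames where all
three formants were found.

Known limitation: when f0 exceeds roughly 180 Hz and harmonics straddle
F1, LPC locks onto harmonics and splits or displaces the first formant
— the classic high-pitch formant-analysis problem, affecting any
LPC-based tracker. Formant recovery to ±5% holds on the steady-vowel
battery at speaking f0; female-range voices in running speech carry a
bias that is stable within speaker and therefore largely cancels in
within-speaker differences.

## Spectral tilt

Per voiced frame (window of 6 f0 periods — long enough that the Hann
mainlobe stays well under the harmonic spacing, so weak high harmonics
are not polluted by sidelobe leakage — zero-padded ×4): H1 and H2 are
peak magnitudes within ±f0/4 of f0 and 2 f0; each Ak is the strongest
harmonic peak within ±f0/2 of formant Fk, ties broken toward the lower
harmonic. Frames riding an amplitude ramp (> 6 dB across the window) or
containing an impulsive transient (peak > 8× frame RMS) are skipped:
harmonic measurement assumes local quasi-periodicity. Levels are means
and variabilities population standard deviations over valid frames,
excluded pairwise per measure. No formant-based tilt correction is
applied — the measures are the raw H1−Ak differences; a correction hook
is a natural extension point. Tilt is measured on all voiced frames of
the reading, not on vowel centres only.

## Treatment statistics

The analysis unit is the within-speaker difference `BEF − AFT` per
feature (positive ⇒ lower after treatment), which removes stable
between-speaker variation including gender baselines. Features are
grouped into families: intonation {f0 min, max, range, sd, level},
vocal effort {H1−H2, H1−A1, H1−A2, H1−A3 levels}, loudness {RMS level,
RMS sd}, and a timing family {pauses, mean pause, rate} that is
reported but carries no programmed effects. Family membership is
configurable.

Per family, a one-way MANOVA across the three arms: between-group (H)
and within-group (E) scatter matrices, Wilks' Λ = det(E)/det(H+E),
Rao's F approximation with the standard degrees of freedom, and
multivariate partial η² = 1 − Λ^(1/s). The implementation is verified
in tests against a brute-force elementwise scatter oracle (agreement to
1e−10) and against the statsmodels MANOVA (Λ, F, dfs and p to machine
precision); with a single variable it reduces exactly to the univariate
ANOVA. A Pillai-trace variant is available for robustness to covariance
heterogeneity. Follow-ups: univariate one-way ANOVA with
η²p = SS_effect/(SS_effect+SS_error), pairwise Welch t contrasts with
Holm (default), Bonferroni or no correction, and per-arm mean ± se
summaries. The omnibus threshold defaults to the exploratory α = 0.1;
pairwise contrasts are conventionally judged at 0.05. Analyses are
complete-case per family; with N = 30 no imputation is attempted.
Note that the f0-range column is a deterministic function of the min
and max columns, which makes the intonation family nearly collinear
and can mildly inflate its omnibus type-I rate; calibration checks use
the vocal-effort family, whose members are generated independently.

## Synthetic voices and cohorts

The generator exists so every stage can be validated by parameter
recovery; its defaults are the emulated study conditions.

**Source-filter synthesis.** The voiced source is an impulse train
(phase-accumulated along the f0 contour) convolved with a Rosenberg
glottal-flow-derivative pulse, then shaped by a double real pole (or,
for negative targets, double zero) solved by root-finding so that the
source's H1−H2 at the contour's level frequency equals the programmed
target exactly; each first-order section spans just under 6.02 dB, so
targets within about ±12 dB are reachable. The glottal pulse gives the
natural high-frequency rolloff that all-pole (LPC) analysis assumes —
a bare impulse train destabilises it. The vocal tract is a cascade of
second-order resonators at the programmed formants. The f0 contour is a
0.8 Hz sinusoid between `level·2^(±range/24)` (linear in Hz, so its
time average is the midpoint). Syllables are flat-top (Tukey, 30 ms
ramps) amplitude bumps on a fixed grid; internal pauses are silent
gaps. Ground truth for every measurable quantity is computed
analytically from the programmed contour and filter responses,
restricted to the envelope's support and averaged along the contour
(the same conditioning the frame-wise measurements have).

A deliberate device: one "anchor" syllable is always at the envelope
ceiling and carries a deterministic stress transient (a click pinned to
12× the syllable's RMS) that provides the waveform peak. This keeps the
crest factor constant across conditions, so a programmed loudness
change survives per-file peak normalisation — emulating quieter speech
whose occasional stressed peaks still reach the recording ceiling.
Without it, source-tilt changes alter the crest factor and leak
voice-quality effects into peak-relative loudness (by several dB), as
they plausibly also do in real peak-normalised recordings.

**Cohort design.** Defaults mirror the emulated study: 3 arms × 10
speakers, 7 female / 3 male per arm, one BEF and one AFT reading each
(48 kHz output, 20 s readings). Baselines are conventional phonetics
values — female f0 level 200 ± 20 Hz with formants near 550/1700/2800,
male 120 ± 15 Hz with 500/1500/2500, H1−H2 around 6 dB (female) or
3 dB (male) — synthetic choices, not study data; features are drawn
independently per speaker (real between-speaker covariance is unknown
and not modelled). Both readings of a speaker share one syllable/pause
layout (the same text read twice), so paired differences isolate the
programmed voice changes.

**Effect presets.** The control arm encodes the directional pattern of
interest: f0 minimum and level drop after the waiting period (positive
diffs), the f0 range widens, all four tilt measures drop (tenser
voice), the reading gets 4.5 dB softer and less variable in loudness.
The two intervention arms share one near-zero preset with slightly
negative tilt diffs (breathier after treatment), making their pairwise
contrast null by construction; a null preset (all zeros) supports
type-I calibration. Only the 4.5 dB loudness anchor tracks a reported
magnitude; every other magnitude is a synthetic calibration value
chosen once to give realistic, detectable effects at n = 10/arm.
Per-speaker effects scatter around the arm mean with sd = 30% of the
effect magnitude, plus feature-specific session-to-session noise
(e.g. 1 dB for RMS level, 2.5 Hz for f0 level) that keeps the null
generator non-degenerate.

**Fast path.** `simulate_cohort_features` draws the feature tables
directly (no audio), with the f0 range recomputed from the simulated
extrema so rows stay internally consistent. It drives the statistical
calibration studies (500-replicate type-I error, power, direction
rates) where audio synthesis would be pointlessly expensive.

## Problem sizes used in tests and validation

Audio validation runs at 16 kHz with 8–12 s readings and 3–5 speakers
per arm; the feature-level studies use the full 10-per-arm design.
These sizes were chosen as the smallest at which every recovery
tolerance is meaningfully exercised; the generator's defaults remain
the full study conditions (48 kHz, 20 s, 10 per arm) and scale freely.

## What the synthetic validation does and does not show

Passing recovery tests shows the implementation measures what it claims
to measure on signals whose ground truth is known exactly: harmonic
source, stationary formants, noise-free channel, programmed pauses.
Real read speech adds aspiration and channel noise, consonants and
unvoiced stretches, formant movement, room acoustics and speaker
idiosyncrasy; none of these are modelled, so the tolerances achieved
here are lower bounds on real-data error, not guarantees. The
statistical layer's calibration, by contrast, depends only on the
distributional assumptions of the feature simulator (independent
normal noise) and transfers directly whenever those approximately hold
for measured features.
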