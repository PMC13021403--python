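# prosodiff

Speech prosody is a sensitive, non-invasive biosignal for stress and
relaxation: pitch, loudness, timing and voice quality shift
systematically with a speaker's physiological state. `prosodiff` is a
Python library for quantifying such shifts in before/after intervention
studies with read speech. It implements the complete analysis chain:

1. **Feature extraction** per recording: fundamental-frequency (f0)
   minimum, maximum, range (semitones), standard deviation and level;
   number and mean duration of silent pauses; speaking rate (syl/s);
   RMS loudness level and variability (20 ms windows, dB); formant
   levels F1–F3 (LPC root-solving); and the spectral-tilt voice-quality
   measures H1−H2, H1−A1, H1−A2, H1−A3 with their variabilities.
   Recordings are peak-normalised to 99% of full scale first.
2. **Within-speaker differencing**: the analysis unit is
   `diff = value(BEF) − value(AFT)` per feature — positive means the
   feature was *lower* after treatment.
3. **Three-arm treatment statistics**: one-way MANOVA per vocal
   dimension (Wilks' Λ = det(E)/det(H+E), Rao's F approximation,
   multivariate partial η² = 1 − Λ^(1/s)), univariate ANOVA follow-ups,
   pairwise Welch t contrasts with Holm/Bonferroni correction, and
   per-arm summaries, at the exploratory significance threshold
   α = 0.1. Treatment arms are VBRO (vibroacoustic stimulation), MEDI
   (guided mindfulness meditation) and CONT (no-stimuli control).
4. **A synthetic voice and cohort generator** (source-filter model with
   analytic spectral-tilt control) that emulates the study design —
   30 speakers, 3 arms × 10 (7 female / 3 male), two readings each —
   so every stage is verifiable by parameter recovery against
   programmed ground truth.

It is aimed at phoneticians and biosignal researchers running
before/after designs who want a reproducible, tested alternative to
ad-hoc analysis scripts.

## Worked example

`examples/03_treatment_statistics.py` simulates a feature cohort at the
full study design (10 speakers per arm) with the directional effect
presets and runs the inference chain:

```text
MANOVA per feature family (BEF-AFT differences, alpha = 0.1):
  intonation    Wilks lambda=0.181 F(10,46.0)=6.20 p=0.0000* eta_p^2=0.574
  vocal_effort  Wilks lambda=0.097 F(8,48.0)=13.28 p=0.0000* eta_p^2=0.689
  loudness      Wilks lambda=0.298 F(4,52.0)=10.82 p=0.0000* eta_p^2=0.454
  timing        Wilks lambda=0.929 F(6,50.0)=0.31 p=0.9281  eta_p^2=0.036

loudness-level contrasts (Welch t, Holm-corrected, alpha = 0.05):
  VBRO-MEDI: t=+0.16 p_adj=0.8714 (ns)
  VBRO-CONT: t=-5.67 p_adj=0.0001 (significant)
  MEDI-CONT: t=-5.58 p_adj=0.0001 (significant)

per-arm mean loudness difference (positive = softer after):
  CONT: +4.03 +- 0.45 dB (n=10)
  MEDI: +0.96 +- 0.31 dB (n=10)
  VBRO: +1.03 +- 0.28 dB (n=10)
```

The three programmed vocal dimensions separate the arms (small Λ, large
η²) while the untouched timing family stays null; the control arm reads
about 4 dB softer after the waiting period while the two intervention
arms are indistinguishable from each other — the pattern the generator
encodes. `examples/01_extract_profile.py` shows single-recording
feature recovery against programmed ground truth, and
`examples/02_simulate_audio_cohort.py` runs the same comparison end to
end through synthesised WAV audio.

## Command-line interface

For batch use from a shell, the `prosodiff` command wraps the library:

```bash
prosodiff simulate --out-dir cohort --seed 1        # synthetic cohort + manifest
prosodiff run cohort/manifest.csv --out-dir run     # extract, diff, stats, figures
prosodiff extract|diff|stats|plot ...               # the individual stages
```

A run directory contains `features.csv`, `diffs.csv`, `stats.json`,
`report.txt`, figures, and `run_config.json` with the full
configuration, library versions and input checksums.

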