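"""Simulate a small before/after audio cohort and recover the effects.

Writes WAV readings for 3 speakers per treatment arm (scaled down from
the default 10 for a quick demo), runs the feature extractor over the
manifest, forms within-speaker BEF-AFT differences, and compares the
recovered control-arm loudness drop with the programmed one. Positive
differences mean the feature was lower after treatment.
"""

import tempfile

from prosodiff import (
    CohortDesign,
    extract_features,
    simulate_cohort_audio,
    within_speaker_differences,
)

design = CohortDesign(
    n_per_group=3, n_female_per_group=2, seed=11,
    sample_rate=16_000.0, duration_s=10.0,
)
with tempfile.TemporaryDirectory() as tmp:
    manifest, truth = simulate_cohort_audio(design, tmp)
    print(f"synthesised {len(manifest.records)} readings "
          f"({manifest.n_speakers} speakers x BEF/AFT)")
    features = extract_features(manifest)

diffs = within_speaker_differences(features)
programmed = (
    truth[truth.condition == "AFT"]
    .set_index("speaker_id")["programmed_rms_shift_db"]
)

print("\narm   mean BEF-AFT diff:  f0_min(Hz)  H1-H2(dB)  rms(dB)")
for arm, group in diffs.groupby("treatment"):
    print(f"{arm}:  {group['f0_min_hz'].mean():>17.2f}"
          f"  {group['h1_h2_db'].mean():>9.2f}"
          f"  {group['rms_level_db'].mean():>7.2f}")

cont = diffs[diffs.treatment == "CONT"].set_index("speaker_id")
print(
    f"\ncontrol-arm loudness drop: recovered "
    f"{cont['rms_level_db'].mean():.2f} dB vs programmed "
    f"{programmed[cont.index].mean():.2f} dB."
)
print("The control arm shows the full pattern (lower f0 minimum, tenser")
print("voice, softer reading after the wait); intervention arms stay near zero.")
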