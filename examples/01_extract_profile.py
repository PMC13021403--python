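"""Extract the full prosody profile of one synthetic reading.

Synthesises a 8 s reading-like utterance with known voice parameters
(f0 level 120 Hz, 7 st range, H1-H2 source tilt +3 dB, formants at
500/1500/2500 Hz, two internal pauses), runs the extractor and prints
each measured feature next to its programmed ground truth. Close
agreement is what qualifies the extractor for real recordings.
"""

import numpy as np

from prosodiff import extract_profile, peak_normalise, synthesize_utterance
from prosodiff.synthetic_voice import build_reading_spec

rng = np.random.default_rng(42)
spec = build_reading_spec(
    duration_s=8.0, rng=rng, sample_rate=16_000.0,
    f0_level_hz=120.0, f0_range_st=7.0, h1_h2_db=3.0,
    formants_hz=(500.0, 1500.0, 2500.0), n_pauses=2,
)
signal, truth = synthesize_utterance(spec)
profile = extract_profile(peak_normalise(signal)).to_dict()

print("feature                measured   programmed")
rows = [
    ("f0 level (Hz)", profile["f0_level_hz"], truth.f0_level_hz),
    ("f0 range (st)", profile["f0_range_st"], truth.f0_range_st),
    ("H1-H2 (dB)", profile["h1_h2_db"], truth.h1_h2_db),
    ("F1 (Hz)", profile["f1_hz"], truth.formants_hz[0]),
    ("F2 (Hz)", profile["f2_hz"], truth.formants_hz[1]),
    ("F3 (Hz)", profile["f3_hz"], truth.formants_hz[2]),
    ("pauses (count)", profile["n_pauses"], truth.n_pauses),
    ("mean pause (s)", profile["mean_pause_s"], truth.mean_pause_s),
    ("speak rate (syl/s)", profile["speaking_rate_sps"],
     truth.n_syllables / truth.speech_span_s),
]
for name, got, want in rows:
    print(f"{name:<22} {got:>8.2f}   {want:>8.2f}")
print(
    "\nrms level (dB re full scale):", round(profile["rms_level_db"], 2),
    "- absolute level depends on the recording chain; only within-speaker",
    "differences are analysed downstream.",
)
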