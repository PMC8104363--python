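"""Simulate a night of polysomnography and inspect its structure.

Generates a 120-epoch hypnogram (five sleep cycles, normal-adult stage
proportions), synthesizes the matching stage-conditioned EEG at 125 Hz,
and writes both to disk as EDF + a plain-text hypnogram.
"""

from sleeptransfer import HypnogramSpec, generate_recording, write_edf
from sleeptransfer.eeg_io import write_hypnogram

spec = HypnogramSpec(n_epochs=120, n_cycles=5, seed=7)
rec, hyp = generate_recording(spec)

print(f"recording: {rec.samples.size} samples at {rec.sampling_rate:g} Hz "
      f"({rec.duration/60:.1f} min), channel {rec.channel!r}")
print("realized stage fractions (%):")
for stage, frac in sorted(hyp.fractions().items()):
    print(f"  {stage:>3}: {100*frac:5.1f}")
print("first two cycles of the hypnogram:")
print("  " + " ".join(hyp.stages[:48]))

write_edf("night.edf", rec)
write_hypnogram("night.hyp", hyp)
print("wrote night.edf and night.hyp")

# The fractions track the requested 5/20/50/25% N1/N2/N3/REM mix (exactly at
# large epoch counts); the label sequence shows each cycle descending
# N1 -> N2 -> N3, re-ascending to N2, then REM.
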