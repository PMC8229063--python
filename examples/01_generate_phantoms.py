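"""Generate a small synthetic radiograph dataset.

Renders rod-shaped implant phantoms with class-specific head geometry over
a soft-tissue background gradient, and writes a manifest CSV alongside the
PNGs.  Same spec + seed always reproduces the same bytes.
"""
from pathlib import Path

from drenet import SyntheticDatasetSpec, generate_dataset

out = Path("scratch_example_phantoms")
spec = SyntheticDatasetSpec(
    counts_per_class={"C1": 8, "C2": 30, "C3": 7, "C4": 15},
    master_seed=1, difficulty="easy")
manifest = generate_dataset(spec, out)

print(manifest.head())
print("\nper-class counts:", manifest["label"].value_counts().to_dict())
print(f"wrote {len(manifest)} PNGs to {out}/")
# The counts mirror a 1:3.5:0.9:1.8 manufacturer imbalance; 'hard' mode
# narrows the C2/C4 geometric gap to emulate the confusable class pair.
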