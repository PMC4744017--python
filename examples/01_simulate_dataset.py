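"""Generate a synthetic face-viewing dataset and write it to TSV.

The generator emulates a face-recognition eye-tracking study: each
participant studies 48 faces (16 Caucasian, 16 African, 16 Chinese) from a
controlled pre-stimulus start position, then sees 96 faces for 1 s each in
an old/new test.  Fixations follow a race-specific mixture over facial
features, so own-race faces attract slightly more eye fixations.
"""

from pathlib import Path

from gazecontrast import GeneratorParams, generate_dataset
from gazecontrast.io import write_aois, write_fixations

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

params = GeneratorParams(n_participants=6, seed=7)
ds = generate_dataset(params)
write_fixations(ds, out / "fixations.tsv")
write_aois(ds.layouts, out / "aois.tsv")

n_study = len(ds.select(phase="study"))
n_test = len(ds.select(phase="test"))
print(f"participants: {len(ds.participants)}")
print(f"study trials: {n_study} (48 per participant), test trials: {n_test}")
print(f"faces: {len(ds.layouts)} (32 per race, half mirrored)")
print(f"wrote {out / 'fixations.tsv'} and {out / 'aois.tsv'}")
# Every (race x start position) cell holds the same number of trials, so all
# relative-frequency denominators are fixed by design.
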