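"""Aligned Gaussian fixation-density maps and vertical profile curves.

Fixations 2-5 of each study trial are translated into a common reference
frame (the translation minimizing the summed squared distance between each
face's AOI centers and the population mean centers) and rendered as
unit-mass Gaussians with sd 0.3 degrees.  Summing a map along the horizontal
axis yields the vertical profile: fixation density over facial features from
forehead to chin.
"""

import numpy as np

from gazecontrast import GeneratorParams, generate_dataset
from gazecontrast.density import (
    GridSpec,
    alignment_offsets,
    average_maps,
    difference_map,
    profile,
    render_density,
)
from gazecontrast.model import window_fixations

ds = generate_dataset(GeneratorParams(include_test=False, seed=17))
grid = GridSpec(width=64, height=64, pixel_size=0.25, origin=(-1.5, -0.5))
offsets = alignment_offsets(ds.layouts)

maps = {}
for race in ("caucasian", "chinese"):
    per_participant = []
    for pid in ds.participants:
        trials = ds.select(phase="study", race=race, participant_id=pid)
        fx = [f for t in trials for f in window_fixations(t, "study")]
        dm = render_density(fx, offsets, grid, sigma=0.3)
        dm.values /= len(trials)  # average across trials
        per_participant.append(dm)
    maps[race] = average_maps(per_participant)
    print(
        f"{race:10s} mean map: {maps[race].n_fixations} fixations/participant, "
        f"peak density {maps[race].values.max():.4f} per pixel"
    )

diff = difference_map(maps["caucasian"], maps["chinese"])
y_prof = profile(diff, "y_profile")
peak_row = int(np.argmax(y_prof.values))
peak_deg = grid.y_centers[peak_row]
print(
    f"difference map range: [{diff.values.min():+.4f}, {diff.values.max():+.4f}]"
)
print(
    f"largest own-race surplus in the vertical profile at y = {peak_deg:.1f} deg "
    "(eye region spans roughly y = 4.8-6.4 deg)"
)
# A positive y-profile peak near the eyes says Caucasian faces drew more
# fixation mass there than Chinese faces in this dataset.
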