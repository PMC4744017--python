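"""Monte Carlo permutation statistical maps with FDR correction.

Exchangeability is assumed only between fixations of the same ordinal rank
within a participant: each iteration reshuffles those (location, alignment)
tokens between the two race conditions, rebuilds the group difference map,
and the observed map is ranked against the resampled distribution pixel by
pixel (sign-dependent tails).  Uncorrected maps are thresholded at per-tail
p < 0.01 (two-tailed 0.02); FDR correction at q < 0.05 runs over face-region
pixels only.  Profile p-values reuse the identical resamples after
collapsing each map along one axis.
"""

from gazecontrast import GeneratorParams, generate_dataset
from gazecontrast.density import GridSpec
from gazecontrast.permutation import (
    PermutationConfig,
    build_contrast_tokens,
    face_region_mask,
    fdr_correct,
    permutation_maps,
    threshold_pmap,
)

ds = generate_dataset(GeneratorParams(include_test=False, seed=19))
grid = GridSpec(width=64, height=64, pixel_size=0.25, origin=(-1.5, -0.5))

tokens = build_contrast_tokens(
    ds, {"race": "caucasian"}, {"race": "chinese"}, grid, sigma=0.3
)
print(f"contrast tokens: {tokens.n_tokens} fixations across 30 participants")

maps = permutation_maps(tokens, PermutationConfig(n_iter=2000, seed=19))
pm = maps["map"]

unc = threshold_pmap(pm, per_tail_alpha=0.01)
mask = face_region_mask(grid, ds.layouts)
fdr = fdr_correct(pm, mask, q=0.05)
print(
    f"uncorrected (per-tail p < 0.01, two-tailed "
    f"{unc.threshold['two_tailed_equivalent']}): {int(unc.mask.sum())} pixels"
)
print(f"FDR corrected (q = 0.05, {int(mask.sum())} face pixels): "
      f"{int(fdr.mask.sum())} pixels")

prof = maps["y_profile"]
prof_unc = threshold_pmap(prof, per_tail_alpha=0.025)
prof_fdr = fdr_correct(prof, None, q=0.05)  # profiles use all pixels
print(
    f"vertical profile: {int(prof_unc.mask.sum())} rows at per-tail p < 0.025 "
    f"(two-tailed {prof_unc.threshold['two_tailed_equivalent']}), "
    f"{int(prof_fdr.mask.sum())} after FDR"
)
# The typical outcome mirrors the methodological point: scattered uncorrected
# pixels, an empty FDR map, and occasional surviving profile rows -- subtle
# effects are easier to detect the more the analysis pools data.
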