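"""Extract the region-averaged shoot depths l_near and l_far.

The depth raster is gated to a plausible range, median-smoothed over valid
pixels, and averaged over segmented shoot pixels inside two fixed regions:
the frame centre (l_near) and the left edge (l_far). Masking matters: old
leaves sit ~8 cm deeper and would bias an unmasked mean.
"""

from teaprof import (
    NEAR_REGION, SceneParams, extract_l_values, generate_frame,
    region_mean_depth, segment_shoots,
)

frame, truth = generate_frame(SceneParams(seed=7))
mask = segment_shoots(frame.rgb)
l_near, l_far, info = extract_l_values(frame, mask)

print(f"l_near = {l_near:.3f} cm   (truth {truth.true_l_near:.3f} cm)")
print(f"l_far  = {l_far:.3f} cm   (truth {truth.true_l_far:.3f} cm)")
print(f"fallbacks used: {info['fallback']}")

unmasked = region_mean_depth(frame.depth, None, NEAR_REGION)
print(
    f"unmasked centre-region mean: {unmasked:.3f} cm — deeper than the masked "
    "value because old-leaf pixels drag the average down"
)
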