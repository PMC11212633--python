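"""Fit block edges and the sarcomeric-actin motif on noiseless images.

Blocks (plateaus) get their edges from per-flank sigmoid fits; the
block-with-middle-band motif gets its central band from a Gaussian fit
and its edges from the robust quantile-half-max rule.
"""

import numpy as np

import patternkit as pk

# --- blocks: plateaus 12 px wide, repeated every 25 px --------------------
cfg = pk.SimulationConfig(pattern_kind="blocks", block_width=12.0,
                          snr=float("inf"))
image, truth = pk.simulate_image(cfg)
h, w = image.shape_yx
sel = pk.Selection([(0.0, (h - 1) / 2), (w - 1.0, (h - 1) / 2)], linewidth=7)
profile = pk.extract_profile(image, sel)
res = pk.extract_features(profile, pk.PatternSpec.parse("blocks:1"))
lefts = res.table.positions(0, "block_left_edge")
rights = res.table.positions(0, "block_right_edge")
print("block edges (first 3 repeats), fitted vs true:")
for i in range(3):
    print(f"  left {lefts[i]:7.3f} (true {truth.edges[i, 0]:5.1f})   "
          f"right {rights[i]:7.3f} (true {truth.edges[i, 1]:5.1f})")

# --- actin motif: 16 px block with a brighter central band ----------------
cfg = pk.SimulationConfig(pattern_kind="block_with_middle_band",
                          block_width=16.0, snr=float("inf"))
image, truth = pk.simulate_image(cfg)
profile = pk.extract_profile(image, sel)
res = pk.extract_features(profile, pk.PatternSpec.parse("actin"))
centers = res.pattern_centers[0]
errs = np.sort(centers)[:10] - truth.band_positions
print(f"actin middle-band errors (px): max |err| = {np.abs(errs).max():.4f}")
# both motif families localize to a few hundredths of a pixel without noise
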