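"""Track sarcomere-like patterns through a simulated contracting movie.

A 12-frame movie contracts the band ladder by up to 10% and relaxes
again; each frame is analyzed independently and the pattern centers are
linked into tracks.
"""

import numpy as np

import patternkit as pk

factors = 1.0 - 0.1 * np.sin(np.linspace(0.0, np.pi, 12))
movie, truths = pk.simulate_movie(pk.SimulationConfig(snr=6.0, seed=7), factors)

centers, sel_lengths = {}, {}
for f in range(movie.n_frames):
    frame = pk.ImageData(movie.pixel_array[f][None])
    h, w = frame.shape_yx
    sel = pk.Selection([(0.0, (h - 1) / 2), (w - 1.0, (h - 1) / 2)], linewidth=7)
    prof = pk.extract_profile(frame, sel)
    res = pk.extract_features(prof, pk.PatternSpec.parse("bands:1"))
    centers[f] = res.pattern_centers[0]
    sel_lengths[f] = sel.path_length()

tracks = pk.track_features(centers, sel_lengths)
full = [t for t in tracks.tracks if len(t.frames) == movie.n_frames]
print(f"tracks spanning the whole movie: {len(full)}")

est = []
for f in range(movie.n_frames):
    pos = np.sort([t.positions[t.frames.index(f)] for t in full])
    est.append(np.mean(np.diff(pos)))
true = [t.spacings.mean() for t in truths]
r = np.corrcoef(est, true)[0, 1]
print("frame  est spacing  true spacing")
for f in (0, 3, 6, 9, 11):
    print(f"{f:5d}  {est[f]:10.3f}  {true[f]:11.3f}")
print(f"correlation with the true contraction: r = {r:.4f}")
# the recovered mean spacing follows the imposed contraction almost exactly
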