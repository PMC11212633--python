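# Methods

## The problem

Striated muscle and many other biological structures show regular
one-dimensional patterns: sarcomeres delimited by Z-disks (single bright
bands in fluorescence), myosin blocks, or sarcomeric actin — a block with
a brighter central band. The quantity of interest is the geometry of
these motifs — band positions, block edges, pattern lengths — extracted
with subpixel precision from an intensity profile that the user draws
across the structure on a microscopy image.

## Pipeline

1. **Profile extraction.** The polyline selection is sampled every
   1.0 px of arc length. At each sample the intensity is the mean of
   `linewidth` bilinear samples spaced 1 px apart perpendicular to the
   local path direction. Each channel is then normalized so its minimum
   is 0 and its maximum 1. A constant channel raises an error rather
   than silently returning zeros, to surface dead channels early. For a
   straight selection misaligned by an angle θ from the pattern axis the
   measured lengths are stretched by 1/cos θ, a relative error of
   1/cos θ − 1 (0.38% at 5°) — small enough that hand-drawn selections
   are reliable.

2. **Period estimate.** The mean-subtracted, biased-normalized
   autocorrelation of the profile is computed; lags are skipped until it
   first drops below 0.5 (stepping off the zero-lag shoulder), and the
   first local maximum with positive correlation gives the integer-lag
   period. A Gaussian plus *linear* baseline is least-squares fitted
   over ±`fit_window` lags around it, `fit_window = max(3,
   round(0.25·lag))`. The linear term matters: the neighboring
   correlation peaks leave an asymmetric shoulder under the secondary
   maximum that otherwise biases the center by several hundredths of a
   pixel. At least three repeats of the motif are needed for a usable
   secondary peak.

3. **Segmentation.** A reference window one period wide is centered on
   the profile's global maximum (shifted inward if it would clip). The
   zero-mean reference is cross-correlated against the profile in
   *valid* mode only — zero-padded edges would manufacture artificial
   peaks where the reference slides off the data. The highest peak
   anchors the segmentation; from each accepted peak the next is the
   best local maximum in the window 0.5–1.5 periods away, in both
   directions, which tolerates pattern sizes between 50% and 150% of
   the estimate. Peaks are kept at integer precision here; a monotone
   rise toward a window edge, or a perfectly flat stretch, is not
   accepted as a peak. The period from step 2 stays fixed during
   propagation.

4. **Feature fits.** Within each segment window, per motif family:
   * *bands* — candidate maxima are detected on a 3-point moving
     average (detection only, never fitting; plateau-aware, since ties
     are common in integer count data) and ranked by smoothed height;
     around each of the `n` highest, a Gaussian plus constant offset is
     fitted over ±max(3, period/3) px. The wide sub-window pins the
     offset from the Gaussian wings; with the narrower windows we tried
     first, offset and amplitude are nearly degenerate and the center
     variance grows ~40% above the Cramér–Rao bound. Weights follow the
     shot-noise model — σ ∝ sqrt of the window's min-max-normalized
     intensity plus a 0.05 floor — which also keeps fitted positions
     exactly invariant under affine intensity rescaling. A fit whose
     center escapes its sub-window falls back to the integer maximum
     and is flagged.
   * *blocks* — the window is split at its intensity-weighted center;
     an ascending sigmoid `low + (high−low)/(1+exp(−(x−m)/s))` is
     fitted on the left flank, a descending one on the right. The edge
     is the midpoint parameter `m` (the 50% crossing); any other
     threshold t is `m ± s·ln(t/(1−t))` from the fitted parameters.
   * *block with middle band* — the central band is Gaussian-fitted;
     10 px around it are excluded (a fixed pixel count, deliberately
     not scaled by pixel size); on each side the 90% intensity quantile
     is computed and the edge is the half-quantile crossing nearest the
     center (last upward crossing on the left, first downward on the
     right), linearly interpolated between samples.

   Pattern centers: mean of band centers, mean of block-edge midpoints,
   or the middle-band position. When the motif multiplicity admits more
   than one grouping of features into patterns, the contiguous phase
   minimizing the total within-group spread wins, with brighter features
   preferred toward the group center on exact ties. Per-pattern length
   is the distance between consecutive pattern centers. Failed segments
   are reported with a reason and excluded from length statistics.

5. **Aggregation.** Lengths pool across selections; every pattern
   window is aligned on its center, resampled by linear interpolation
   onto a common grid of `round(mean length) + 1` samples spanning one
   mean length, and averaged per channel with equal weights.

6. **Time lapse.** Keyframe selections are resampled to 100 points by
   arc length; intermediate frames get the per-coordinate linear blend
   of the flanking keyframes. Pattern centers are linked greedily,
   closest first, with a match radius of half the mean pattern size;
   positions and sizes are first divided by the selection length at
   that frame so the radius follows contraction. Unmatched tracks stay
   open for up to 20 frames; unmatched detections open new tracks.
   Per-track normalized length divides by that track's own mean.

## The synthetic validation images

The generator emulates a fluorescence image of a banded structure:
motifs are rendered on an `oversample`-times finer grid (default 8;
impulses and block edges are placed with subpixel accuracy by linear
splatting / partial-pixel coverage), blurred with a Gaussian PSF,
integrated down to the camera pixel (42 nm, typical of a 100×
objective), and corrupted with Poisson noise. Per-band intensity
factors are N(1, `intensity_sd`) and per-band position shifts
N(0, `position_sd`), so intensity and period variation are independent
dials. Defaults mirror the validation conditions: 10 repeats, 25 px
spacing, 15 px image height, PSF σ = 2.5 px (≈105 nm, a diffraction
scale for a high-NA 100× objective).

**Operational SNR definition.** SNR = band peak amplitude divided by
the standard deviation of the Poisson noise at the band-peak intensity,
i.e. A/√(A+B) for amplitude A over baseline B photons. The baseline is
0.5 photons per pixel — the structures sit on a nearly dark background,
as in fluorescence; the small nonzero value keeps background noise
statistics well defined. This calibration matters: with a bright
baseline (e.g. 10 photons) the Cramér–Rao bound on the pattern-size sd
at SNR 6 is already 0.11 px, i.e. no estimator could reach the
precision the pipeline is expected to deliver; with the near-dark
baseline the bound is 0.093 px and the weighted Gaussian fit operates
a few percent above it.

What the generator does **not** emulate: camera read noise, gain and
EMCCD excess noise; structured background and out-of-focus haze;
curvature of real myofibrils; chromatic offsets between channels.
Passing benchmarks on these images therefore demonstrates the
estimator's statistical behavior under shot noise, not robustness to
every artifact of real microscopy.

## Benchmark definitions

A band counts as detected when its greedily matched extraction lies
within 2.36 px (100 nm at 42 nm/px). An image is fully recovered when
every true band is detected; spurious extra detections (e.g. in empty
margins of the selection) do not void recovery but are visible as
unmatched positions. Precision is the mean over fully recovered images
of the sd of the extracted pattern sizes, computed from the matched
bands; its spread is reported as the sd of that quantity. Sweeps use
200 images per condition by default — the binomial sd of a 95%
fraction at n = 200 is 1.5%, adequate for the recovery checks — with
per-image seeds derived from one master seed via `SeedSequence`, so
conditions are reproducible and order-independent.

For the period-estimator comparison, the feature-based "mean spacing"
is the OLS slope of band center versus band index: the naive mean of
consecutive spacings telescopes to the two outermost bands only,
whereas the slope weights every band equally — the property that makes
the feature route beat the refined-autocorrelation route, whose peak is
dominated by the brighter bands, at low SNR.

## Numerical choices and degenerate inputs

* Ties between equal secondary autocorrelation maxima: smaller lag wins.
* Gaussian refinements are bounded so the center stays inside its
  window; on failure the integer-precision location is used and logged.
* Cross-correlation search windows with no interior local maximum stop
  propagation (no extrapolated peaks).
* Profiles shorter than one period, constant profiles, aperiodic
  profiles and empty poolings raise typed errors
  (`patternkit.errors`); per-image failures inside sweeps count as
  non-recovery instead of aborting the sweep.
* Rolling-ball background correction (for light-background EM-style
  images) runs the ball on the gray-inverted image — equivalent to
  ImageJ's "light background" mode with smoothing disabled — and
  returns the inverted, background-free result directly; default
  radius 50 px.
* ImageJ `.roi`/`.zip` import handles line, polyline and freehand-line
  types (with subpixel coordinates when present); other ROI types are
  skipped with a warning. Bit-exact agreement with ImageJ's own
  linewidth-averaging kernel is not promised: the perpendicular
  averaging here uses `linewidth` equally spaced offsets with bilinear
  interpolation.

## Known limitations

* Segmentation runs on one driving channel (the actin-motif channel if
  present, else channel 0); all channels share its segment windows.
* The tracker is greedy per frame, not a global assignment; crossing
  patterns can swap identities.
* Absolute recovery fractions at very low SNR (≤ 1) depend strongly on
  the photon budget, which is an operational choice here; they should
  be read as indicative curves, not calibrated constants.
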