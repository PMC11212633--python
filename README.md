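# patternkit

Subpixel geometry of regular one-dimensional patterns in microscopy
images.

Many biological structures are periodic: striated muscle shows
sarcomeres delimited by Z-disk bands, myosin blocks, and sarcomeric
actin — a block with a brighter central band. `patternkit` extracts the
geometry of such motifs from intensity profiles drawn across an image:
it estimates the spatial period from the first secondary peak of the
profile's autocorrelation, segments the profile into repeats by
cross-correlation against an automatically chosen reference pattern,
and localizes features inside each repeat with subpixel precision —
band centers by Gaussian fits, block edges by sigmoid fits, and the
actin motif by a Gaussian center plus quantile-half-max edges. It also
interpolates selections across time-lapse frames and tracks patterns
over time, and ships a synthetic-image generator (Gaussian PSF +
Poisson noise) that the benchmark uses to validate the whole pipeline
against known ground truth.

Intended users: microscopists quantifying sarcomere lengths (or any
1D-periodic structure) from fluorescence, EM or brightfield images, in
Python scripts or from the shell.

## The core quantities

For a profile I(x) sampled every pixel along a selection:

* period estimate: lag of the first secondary maximum of the
  autocorrelation r(ℓ), refined by fitting
  a·exp(−(ℓ−ℓ₀)²/2σ²) + b + c·(ℓ−ℓ₀) around it and reporting ℓ₀;
* band position: center μ of a fitted a·exp(−(x−μ)²/2s²) + b inside a
  segment, with shot-noise weights;
* block edge: midpoint m of a fitted sigmoid
  low + (high−low)/(1 + e^∓(x−m)/s) (the 50% crossing; other
  thresholds t follow as m ± s·ln(t/(1−t)));
* pattern length: distance between consecutive pattern centers (mean
  of band centers, mean of edge midpoints, or the middle band);
* a selection misaligned by θ degrees inflates lengths by
  1/cos θ − 1 (0.38% at 5°).

## Worked example

`python examples/extract_band_ladder.py` simulates a 10-band ladder
(25 px spacing) at SNR 3, extracts a linewidth-7 profile and fits every
band:

```
estimated period      : 24.974 px (true 25.000)
bands detected        : 10/10 (within the 2.36 px tolerance)
per-band error (px)   : -0.093 +0.027 -0.206 -0.154 -0.189 -0.006 -0.021 -0.056 +0.169 +0.159
mean pattern length   : 25.028 px
```

Every band lands within ~0.2 px of its true position at an SNR where
the bands are barely visible by eye. The other examples cover block and
actin motifs (`blocks_and_actin_motifs.py`), averaging patterns across
selections (`average_pattern.py`), tracking a contracting movie
(`timelapse_tracking.py`) and the recovery/precision benchmark
(`benchmark_recovery_vs_snr.py`).

The same pipeline is scriptable from the shell:

```
patternkit simulate --snr 8 --seed 4 --out sim/
patternkit extract --image sim/simulated.tif --selections sel.json \
    --pattern bands:1 --out results/
patternkit analyze --image sim/simulated.tif --selections sel.json \
    --pattern bands:1 --out results/ --histogram
```

Selections come from JSON files or ImageJ `.roi`/`.zip` files; features
and lengths are written as CSV, summaries as JSON, average patterns as
TIFF.

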