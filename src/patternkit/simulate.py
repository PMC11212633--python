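"""Synthetic microscopy images of regular 1D patterns with known truth.

The generator emulates a fluorescence image of a banded structure as a
real microscope would record it: features are rendered on an oversampled
grid, blurred with a Gaussian point-spread function to simulate
diffraction, integrated down to the camera pixel size (42 nm, a typical
100x objective), and corrupted with Poisson (shot) noise.  Per-band
intensity factors and per-band position shifts are both drawn from
normal distributions, so intensity variation and period variation can
be dialed independently.

SNR definition used throughout the package: band peak amplitude divided
by the standard deviation of the Poisson noise at the band-peak
intensity, i.e. ``A / sqrt(A + B)`` for amplitude ``A`` photons over a
background of ``B`` photons.  Given a target SNR the amplitude is solved
from that relation, so the realized noise level matches the target by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ParameterError
from .profiles import ImageData

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_image",
    "simulate_movie",
    "classify_period_variation",
]

# Baseline photon level per final pixel.  The simulated structures sit on a
# nearly dark background, as fluorescence ladders do; the small nonzero
# baseline keeps background noise statistics well defined.
BACKGROUND_PHOTONS = 0.5


@dataclass
class SimulationConfig:
    """Parameters of one synthetic image.

    snr=inf (or any non-finite value) disables noise entirely.
    ``motif`` geometry (used for kinds other than "bands"): block_width
    in final pixels; the actin motif adds a central band of relative
    amplitude ``band_boost`` on top of the block.
    """

    n_repeats: int = 10
    spacing: float = 25.0
    pattern_kind: str = "bands"  # bands | blocks | block_with_middle_band
    snr: float = 8.0
    intensity_sd: float = 0.0  # sd of per-band intensity factors (mean 1)
    position_sd: float = 0.0  # sd of per-band position shifts, px
    psf_sigma: float = 2.5  # Gaussian PSF sd, final pixels
    oversample: int = 8
    pixel_size_nm: float = 42.0
    seed: int = 0
    image_height: int = 15
    margin: float = 20.0  # px of empty image on each side
    block_width: float = 12.0
    band_boost: float = 1.0  # actin motif: extra central-band amplitude

    def __post_init__(self):
        if self.snr <= 0:
            raise ParameterError("snr must be > 0")
        if self.intensity_sd < 0 or self.position_sd < 0:
            raise ParameterError("sd parameters must be >= 0")
        if self.oversample < 4:
            raise ParameterError("oversample must be >= 4")
        if self.pattern_kind != "bands" and self.block_width >= self.spacing:
            raise ParameterError("motif wider than spacing")


@dataclass
class GroundTruth:
    """True feature geometry of one simulated frame, final-pixel units."""

    band_positions: np.ndarray  # pattern centers (band or motif centers)
    edges: np.ndarray | None = None  # (n, 2) block edges if applicable
    intensity_factors: np.ndarray | None = None

    @property
    def spacings(self) -> np.ndarray:
        return np.diff(self.band_positions)


def classify_period_variation(truth: GroundTruth) -> float:
    """Percent spread of spacings: 100 * (max - min) / mean.

    This is the classification used to bin images by how irregular the
    pattern is (difference between the closest and furthest band pair).
    """
    if truth.band_positions.size < 3:
        raise ParameterError("need >= 3 bands to classify period variation")
    s = truth.spacings
    return float(100.0 * (s.max() - s.min()) / s.mean())


def _render_row(config: SimulationConfig, rng: np.random.Generator):
    """Noiseless unit-amplitude 1D motif profile + truth, final pixels."""
    os_ = config.oversample
    n = config.n_repeats
    width_px = 2 * config.margin + (n - 1) * config.spacing
    n_final = int(np.ceil(width_px)) + 1
    n_over = n_final * os_

    centers = config.margin + config.spacing * np.arange(n)
    if config.position_sd > 0:
        centers = centers + rng.normal(0.0, config.position_sd, size=n)
        centers = np.sort(centers)
    factors = np.ones(n)
    if config.intensity_sd > 0:
        factors = rng.normal(1.0, config.intensity_sd, size=n)
        factors = np.clip(factors, 0.05, None)

    over = np.zeros(n_over)
    # final-pixel coordinate p maps to oversampled index (p + 0.5)*os - 0.5
    def to_over(p):
        return (np.asarray(p) + 0.5) * os_ - 0.5

    def splat_impulse(pos, amp):
        # linear splat between neighboring oversampled pixels keeps the
        # center of mass exactly at the requested subpixel position
        u = to_over(pos)
        i0 = int(np.floor(u))
        w = u - i0
        if 0 <= i0 < n_over:
            over[i0] += amp * (1 - w)
        if 0 <= i0 + 1 < n_over:
            over[i0 + 1] += amp * w

    def splat_block(l, r, amp):
        lo_u, hi_u = to_over(l), to_over(r)
        for i in range(max(0, int(np.floor(lo_u))), min(n_over, int(np.ceil(hi_u)) + 1)):
            overlap = min(hi_u, i + 0.5) - max(lo_u, i - 0.5)
            if overlap > 0:
                over[i] += amp * min(overlap, 1.0)

    edges = None
    if config.pattern_kind == "bands":
        for c, f in zip(centers, factors):
            splat_impulse(c, f * os_)
    else:
        half = config.block_width / 2.0
        edges = np.stack([centers - half, centers + half], axis=1)
        for (l, r), f in zip(edges, factors):
            splat_block(l, r, f)
        if config.pattern_kind == "block_with_middle_band":
            for c, f in zip(centers, factors):
                splat_impulse(c, f * config.band_boost * os_)

    # diffraction blur on the oversampled grid
    from scipy.ndimage import gaussian_filter1d

    over = gaussian_filter1d(over, sigma=config.psf_sigma * os_, mode="constant")
    # integrate down to camera pixels (photon-conserving)
    row = over.reshape(n_final, os_).sum(axis=1)
    truth = GroundTruth(
        band_positions=centers, edges=edges, intensity_factors=factors
    )
    return row, truth


def _amplitude_for_snr(snr: float, background: float) -> float:
    # solve A / sqrt(A + B) = snr  ->  A = (snr^2 + snr*sqrt(snr^2 + 4B)) / 2
    return 0.5 * (snr**2 + snr * np.sqrt(snr**2 + 4.0 * background))


def simulate_image(config: SimulationConfig) -> tuple[ImageData, GroundTruth]:
    """Render one noisy single-channel frame plus its ground truth.

    Deterministic given ``config.seed``; identical configs give
    bit-identical images.
    """
    rng = np.random.default_rng(config.seed)
    row, truth = _render_row(config, rng)
    peak = float(row.max())
    if peak <= 0:
        raise ParameterError("motif rendered empty; check geometry")
    noiseless = not np.isfinite(config.snr)
    if noiseless:
        img_row = row / peak + 0.0
        frame = np.tile(img_row, (config.image_height, 1))
    else:
        amp = _amplitude_for_snr(config.snr, BACKGROUND_PHOTONS)
        expected = BACKGROUND_PHOTONS + row * (amp / peak)
        frame = rng.poisson(
            np.tile(expected, (config.image_height, 1))
        ).astype(float)
    return ImageData(frame[None, None]), truth


def simulate_movie(
    config: SimulationConfig, contraction: Sequence[float]
) -> tuple[ImageData, list[GroundTruth]]:
    """Time series of ladders whose spacing scales with ``contraction``.

    Frame t uses ``spacing * contraction[t]``; frames share the jitter
    pattern drawn once from the seed so motion is smooth, and each frame
    receives independent noise.
    """
    factors = np.asarray(contraction, dtype=float)
    if np.any(factors <= 0):
        raise ParameterError("contraction factors must be > 0")
    frames, truths = [], []
    width = None
    for t, f in enumerate(factors):
        cfg = replace(config, spacing=config.spacing * f, seed=config.seed + 7919 * t)
        img, truth = simulate_image(cfg)
        plane = img.pixel_array[0, 0]
        if width is None:
            width = int(np.ceil(2 * config.margin + (config.n_repeats - 1)
                                * config.spacing * factors.max())) + 1
        padded = np.zeros((config.image_height, width))
        w = min(width, plane.shape[1])
        padded[:, :w] = plane[:, :w]
        if not np.isfinite(config.snr):
            pass
        else:
            # keep background photons outside the rendered area
            padded[:, w:] = np.random.default_rng(
                config.seed + 7919 * t + 1
            ).poisson(BACKGROUND_PHOTONS, size=(config.image_height, width - w))
        frames.append(padded)
        truths.append(truth)
    stack = np.stack(frames)[:, None]
    return ImageData(stack), truths
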