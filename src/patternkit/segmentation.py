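"""Segmentation of a profile into pattern repeats by cross-correlation.

A reference window one period wide, centered on the brightest point of
the profile, is cross-correlated against the whole profile.  The highest
cross-correlation peak anchors the segmentation; further repeats are
found by propagating a search window half a period to one-and-a-half
periods away from each accepted peak, in both directions.  This windowed
search tolerates pattern-size variation between 50% and 150% of the
estimated period.  Peaks are kept at integer precision here — subpixel
localization happens later, inside each segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate

from .errors import SegmentationError, TooFewPatternsError
from .profiles import IntensityProfile

__all__ = ["PatternSegment", "SegmentationResult", "pick_reference", "segment_profile"]


@dataclass
class PatternSegment:
    center: float  # position along the profile, pixels
    left: int
    right: int
    index: int


@dataclass
class SegmentationResult:
    segments: list[PatternSegment]
    reference: tuple[int, int]
    period_used: float
    channel_used: int

    def centers(self) -> np.ndarray:
        return np.asarray([s.center for s in self.segments], dtype=float)


def _as_channel(profile, channel: int) -> np.ndarray:
    if isinstance(profile, IntensityProfile):
        return profile.channel(channel)
    return np.asarray(profile, dtype=float)


def pick_reference(
    profile: IntensityProfile | np.ndarray, channel: int, period: float
) -> tuple[int, int]:
    """Reference window: one period wide, centered on the global maximum.

    If the maximum sits within half a period of a profile end, the window
    is shifted inward so it keeps its full width.
    """
    x = _as_channel(profile, channel)
    n = x.size
    width = int(round(period))
    if n < width:
        raise SegmentationError("profile shorter than one period")
    center = int(np.argmax(x))
    left = center - width // 2
    left = max(0, min(left, n - width))
    return left, left + width


def _local_maxima_in(xc: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indices in [lo, hi] that are local maxima of the full xc array."""
    lo = max(1, lo)
    hi = min(xc.size - 2, hi)
    if hi < lo:
        return np.empty(0, dtype=int)
    idx = np.arange(lo, hi + 1)
    # plateau maxima count, but perfectly flat stretches and the masked
    # (edge) region do not
    mask = (
        np.isfinite(xc[idx])
        & np.isfinite(xc[idx - 1])
        & np.isfinite(xc[idx + 1])
        & (xc[idx] >= xc[idx - 1])
        & (xc[idx] >= xc[idx + 1])
        & ((xc[idx] > xc[idx - 1]) | (xc[idx] > xc[idx + 1]))
    )
    return idx[mask]


def segment_profile(
    profile: IntensityProfile | np.ndarray,
    channel: int,
    period: float,
) -> SegmentationResult:
    """Segment a profile into repeats of the estimated period.

    A monotone rise toward a search-window edge is not accepted as a
    peak (conservative stop at profile ends).
    """
    x = _as_channel(profile, channel)
    n = x.size
    if period <= 4:
        raise SegmentationError("period must exceed 4 px for segmentation")
    ref_left, ref_right = pick_reference(x, 0, period)
    ref = x[ref_left:ref_right].astype(float)
    ref = ref - ref.mean()
    # Edge-value padding before valid-mode correlation: zero padding would
    # put a step under the sliding reference and manufacture artificial
    # peaks at the profile ends; continuing the edge value keeps the
    # correlation flat over flat margins while bands at the very ends of
    # the profile remain findable.
    w = ref.size
    lpad = w // 2
    xp = np.pad(x, (lpad, w - 1 - lpad), mode="edge") - x.mean()
    xc = correlate(xp, ref, mode="valid")
    assert xc.size == n

    anchor_candidates = _local_maxima_in(xc, 0, n - 1)
    if anchor_candidates.size == 0:
        raise TooFewPatternsError("cross-correlation has no interior maximum")
    anchor = int(anchor_candidates[np.argmax(xc[anchor_candidates])])

    # floor for accepting propagated peaks: genuine repeats correlate at a
    # sizable fraction of the anchor, while maxima riding on band tails or
    # numerical dust sit orders of magnitude below it
    floor = 0.02 * xc[anchor]

    accepted = [anchor]
    for direction in (+1, -1):
        prev = anchor
        while True:
            if direction > 0:
                lo = int(np.ceil(prev + 0.5 * period))
                hi = int(np.floor(prev + 1.5 * period))
            else:
                lo = int(np.ceil(prev - 1.5 * period))
                hi = int(np.floor(prev - 0.5 * period))
            if lo >= n or hi < 0:
                break
            cands = _local_maxima_in(xc, lo, hi)
            cands = cands[xc[cands] > max(floor, 0.0)]
            if cands.size == 0:
                break
            peak = int(cands[np.argmax(xc[cands])])
            accepted.append(peak)
            prev = peak

    centers = sorted(set(accepted))
    if len(centers) < 2:
        raise TooFewPatternsError("fewer than two pattern repeats found")
    half = period / 2.0
    segments = [
        PatternSegment(
            center=float(c),
            left=int(max(0, round(c - half))),
            right=int(min(n - 1, round(c + half))),
            index=i,
        )
        for i, c in enumerate(centers)
    ]
    return SegmentationResult(
        segments=segments,
        reference=(ref_left, ref_right),
        period_used=float(period),
        channel_used=channel,
    )
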