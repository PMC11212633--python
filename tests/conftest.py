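"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from patternkit.profiles import ImageData, IntensityProfile, Selection


def gaussian_bumps(length: int, centers, sigma: float = 2.5, amps=None,
                   offset: float = 0.05) -> np.ndarray:
    """Analytic 1D profile of Gaussian bands at known subpixel centers."""
    x = np.arange(length, dtype=float)
    amps = np.ones(len(centers)) if amps is None else np.asarray(amps, float)
    y = np.full(length, offset)
    for c, a in zip(centers, amps):
        y += a * np.exp(-0.5 * ((x - c) / sigma) ** 2)
    return y


def as_profile(values: np.ndarray) -> IntensityProfile:
    v = np.asarray(values, dtype=float)
    v = (v - v.min()) / (v.max() - v.min())
    return IntensityProfile(
        positions=np.arange(v.size, dtype=float),
        intensities=v[None, :],
        normalization=[(0.0, 1.0)],
    )


def ladder_image(n_bands: int = 10, spacing: float = 25.0, height: int = 15,
                 sigma: float = 2.5, margin: float = 20.0) -> tuple[ImageData, np.ndarray]:
    """Deterministic band-ladder image with exactly known band columns."""
    centers = margin + spacing * np.arange(n_bands)
    width = int(np.ceil(centers[-1] + margin)) + 1
    row = gaussian_bumps(width, centers, sigma=sigma, offset=0.0)
    img = np.tile(row, (height, 1))
    return ImageData(img[None, None]), centers


@pytest.fixture
def noiseless_ladder():
    return ladder_image()


def midline_selection(image: ImageData, linewidth: int = 1) -> Selection:
    h, w = image.shape_yx
    return Selection([(0.0, (h - 1) / 2), (w - 1.0, (h - 1) / 2)],
                     linewidth=linewidth)


# ---------------------------------------------------------------------------
# ImageJ ROI byte writers (the binary files are built in memory at test time)

def imagej_line_roi(x1, y1, x2, y2, stroke_width=0) -> bytes:
    buf = bytearray(64)
    buf[0:4] = b"Iout"
    struct.pack_into(">h", buf, 4, 228)
    buf[6] = 3  # line
    struct.pack_into(">4h", buf, 8, int(min(y1, y2)), int(min(x1, x2)),
                     int(max(y1, y2)), int(max(x1, x2)))
    struct.pack_into(">4f", buf, 18, x1, y1, x2, y2)
    struct.pack_into(">h", buf, 34, stroke_width)
    return bytes(buf)


def imagej_polyline_roi(points, stroke_width=0) -> bytes:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    left, top = int(min(xs)), int(min(ys))
    n = len(points)
    buf = bytearray(64 + 4 * n)
    buf[0:4] = b"Iout"
    struct.pack_into(">h", buf, 4, 228)
    buf[6] = 5  # polyline
    struct.pack_into(">4h", buf, 8, top, left, int(max(ys)), int(max(xs)))
    struct.pack_into(">h", buf, 16, n)
    struct.pack_into(">h", buf, 34, stroke_width)
    for i, (x, y) in enumerate(points):
        struct.pack_into(">h", buf, 64 + 2 * i, int(round(x)) - left)
        struct.pack_into(">h", buf, 64 + 2 * n + 2 * i, int(round(y)) - top)
    return bytes(buf)


def imagej_rect_roi(left, top, right, bottom) -> bytes:
    buf = bytearray(64)
    buf[0:4] = b"Iout"
    struct.pack_into(">h", buf, 4, 228)
    buf[6] = 1  # rectangle
    struct.pack_into(">4h", buf, 8, top, left, bottom, right)
    return bytes(buf)
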