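"""Images, line selections and normalized intensity profiles.

This module turns a multi-channel microscopy image plus a user polyline
("selection") into a 1D intensity profile sampled every pixel of path
length, averaging perpendicular to the path over the selection's
linewidth.  Profiles are normalized per channel so the minimum is 0 and
the maximum 1, which makes channels directly comparable.

Coordinate conventions: 0-based, pixel centers at integer coordinates,
``x`` along columns and ``y`` along rows.  Positions along a profile are
subpixel floats in pixel units with a fixed sampling step of 1.0.
"""

from __future__ import annotations

import json
import logging
import math
import struct
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage
from skimage.restoration import rolling_ball

from .errors import (
    BoundsError,
    DegenerateProfileError,
    EmptyResultError,
    FormatError,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ImageData",
    "Selection",
    "IntensityProfile",
    "load_image",
    "subtract_background_em",
    "extract_profile",
    "angular_length_error",
    "import_imagej_rois",
    "save_selections",
    "load_selections",
    "profile_to_csv",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImageData:
    """Image stack indexed ``(frame, channel, row, col)``.

    ``pixel_size`` is the physical length of one pixel (any unit the
    caller likes, e.g. nm); it is optional and only used to convert
    reported lengths.
    """

    pixel_array: np.ndarray
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixel_array, dtype=float)
        if arr.ndim != 4:
            raise FormatError(
                f"pixel_array must be 4D (frame, channel, row, col); got {arr.ndim}D"
            )
        if not np.all(np.isfinite(arr)):
            raise FormatError("image contains non-finite values")
        if np.any(arr < 0):
            raise FormatError("image contains negative intensities")
        self.pixel_array = arr

    @property
    def n_frames(self) -> int:
        return self.pixel_array.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixel_array.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixel_array.shape[2:]


@dataclass
class Selection:
    """A polyline drawn on the image with an averaging linewidth.

    vertices : ordered ``(x, y)`` subpixel coordinates (>= 2)
    linewidth : width in pixels perpendicular to the path over which
        intensities are averaged (>= 1)
    frame : 0-based frame index the selection applies to
    """

    vertices: Sequence[tuple[float, float]]
    linewidth: int = 1
    frame: int = 0
    label: str = "selection"

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 2:
            raise ParameterError("selection needs >= 2 (x, y) vertices")
        if self.path_length() <= 0:
            raise ParameterError("selection path length must be > 0")
        if int(self.linewidth) < 1:
            raise ParameterError("linewidth must be >= 1")
        self.linewidth = int(self.linewidth)

    def vertex_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def path_length(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))

    def to_dict(self) -> dict:
        return {
            "vertices": [[float(x), float(y)] for x, y in self.vertices],
            "linewidth": self.linewidth,
            "frame": self.frame,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Selection":
        return cls(
            vertices=[tuple(p) for p in d["vertices"]],
            linewidth=d.get("linewidth", 1),
            frame=d.get("frame", 0),
            label=d.get("label", "selection"),
        )


@dataclass
class IntensityProfile:
    """Per-channel normalized intensities sampled along a selection.

    positions : sample positions along the path, spacing 1.0 px
    intensities : array ``(n_channels, n_samples)``, each channel in [0, 1]
    normalization : per-channel ``(raw_min, raw_max)`` used to normalize
    """

    positions: np.ndarray
    intensities: np.ndarray
    source: Selection | None = None
    normalization: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    def __len__(self) -> int:
        return self.positions.size

    def channel(self, c: int) -> np.ndarray:
        return self.intensities[c]


# ---------------------------------------------------------------------------
# image loading


_FRAME_AXES = set("TZIQ")
_CHANNEL_AXES = set("CS")


def _normalize_axes(arr: np.ndarray, axes: str) -> np.ndarray:
    """Reorder a tifffile array with axis string ``axes`` to (T, C, Y, X)."""
    if arr.ndim == 2:
        return arr[None, None]
    axes = axes.upper()
    if len(axes) != arr.ndim or "Y" not in axes or "X" not in axes:
        raise FormatError(f"unsupported TIFF axis layout {axes!r}")
    frame_dims = [i for i, a in enumerate(axes) if a in _FRAME_AXES]
    chan_dims = [i for i, a in enumerate(axes) if a in _CHANNEL_AXES]
    spatial = [axes.index("Y"), axes.index("X")]
    known = set(frame_dims) | set(chan_dims) | set(spatial)
    if known != set(range(arr.ndim)):
        extra = "".join(axes[i] for i in range(arr.ndim) if i not in known)
        raise FormatError(f"unsupported TIFF axes {extra!r} in layout {axes!r}")
    arr = np.transpose(arr, frame_dims + chan_dims + spatial)
    n_frames = int(np.prod([arr.shape[i] for i in range(len(frame_dims))], dtype=int)) or 1
    n_chan = int(
        np.prod([arr.shape[len(frame_dims) + i] for i in range(len(chan_dims))], dtype=int)
    ) or 1
    return arr.reshape(n_frames, n_chan, *arr.shape[-2:])


def load_image(
    path: str | Path,
    invert: bool = False,
    blur_sigma: float = 0.0,
    pixel_size: float | None = None,
) -> ImageData:
    """Load a TIFF into an :class:`ImageData`, with optional preprocessing.

    ``invert`` replaces each channel's values ``v`` by ``max(v) - v`` —
    useful for electron-microscopy-like images where the features of
    interest are dark.  ``blur_sigma > 0`` applies an isotropic Gaussian
    blur of that sigma (pixels) per channel and frame, which can rescue
    very low-SNR images at a small resolution cost.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            series = tif.series[0]
            arr = series.asarray()
            axes = series.axes
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    arr = _normalize_axes(np.asarray(arr), axes)
    arr = arr.astype(float)
    if invert:
        for f in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                arr[f, c] = arr[f, c].max() - arr[f, c]
    if blur_sigma < 0:
        raise ParameterError("blur_sigma must be >= 0")
    if blur_sigma > 0:
        for f in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                arr[f, c] = ndimage.gaussian_filter(
                    arr[f, c], sigma=blur_sigma, mode="reflect"
                )
    return ImageData(arr, pixel_size=pixel_size)


def subtract_background_em(image: ImageData, radius: int = 50) -> ImageData:
    """Rolling-ball background removal for light-background (EM-style) images.

    The ball runs on the gray-inverted image (equivalent to ImageJ's
    "light background" mode, smoothing disabled), so electron-dense dark
    features come out bright in the returned image — no separate LUT
    inversion step is needed.
    """
    if radius <= 0:
        raise ParameterError("rolling-ball radius must be > 0")
    if image.n_channels != 1:
        raise ParameterError("background subtraction expects a single-channel image")
    out = np.empty_like(image.pixel_array)
    for f in range(image.n_frames):
        plane = image.pixel_array[f, 0]
        inv = plane.max() - plane  # light background -> dark background
        bg = rolling_ball(inv, radius=radius)
        out[f, 0] = np.clip(inv - bg, 0.0, None)
    return ImageData(out, pixel_size=image.pixel_size)


# ---------------------------------------------------------------------------
# profile extraction


def _sample_path(vertices: np.ndarray, step: float = 1.0):
    """Sample a polyline every ``step`` of arc length.

    Returns (points (n,2), tangents (n,2) unit vectors, positions (n,)).
    """
    seg = np.diff(vertices, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    starts = vertices[:-1][keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    positions = np.arange(0.0, total + 1e-9, step)
    idx = np.clip(np.searchsorted(cum, positions, side="right") - 1, 0, len(seg_len) - 1)
    frac = (positions - cum[idx]) / seg_len[idx]
    points = starts[idx] + seg[idx] * frac[:, None]
    tangents = seg[idx] / seg_len[idx, None]
    return points, tangents, positions


def normalize_channel(values: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Scale so min -> 0 and max -> 1; idempotent on already-normalized data."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        raise DegenerateProfileError(
            "constant profile: min == max, normalization undefined"
        )
    return (values - lo) / (hi - lo), (lo, hi)


def extract_profile(
    image: ImageData,
    selection: Selection,
    channel: int | None = None,
    normalize: bool = True,
) -> IntensityProfile:
    """Sample the image along a selection into a normalized profile.

    The path is sampled every 1.0 px of arc length.  At each sample the
    intensity is the mean of ``linewidth`` bilinear samples spaced 1 px
    apart perpendicular to the local path direction, centered on the path.
    ``channel=None`` extracts all channels (sharing the same geometry).
    """
    frame = selection.frame
    if not (0 <= frame < image.n_frames):
        raise BoundsError(f"frame {frame} outside image with {image.n_frames} frames")
    channels = range(image.n_channels) if channel is None else [channel]
    points, tangents, positions = _sample_path(selection.vertex_array())
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    w = selection.linewidth
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0
    # coords: (n_offsets, n_samples, 2) in (x, y)
    coords = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    rows, cols = image.shape_yx
    xs, ys = coords[..., 0], coords[..., 1]
    if xs.min() < 0 or ys.min() < 0 or xs.max() > cols - 1 or ys.max() > rows - 1:
        raise BoundsError(
            "selection (with linewidth) extends outside the image bounds"
        )
    stacked = []
    norms: list[tuple[float, float]] = []
    for c in channels:
        plane = image.pixel_array[frame, c]
        samples = ndimage.map_coordinates(
            plane, [ys.ravel(), xs.ravel()], order=1, mode="nearest"
        ).reshape(xs.shape)
        prof = samples.mean(axis=0)
        if normalize:
            prof, (lo, hi) = normalize_channel(prof)
        else:
            lo, hi = float(prof.min()), float(prof.max())
        stacked.append(prof)
        norms.append((lo, hi))
    return IntensityProfile(
        positions=positions,
        intensities=np.asarray(stacked),
        source=selection,
        normalization=norms,
    )


def angular_length_error(theta_degrees: float) -> float:
    """Relative length error from a selection misaligned by ``theta`` degrees.

    A straight selection at angle theta to the pattern axis measures path
    lengths stretched by 1/cos(theta); the relative error is
    ``1/cos(theta) - 1`` (0.38% at 5 degrees).
    """
    if not 0 <= theta_degrees < 90:
        raise ParameterError("theta must be in [0, 90) degrees")
    return 1.0 / math.cos(math.radians(theta_degrees)) - 1.0


# ---------------------------------------------------------------------------
# ImageJ ROI import

_ROI_LINE = 3
_ROI_FREELINE = 4
_ROI_POLYLINE = 5
_OPT_SUBPIXEL = 128


def _parse_roi_bytes(data: bytes, label: str) -> Selection | None:
    """Decode one ImageJ ``.roi`` blob; None for non-line ROI types."""
    if len(data) < 64 or data[:4] != b"Iout":
        raise FormatError(f"{label}: not an ImageJ ROI file")
    roi_type = data[6]
    top, left, bottom, right = struct.unpack(">4h", data[8:16])
    n_coords = struct.unpack(">h", data[16:18])[0]
    stroke_width = struct.unpack(">h", data[34:36])[0]
    options = struct.unpack(">h", data[50:52])[0]
    linewidth = max(1, stroke_width)
    if roi_type == _ROI_LINE:
        x1, y1, x2, y2 = struct.unpack(">4f", data[18:34])
        verts = [(x1, y1), (x2, y2)]
    elif roi_type in (_ROI_POLYLINE, _ROI_FREELINE):
        if n_coords < 2:
            return None
        base = 64
        xs = struct.unpack(f">{n_coords}h", data[base : base + 2 * n_coords])
        ys = struct.unpack(
            f">{n_coords}h", data[base + 2 * n_coords : base + 4 * n_coords]
        )
        if options & _OPT_SUBPIXEL and len(data) >= base + 8 * n_coords:
            fbase = base + 4 * n_coords
            fx = struct.unpack(f">{n_coords}f", data[fbase : fbase + 4 * n_coords])
            fy = struct.unpack(
                f">{n_coords}f", data[fbase + 4 * n_coords : fbase + 8 * n_coords]
            )
            verts = list(zip(fx, fy))
        else:
            verts = [(left + x, top + y) for x, y in zip(xs, ys)]
    else:
        logger.warning("skipping non-line ROI %r (type %d)", label, roi_type)
        return None
    return Selection(vertices=verts, linewidth=linewidth, label=label)


def import_imagej_rois(path: str | Path) -> list[Selection]:
    """Read line-type ROIs from an ImageJ ``.roi`` file or ``.zip`` of ROIs.

    Non-line ROI types (rectangles, ovals, points, ...) are skipped with
    a warning; an input containing no line-type ROI raises
    :class:`EmptyResultError`.
    """
    path = Path(path)
    selections: list[Selection] = []
    if zipfile.is_zipfile(path):
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                sel = _parse_roi_bytes(zf.read(name), Path(name).stem)
                if sel is not None:
                    selections.append(sel)
    else:
        sel = _parse_roi_bytes(path.read_bytes(), path.stem)
        if sel is not None:
            selections.append(sel)
    if not selections:
        raise EmptyResultError(f"no line-type ROI found in {path}")
    return selections


# ---------------------------------------------------------------------------
# plain-text I/O


def save_selections(selections: Sequence[Selection], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([s.to_dict() for s in selections], indent=1) + "\n"
    )


def load_selections(path: str | Path) -> list[Selection]:
    data = json.loads(Path(path).read_text())
    return [Selection.from_dict(d) for d in data]


def profile_to_csv(profile: IntensityProfile, path: str | Path) -> None:
    import pandas as pd

    cols = {"position_px": profile.positions}
    for c in range(profile.n_channels):
        cols[f"channel_{c}"] = profile.intensities[c]
    pd.DataFrame(cols).to_csv(path, index=False)
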