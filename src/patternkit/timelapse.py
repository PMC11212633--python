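"""Time-lapse support: selection interpolation and pattern tracking.

A user draws selections ("keyframes") at a few frames of a movie; every
intermediate frame receives a selection whose 100 resampled coordinates
are the per-coordinate linear blend of the flanking keyframes.  After
per-frame feature extraction, each pattern's reference position (its
canonical center) is linked frame-to-frame by greedy nearest-neighbor
matching: the search radius is half a pattern size, all positions being
first rescaled by the selection length at that frame so that the radius
tracks contraction and stretching.  A track missing its match is kept
open for up to 20 frames before it is closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .profiles import Selection

__all__ = [
    "N_INTERP_POINTS",
    "MAX_GAP_FRAMES",
    "SelectionKeyframes",
    "Track",
    "TrackSet",
    "resample_polyline",
    "interpolate_selections",
    "track_features",
]

N_INTERP_POINTS = 100
MAX_GAP_FRAMES = 20


def resample_polyline(vertices: np.ndarray, n_points: int = N_INTERP_POINTS) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced by arc length."""
    v = np.asarray(vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    targets = np.linspace(0.0, cum[-1], n_points)
    xs = np.interp(targets, cum, v[:, 0])
    ys = np.interp(targets, cum, v[:, 1])
    return np.stack([xs, ys], axis=1)


@dataclass
class SelectionKeyframes:
    """User-drawn keyframe selections plus the generated in-betweens."""

    keyframes: dict[int, Selection]
    generated: dict[int, Selection] = field(default_factory=dict)

    def all_frames(self) -> dict[int, Selection]:
        return {**self.generated, **self.keyframes}


def interpolate_selections(keyframes: SelectionKeyframes) -> dict[int, Selection]:
    """Fill every frame between consecutive keyframes.

    Each keyframe polyline is resampled to 100 points; frame ``i+k``
    between keyframes ``i`` and ``j`` gets coordinates
    ``((j-i-k)*P_i + k*P_j) / (j-i)``, x and y independently.
    """
    if len(keyframes.keyframes) < 2:
        raise ParameterError("need at least 2 keyframes to interpolate")
    frames = sorted(keyframes.keyframes)
    resampled = {
        f: resample_polyline(keyframes.keyframes[f].vertex_array()) for f in frames
    }
    out: dict[int, Selection] = {}
    for f in frames:
        src = keyframes.keyframes[f]
        out[f] = Selection(
            [tuple(p) for p in resampled[f]],
            linewidth=src.linewidth, frame=f, label=src.label,
        )
    for a, b in zip(frames[:-1], frames[1:]):
        pa, pb = resampled[a], resampled[b]
        lw = keyframes.keyframes[a].linewidth
        label = keyframes.keyframes[a].label
        for k in range(1, b - a):
            blend = ((b - a - k) * pa + k * pb) / (b - a)
            sel = Selection([tuple(p) for p in blend], linewidth=lw,
                            frame=a + k, label=label)
            out[a + k] = sel
            keyframes.generated[a + k] = sel
    return out


@dataclass
class Track:
    track_id: int
    frames: list[int] = field(default_factory=list)
    positions: list[float] = field(default_factory=list)  # px along the profile
    lengths: list[float] = field(default_factory=list)  # local pattern length

    def normalized_lengths(self) -> np.ndarray:
        """Length series divided by this track's own mean (1 = track average)."""
        arr = np.asarray(self.lengths, dtype=float)
        valid = arr[np.isfinite(arr)]
        if valid.size == 0:
            return arr
        return arr / valid.mean()


@dataclass
class TrackSet:
    tracks: list[Track]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            for f, p, ln in zip(t.frames, t.positions, t.lengths):
                rows.append(
                    {"track_id": t.track_id, "frame": f,
                     "position_px": p, "length_px": ln}
                )
        return pd.DataFrame(rows)


def _local_lengths(centers: np.ndarray) -> np.ndarray:
    """Per-pattern length from neighboring centers (mean of flanking gaps)."""
    if centers.size < 2:
        return np.full(centers.size, np.nan)
    gaps = np.diff(centers)
    out = np.empty(centers.size)
    out[0], out[-1] = gaps[0], gaps[-1]
    if centers.size > 2:
        out[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
    return out


def track_features(
    centers_per_frame: dict[int, np.ndarray],
    selection_lengths: dict[int, float] | None = None,
    max_gap: int = MAX_GAP_FRAMES,
) -> TrackSet:
    """Link per-frame pattern centers into tracks.

    ``centers_per_frame`` maps frame index to sorted reference positions
    (px along the profile); ``selection_lengths`` gives the selection
    path length per frame, used to rescale positions so the match radius
    follows global contraction (defaults to 1 everywhere).  Matching is
    greedy closest-first with radius = half the mean normalized pattern
    size at the current frame; a track unmatched for more than
    ``max_gap`` frames closes; unmatched detections open new tracks.
    """
    if not centers_per_frame:
        raise ParameterError("no detections to track")
    frames = sorted(centers_per_frame)
    scale = {f: (selection_lengths or {}).get(f, 1.0) for f in frames}
    if any(s <= 0 for s in scale.values()):
        raise ParameterError("selection lengths must be > 0")

    tracks: list[Track] = []
    open_tracks: list[dict] = []  # {track, last_frame, norm_pos}
    next_id = 0
    for f in frames:
        centers = np.asarray(centers_per_frame[f], dtype=float)
        order = np.argsort(centers)
        centers = centers[order]
        lengths = _local_lengths(centers)
        s = scale[f]
        norm_centers = centers / s
        norm_lengths = lengths / s
        mean_size = np.nanmean(norm_lengths) if np.any(np.isfinite(norm_lengths)) else np.inf
        radius = 0.5 * mean_size

        open_tracks = [t for t in open_tracks if f - t["last_frame"] <= max_gap]
        # greedy closest-first assignment
        pairs = []
        for ti, t in enumerate(open_tracks):
            for di, nc in enumerate(norm_centers):
                d = abs(nc - t["norm_pos"])
                if d <= radius:
                    pairs.append((d, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for d, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            t = open_tracks[ti]
            t["track"].frames.append(f)
            t["track"].positions.append(float(centers[di]))
            t["track"].lengths.append(float(lengths[di]))
            t["last_frame"] = f
            t["norm_pos"] = float(norm_centers[di])
        for di, nc in enumerate(norm_centers):
            if di in used_d:
                continue
            tr = Track(next_id, [f], [float(centers[di])], [float(lengths[di])])
            next_id += 1
            tracks.append(tr)
            open_tracks.append({"track": tr, "last_frame": f, "norm_pos": float(nc)})
    tracks.sort(key=lambda t: t.track_id)
    return TrackSet(tracks)
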