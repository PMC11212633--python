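"""Pooling of extraction results and average-pattern construction.

Lengths from many selections/images are pooled into one distribution;
every non-failed pattern window is aligned on its canonical center,
resampled to a common grid by linear interpolation and averaged per
channel, giving the average motif profile and a rendered average image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .errors import EmptyResultError
from .features import ExtractionResult
from .profiles import IntensityProfile

__all__ = ["AnalysisSummary", "pool_and_summarize", "render_average_image"]


@dataclass
class AnalysisSummary:
    lengths: pd.DataFrame  # columns: source, pattern_index, length_px
    mean_length: float
    sd_length: float
    n: int
    average_profile: np.ndarray  # (n_channels, grid_size)
    grid: np.ndarray  # positions relative to the pattern center

    def to_json_dict(self) -> dict:
        return {
            "mean_length_px": self.mean_length,
            "sd_length_px": self.sd_length,
            "n_patterns": self.n,
            "per_source": {
                str(k): {
                    "n": int(g.shape[0]),
                    "mean_length_px": float(g["length_px"].mean()),
                }
                for k, g in self.lengths.groupby("source")
            },
        }


def pool_and_summarize(
    results: list[tuple[ExtractionResult, IntensityProfile]],
) -> AnalysisSummary:
    """Pool per-pattern lengths and build the average aligned profile.

    Each extraction result contributes its per-pattern lengths and, for
    averaging, each consecutive-center window of its profile aligned on
    the midpoint between centers.  The common grid spans one mean length
    centered on the canonical pattern center, with ``round(mean)+1``
    samples.
    """
    rows = []
    for res, _prof in results:
        label = res.table.rows[0].selection_label if res.table.rows else "selection"
        for i, ln in enumerate(res.lengths):
            rows.append({"source": label, "pattern_index": i, "length_px": float(ln)})
    if not rows:
        raise EmptyResultError("no valid patterns to pool")
    lengths = pd.DataFrame(rows)
    mean_len = float(lengths["length_px"].mean())
    sd_len = float(lengths["length_px"].std(ddof=1)) if len(rows) > 1 else 0.0

    grid_size = int(round(mean_len)) + 1
    grid = np.linspace(-mean_len / 2.0, mean_len / 2.0, grid_size)
    sums = None
    count = 0
    for res, prof in results:
        centers = res.pattern_centers[res.driving_channel]
        for center in centers:
            lo, hi = center - mean_len / 2.0, center + mean_len / 2.0
            if lo < prof.positions[0] or hi > prof.positions[-1]:
                continue
            sample_at = center + grid
            block = np.stack(
                [
                    np.interp(sample_at, prof.positions, prof.intensities[c])
                    for c in range(prof.n_channels)
                ]
            )
            sums = block if sums is None else sums + block
            count += 1
    if sums is None:
        raise EmptyResultError("no pattern window fits inside its profile")
    return AnalysisSummary(
        lengths=lengths,
        mean_length=mean_len,
        sd_length=sd_len,
        n=len(rows),
        average_profile=sums / count,
        grid=grid,
    )


def render_average_image(
    summary: AnalysisSummary, height: int = 20, path=None
) -> np.ndarray:
    """Replicate the average profile over ``height`` rows per channel.

    Returns a ``(channels, height, width)`` array; writes a TIFF when
    ``path`` is given.
    """
    img = np.repeat(
        summary.average_profile[:, None, :], height, axis=1
    ).astype(np.float32)
    if path is not None:
        tifffile.imwrite(path, img)
    return img
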