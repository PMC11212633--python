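"""Spatial-period estimation from the autocorrelation secondary peak.

The period of a repeating motif is first bracketed at integer-lag
resolution by the first secondary maximum of the profile's
autocorrelation, then refined to subpixel precision by least-squares
fitting a Gaussian to the correlation values around that maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelmax

from .errors import DegenerateProfileError, NoPeriodError
from .profiles import IntensityProfile

logger = logging.getLogger(__name__)

__all__ = ["PeriodEstimate", "autocorrelate", "estimate_period"]

# Lags are skipped until the autocorrelation first drops below this value,
# to step off the zero-lag peak and its shoulder before searching for the
# first secondary maximum.
SHOULDER_LEVEL = 0.5


@dataclass
class PeriodEstimate:
    period: float  # pixels, subpixel
    peak_lag_int: int  # integer lag of the located secondary maximum
    fit_window: int  # half-width (lags) of the Gaussian refinement window
    method: str = "autocorrelation_gaussian"


def autocorrelate(profile: IntensityProfile | np.ndarray, channel: int = 0) -> np.ndarray:
    """Mean-subtracted, biased-normalized autocorrelation.

    Returns values for integer lags 0 .. n-2, with r(0) == 1.  Biased
    normalization (divide by n, then by the variance) keeps large-lag
    values bounded and naturally down-weights lags with little overlap.
    """
    x = np.asarray(profile.channel(channel) if isinstance(profile, IntensityProfile) else profile, dtype=float)
    n = x.size
    if n < 4:
        raise NoPeriodError("profile too short for autocorrelation (need >= 4 samples)")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        raise DegenerateProfileError("constant profile has no autocorrelation")
    full = np.correlate(x, x, mode="full")
    return full[n - 1 : 2 * n - 2] / denom


def _gaussian(x, amp, center, sigma, offset, tilt=0.0):
    # the linear term absorbs the asymmetric shoulder the neighboring
    # correlation peaks leave under the secondary maximum
    return offset + tilt * (x - center) + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def estimate_period(
    profile: IntensityProfile | np.ndarray, channel: int = 0
) -> PeriodEstimate:
    """Estimate the motif period, in pixels, from one profile channel.

    The first local maximum of the autocorrelation past the zero-lag
    shoulder (and with positive correlation) gives the integer-lag
    estimate; a Gaussian fitted over +/- ``fit_window`` lags around it
    gives the subpixel period.  The profile should contain at least
    three repeats of the motif for the secondary peak to be well formed.
    """
    r = autocorrelate(profile, channel)
    n = r.size
    # step off the zero-lag peak: skip until r first drops below the shoulder
    below = np.nonzero(r < SHOULDER_LEVEL)[0]
    if below.size == 0:
        raise NoPeriodError("autocorrelation never leaves the zero-lag shoulder")
    start = max(2, int(below[0]))
    maxima = argrelmax(r)[0]
    maxima = maxima[(maxima >= start) & (r[maxima] > 0)]
    if maxima.size == 0:
        raise NoPeriodError("no secondary autocorrelation maximum: aperiodic input")
    # equal-height tie -> smaller lag (argrelmax returns sorted lags; take first)
    lag = int(maxima[0])
    fit_window = max(3, round(0.25 * lag))
    lo, hi = max(1, lag - fit_window), min(n - 1, lag + fit_window + 1)
    xs = np.arange(lo, hi, dtype=float)
    ys = r[lo:hi]
    try:
        popt, _ = curve_fit(
            _gaussian,
            xs,
            ys,
            p0=[r[lag], float(lag), fit_window / 2.0, 0.0, 0.0],
            bounds=(
                [0.0, float(lo), 0.1, -1.0, -1.0],
                [np.inf, float(hi - 1), float(4 * fit_window), 1.0, 1.0],
            ),
            maxfev=5000,
        )
        center = float(popt[1])
        if not (lo <= center <= hi - 1):
            raise RuntimeError("fitted center escaped the window")
    except RuntimeError:
        logger.warning("Gaussian refinement failed at lag %d; using integer lag", lag)
        center = float(lag)
    return PeriodEstimate(period=center, peak_lag_int=lag, fit_window=fit_window)
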