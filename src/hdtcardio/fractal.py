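"""Short-term detrended fluctuation analysis of the N-N interval series.

DFA1: integrate the mean-removed series, partition the profile into
non-overlapping boxes of n beats, remove a first-order (linear) trend inside
each box, and measure the root-mean-square residual F(n).  The short-term
scaling exponent alpha1 is the least-squares slope of log F(n) against log n
over box sizes 4..16 beats (the canonical upper bound for the short-term
exponent; the lower bound 4 keeps linear detrending non-degenerate).

alpha1 is ~0.5 for uncorrelated interval fluctuations, ~1.0 for 1/f dynamics
and ~1.5 for Brownian (integrated-noise) dynamics; in resting humans it rises
with sympathovagal balance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSeriesError, InsufficientDataError


@dataclass
class DfaResult:
    alpha1: float
    box_sizes: np.ndarray
    fluctuations: np.ndarray  # F(n), same units as the input series
    fit_residual: float  # RMS residual of the log-log regression


def dfa1(
    nn_ms: np.ndarray,
    box_range: tuple[int, int] = (4, 16),
    min_beats: int = 300,
) -> DfaResult:
    """Compute the short-term scaling exponent of a beat-by-beat series."""
    x = np.asarray(nn_ms, dtype=float)
    if x.size < min_beats:
        raise InsufficientDataError(
            f"DFA needs >= {min_beats} beats, got {x.size}"
        )
    if np.std(x) == 0:
        raise DegenerateSeriesError("zero-variance series: scaling undefined")
    y = np.cumsum(x - x.mean())
    sizes = np.arange(box_range[0], box_range[1] + 1)
    F = np.empty(sizes.size)
    for j, n in enumerate(sizes):
        nb = y.size // n  # trailing partial box discarded
        seg = y[: nb * n].reshape(nb, n)
        t = np.arange(n, dtype=float)
        # least-squares linear detrend of every box at once
        t0 = t - t.mean()
        slope = seg @ t0 / (t0 @ t0)
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * t0
        F[j] = np.sqrt(np.mean(resid**2))
    logn, logF = np.log(sizes), np.log(F)
    slope, intercept = np.polyfit(logn, logF, 1)
    rms = float(np.sqrt(np.mean((logF - (slope * logn + intercept)) ** 2)))
    return DfaResult(alpha1=float(slope), box_sizes=sizes, fluctuations=F, fit_residual=rms)
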