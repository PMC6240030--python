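"""Normalized cross-correlation between ECoG channels.

Uses the classic "coeff" normalization: the raw cross-correlation is
scaled so that the zero-lag autocorrelation of either trace equals 1,
bounding every coefficient in [-1, 1].  The lag sign convention is
*positive lag = first-named channel leads* (i.e. the second trace looks
like a delayed copy of the first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .exceptions import ChannelQualityError, CsdScopeError
from .recording import EPI_FILTER, Recording
from .filters import apply_filter

#: the three channel combinations reported for generalized activity
PAIRS = (("M1_left", "S1_left"), ("M1_left", "M1_right"),
         ("S1_left", "M1_right"))


@dataclass
class Correlogram:
    lags_s: np.ndarray
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        if self.lags_s.size != self.coeffs.size or self.lags_s.size == 0:
            raise ValueError("lag grid and coefficients must match and be non-empty")


@dataclass
class XcorrResult:
    pair: tuple[str, str]
    max_coeff: float
    lag_s: float
    correlogram: Correlogram | None = None

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "max_coeff": self.max_coeff,
                "lag_s": self.lag_s}


def xcorr_coeff(x: np.ndarray, y: np.ndarray, fs: float,
                max_lag_s: float = 2.0) -> Correlogram:
    """Coefficient-normalized cross-correlation on a signed lag grid.

    ``coeffs[k]`` is ``sum_n x[n] y[n + lag]`` of the mean-removed traces,
    scaled by the geometric mean of the two zero-lag autocorrelations; a
    positive-lag peak means x leads y.  Mean removal makes the
    coefficients invariant under per-channel gain and offset (the traces
    this is applied to are high-passed and essentially zero-mean anyway).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("traces must have equal length")
    if max_lag_s >= x.size / fs:
        raise ValueError("max_lag_s must be shorter than the traces")
    x = x - x.mean()
    y = y - y.mean()
    ex, ey = float(np.dot(x, x)), float(np.dot(y, y))
    if ex <= 0 or ey <= 0:
        raise ChannelQualityError("zero-variance input: correlation undefined")
    full = scipy.signal.correlate(y, x, mode="full", method="fft")
    mid = x.size - 1
    m = int(round(max_lag_s * fs))
    coeffs = full[mid - m: mid + m + 1] / np.sqrt(ex * ey)
    lags = np.arange(-m, m + 1) / fs
    return Correlogram(lags_s=lags, coeffs=coeffs)


def max_xcorr(cg: Correlogram) -> tuple[float, float]:
    """Peak coefficient (signed extremum of largest magnitude) and its lag.

    An inverted copy of a trace therefore peaks at -1.0 rather than being
    missed.  Ties are broken toward the smallest absolute lag, then toward
    the negative lag.
    """
    mag = np.abs(cg.coeffs)
    best = mag.max()
    idx = np.flatnonzero(mag == best)
    lags = cg.lags_s[idx]
    order = np.lexsort((lags, np.abs(lags)))
    i = idx[order[0]]
    return float(cg.coeffs[i]), float(cg.lags_s[i])


def pairwise_xcorr(rec: Recording, window: tuple[float, float] | None = None,
                   max_lag_s: float = 2.0,
                   prefiltered: bool = False) -> list[XcorrResult]:
    """Cross-correlate the three channel combinations.

    Traces are conditioned with the epileptiform chain (0.5 Hz HP,
    100 Hz LP) unless ``prefiltered``; the analysis window defaults to the
    terminal 10 minutes, where activity is strongest.  A flat channel
    raises :class:`ChannelQualityError` — a dead electrode excludes the
    animal from the paired-channel analyses.
    """
    T = rec.duration_s
    if window is None:
        window = (max(T - 600.0, 0.0), T)
    i0 = int(round(window[0] * rec.fs))
    i1 = int(round(window[1] * rec.fs))
    traces = {}
    for role in ("M1_left", "S1_left", "M1_right"):
        tr = rec.channel(role)
        tr = tr if prefiltered else apply_filter(tr, rec.fs, EPI_FILTER)
        seg = tr[i0:i1]
        if np.ptp(seg) <= 0 or seg.std() == 0:
            raise ChannelQualityError(
                f"channel {role} is flat in the analysis window; "
                "subject should be excluded")
        traces[role] = seg
    out = []
    for a, b in PAIRS:
        cg = xcorr_coeff(traces[a], traces[b], rec.fs, max_lag_s)
        coeff, lag = max_xcorr(cg)
        out.append(XcorrResult(pair=(a, b), max_coeff=coeff, lag_s=lag,
                               correlogram=cg))
    return out
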