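"""Classical early-warning-signal indicators.

Six indicators computed over rolling windows: lag-1 autocorrelation (AR1),
standard deviation (STD), skewness (S), kurtosis (K, Pearson convention:
a Gaussian scores 3), the detrended-fluctuation-analysis exponent (DFA)
and spectral reddening (FR, the ratio of mean periodogram power in the
lowest to the highest 20% of nonzero frequencies).  Rising AR1, STD and
FR, and a DFA exponent drifting above 0.5, are the canonical statistical
signatures of critical slowing down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy import stats as _stats

from .errors import ConstantSeriesError

__all__ = [
    "EWSTrace",
    "ar1",
    "std",
    "skewness",
    "kurtosis",
    "dfa_exponent",
    "spectral_reddening",
    "rolling_ews",
]

INDICATORS = ("AR1", "STD", "S", "K", "DFA", "FR")


def _check_variance(x: np.ndarray) -> None:
    if np.ptp(x) == 0:
        raise ConstantSeriesError("constant series")


def ar1(x) -> float:
    """Lag-1 Pearson autocorrelation, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    _check_variance(x)
    r = np.corrcoef(x[:-1], x[1:])[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def std(x) -> float:
    """Population standard deviation."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    return float(np.std(x))


def skewness(x) -> float:
    """Third standardized moment."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    _check_variance(x)
    return float(_stats.skew(x, bias=True))


def kurtosis(x) -> float:
    """Fourth standardized moment, Pearson convention (Gaussian -> 3)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    _check_variance(x)
    return float(_stats.kurtosis(x, fisher=False, bias=True))


def dfa_exponent(x, min_box: int = 10, n_boxes: int = 12, order: int = 1) -> float:
    """Detrended-fluctuation-analysis scaling exponent.

    The cumulative-sum profile of the mean-removed series is split into
    non-overlapping boxes of log-spaced sizes in ``[min_box, n // 4]``;
    within each box an order-``order`` polynomial trend is removed and the
    RMS residual computed.  The exponent is the slope of the log-log
    regression of RMS fluctuation against box size (0.5 for white noise,
    1.5 for its cumulative sum).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 observations for DFA")
    _check_variance(x)
    profile = np.cumsum(x - x.mean())
    sizes = np.unique(
        np.round(np.geomspace(min_box, n // 4, n_boxes)).astype(int)
    )
    fluct = np.empty(len(sizes))
    t = np.arange(n)
    for k, s in enumerate(sizes):
        n_seg = n // s
        seg = profile[: n_seg * s].reshape(n_seg, s)
        tt = t[:s]
        coeffs = np.polynomial.polynomial.polyfit(tt, seg.T, order)
        trend = np.polynomial.polynomial.polyval(tt, coeffs)
        fluct[k] = np.sqrt(np.mean((seg - trend) ** 2))
    slope = np.polyfit(np.log(sizes), np.log(fluct), 1)[0]
    return float(slope)


def spectral_reddening(x, band_fraction: float = 0.2) -> float:
    """Low-frequency to high-frequency periodogram power ratio.

    Mean power over the lowest ``band_fraction`` of nonzero frequencies
    divided by the mean power over the highest ``band_fraction``; a flat
    (white) spectrum scores about 1, reddened spectra score above it.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise ValueError("need at least 64 observations")
    freqs, power = _signal.periodogram(x, detrend="constant")
    power = power[freqs > 0]
    k = max(1, int(band_fraction * len(power)))
    high = float(np.mean(power[-k:]))
    if high == 0.0:
        raise ConstantSeriesError("zero high-band power")
    return float(np.mean(power[:k]) / high)


@dataclass
class EWSTrace:
    """Indicator values per rolling window.

    ``values[name]`` is one sequence per indicator; all sequences share
    the length of ``window_end``.  Windows in which an indicator was
    undefined (e.g. constant data) hold NaN and carry a note in ``flags``.
    """

    window_end: np.ndarray
    values: dict[str, np.ndarray]
    window: int
    detrend: bool
    flags: list[str | None]


def rolling_ews(
    x,
    window: int | None = None,
    step: int = 10,
    detrend: bool = True,
) -> EWSTrace:
    """Evaluate all six indicators on rolling windows of a series.

    ``window`` defaults to half the series length.  ``detrend`` removes
    the within-window mean before computing the indicators.  The windows
    may traverse time within one series or, equally, a parameter sweep
    recorded as a series -- the function is agnostic.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window is None:
        window = n // 2
    if not 4 <= window <= n:
        raise ValueError("window must be between 4 and the series length")
    if step < 1:
        raise ValueError("step must be positive")

    starts = range(0, n - window + 1, step)
    out = {name: np.full(len(starts), np.nan) for name in INDICATORS}
    ends = np.empty(len(starts), dtype=int)
    flags: list[str | None] = [None] * len(starts)
    funcs = {
        "AR1": ar1, "STD": std, "S": skewness, "K": kurtosis,
        "DFA": dfa_exponent, "FR": spectral_reddening,
    }
    for w, start in enumerate(starts):
        chunk = x[start : start + window]
        if detrend:
            chunk = chunk - chunk.mean()
        ends[w] = start + window
        notes = []
        for name, fn in funcs.items():
            try:
                out[name][w] = fn(chunk)
            except (ConstantSeriesError, ValueError) as exc:
                notes.append(f"{name}: {exc}")
        flags[w] = "; ".join(notes) if notes else None
    return EWSTrace(window_end=ends, values=out, window=window,
                    detrend=detrend, flags=flags)
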