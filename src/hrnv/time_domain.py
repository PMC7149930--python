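"""Time-domain and geometric HRV/HRnV parameters.

All functions accept either a raw :class:`~hrnv.series.RRSeries` or a
composite :class:`~hrnv.series.DerivedRRSeries`; values are in the units of
the input intervals (milliseconds throughout this package).

The HRnV-specific pair NN50n / pNN50n uses the scaled threshold ``50 * n``
ms on composite sequences (a composite interval aggregates n beats, so the
conventional 50 ms criterion is scaled with the window width); on the raw
sequence (n = 1) they coincide with NN50 / pNN50 and are reported as absent.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

__all__ = [
    "mean_nn",
    "sdnn",
    "rmssd",
    "nn50_family",
    "skewness",
    "kurtosis",
    "triangular_index",
    "time_domain_params",
]


def _values(seq) -> np.ndarray:
    return np.asarray(getattr(seq, "intervals", seq), dtype=float)


def mean_nn(seq) -> float:
    """Arithmetic mean of the (composite) NN intervals, ms."""
    x = _values(seq)
    if x.size == 0:
        raise ValueError("empty sequence")
    return float(np.mean(x))


def sdnn(seq, *, sample: bool = True) -> float:
    """Standard deviation of the intervals, ms (sample convention by default)."""
    x = _values(seq)
    if x.size < 2:
        raise ValueError("need at least 2 elements")
    return float(np.std(x, ddof=1 if sample else 0))


def rmssd(seq) -> float:
    """Root mean square of successive interval differences, ms."""
    x = _values(seq)
    if x.size < 2:
        raise ValueError("need at least 2 elements")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def nn50_family(seq, n: int = 1, *, denominator: str = "intervals"):
    """NN50, pNN50 and their threshold-scaled counterparts NN50n, pNN50n.

    NN50 counts successive differences whose absolute value *exceeds* 50 ms
    (strict inequality); NN50n uses the threshold ``50 * n`` ms.  pNN50 is
    NN50 as a percentage of the element count (``denominator="intervals"``)
    or of the number of successive pairs (``denominator="pairs"``).

    Returns ``(nn50, pnn50, nn50n, pnn50n)``; the last two are ``None`` for
    n = 1 where the scaled threshold is not distinct.
    """
    x = _values(seq)
    if x.size < 2:
        raise ValueError("need at least 2 elements")
    if denominator == "intervals":
        denom = x.size
    elif denominator == "pairs":
        denom = x.size - 1
    else:
        raise ValueError("denominator must be 'intervals' or 'pairs'")
    absd = np.abs(np.diff(x))
    nn50 = int(np.sum(absd > 50.0))
    pnn50 = 100.0 * nn50 / denom
    if n == 1:
        return nn50, pnn50, None, None
    nn50n = int(np.sum(absd > 50.0 * n))
    pnn50n = 100.0 * nn50n / denom
    return nn50, pnn50, nn50n, pnn50n


def skewness(seq) -> float:
    """Third standardized central moment (population normalisation)."""
    x = _values(seq)
    if x.size < 3:
        raise ValueError("need at least 3 elements")
    sd = np.std(x)
    if sd == 0:
        warnings.warn("zero variance: skewness undefined", stacklevel=2)
        return math.nan
    return float(np.mean(((x - np.mean(x)) / sd) ** 3))


def kurtosis(seq, *, excess: bool = False) -> float:
    """Fourth standardized central moment; Pearson convention (normal -> 3)
    unless ``excess`` is requested (normal -> 0)."""
    x = _values(seq)
    if x.size < 3:
        raise ValueError("need at least 3 elements")
    sd = np.std(x)
    if sd == 0:
        warnings.warn("zero variance: kurtosis undefined", stacklevel=2)
        return math.nan
    k = float(np.mean(((x - np.mean(x)) / sd) ** 4))
    return k - 3.0 if excess else k


def triangular_index(seq, bin_width: float = 1000.0 / 128.0) -> float:
    """HRV triangular index: element count / modal bin height of the interval
    histogram, with bins aligned to multiples of ``bin_width`` (7.8125 ms by
    convention).
    """
    x = _values(seq)
    if x.size < 2:
        raise ValueError("need at least 2 elements")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(x / bin_width).astype(np.int64)
    _, counts = np.unique(idx, return_counts=True)
    return float(x.size / counts.max())


def time_domain_params(seq, n: int = 1, *, sample_sd: bool = True,
                       excess_kurtosis: bool = False,
                       pnn50_denominator: str = "intervals",
                       tri_bin_width: float = 1000.0 / 128.0) -> dict:
    """The full time-domain row: Mean NN, SDNN, RMSSD, skewness, kurtosis,
    triangular index and the NN50 family, keyed by parameter label."""
    nn50, pnn50, nn50n, pnn50n = nn50_family(seq, n, denominator=pnn50_denominator)
    out = {
        "mean_nn": mean_nn(seq),
        "sdnn": sdnn(seq, sample=sample_sd),
        "rmssd": rmssd(seq),
        "skewness": skewness(seq),
        "kurtosis": kurtosis(seq, excess=excess_kurtosis),
        "triangular_index": triangular_index(seq, tri_bin_width),
        "nn50": nn50,
        "pnn50": pnn50,
    }
    if n > 1:
        out["nn50n"] = nn50n
        out["pnn50n"] = pnn50n
    return out
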