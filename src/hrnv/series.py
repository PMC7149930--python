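"""RR-interval series and the HRnV composite-interval constructions.

Heart rate n-variability (HRnV) generalises conventional HRV by computing
the usual parameter panel not on the raw normal-to-normal (NN) interval
sequence but on composite intervals, each the sum of ``n`` adjacent NN
intervals.  Two families exist:

* ``RRnI`` — non-overlapping windows (stride ``n``); parameter set HR{n}V.
* ``RRnIm`` — sliding windows of width ``n`` and stride ``m < n`` so that
  consecutive composites share ``n - m`` constituent intervals; parameter
  set HR{n}V{m}.

With ``n = 1`` the construction reduces to conventional HRV, and with
``m = n`` the overlapped family reduces to the non-overlapping one, so a
single sweep over ``1 <= m <= n <= n_max`` enumerates every distinct
sequence exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RRSeries",
    "DerivedRRSeries",
    "HRnVConfig",
    "build_rrni",
    "build_rrnim",
    "enumerate_sequences",
    "sequence_label",
    "n_sequences",
]


class SequenceTooShortError(ValueError):
    """Raised when a construction would yield fewer than two composite intervals."""


def _as_interval_array(intervals) -> np.ndarray:
    arr = np.asarray(intervals, dtype=float)
    if arr.ndim != 1:
        raise ValueError("intervals must be one-dimensional")
    if arr.size and not np.all(arr > 0):
        raise ValueError("all intervals must be positive")
    return arr


@dataclass(frozen=True)
class RRSeries:
    """A sequence of normal-to-normal R-R intervals in milliseconds.

    ``t_end[i]`` is the cumulative time at which interval ``i`` ends,
    i.e. ``sum(intervals[: i + 1])``; it anchors every derived composite
    interval on the real time axis so spectral analysis of the unevenly
    sampled sequence is well defined.
    """

    intervals: np.ndarray
    source_id: str = ""
    t_end: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = _as_interval_array(self.intervals)
        object.__setattr__(self, "intervals", arr)
        if self.t_end is None:
            object.__setattr__(self, "t_end", np.cumsum(arr))
        else:
            t = np.asarray(self.t_end, dtype=float)
            if t.shape != arr.shape:
                raise ValueError("t_end must match intervals in length")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError("t_end must be strictly increasing")
            object.__setattr__(self, "t_end", t)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class DerivedRRSeries:
    """An RRnI / RRnIm composite-interval sequence tagged with ``(n, m)``.

    Each element is the exact sum of ``n`` consecutive parent intervals;
    ``t_end`` carries the parent end-time of each window's last beat.
    """

    n: int
    m: int
    intervals: np.ndarray
    t_end: np.ndarray
    label: str
    source_id: str = ""

    def __post_init__(self):
        if self.n < 1 or not (1 <= self.m <= self.n):
            raise ValueError("require 1 <= m <= n")
        object.__setattr__(self, "intervals", np.asarray(self.intervals, dtype=float))
        object.__setattr__(self, "t_end", np.asarray(self.t_end, dtype=float))

    def __len__(self) -> int:
        return int(self.intervals.size)


def sequence_label(n: int, m: int) -> str:
    """Canonical name: ``HRV`` for n=1, ``HR{n}V`` for m=n, else ``HR{n}V{m}``."""
    if n == 1:
        return "HRV"
    if m == n:
        return f"HR{n}V"
    return f"HR{n}V{m}"


@dataclass
class HRnVConfig:
    """Analysis configuration shared across the parameter panel.

    Parameters
    ----------
    n_max:
        Upper limit N of the window width n.  Must be small relative to the
        number of available intervals; a warning is issued when
        ``n_max > len(series) / 10``.
    vlf_band, lf_band, hf_band:
        Half-open frequency bands (Hz], conventional cut-offs 0–0.04,
        0.04–0.15 and 0.15–0.4 Hz.  Band edges are *not* rescaled with n.
    embedding_dim, tolerance_frac:
        ApEn/SampEn template length m and tolerance r as a fraction of the
        SD of the sequence under analysis.
    dfa_scales_short, dfa_scales_long:
        Box-size ranges (in beats) for the short- and long-range DFA slopes.
    tri_bin_width_ms:
        Histogram bin width for the triangular index (1/128 s by default).
    sample_sd:
        Use the sample (n-1) variance convention for SDNN/SD1/SD2 when True,
        population (n) otherwise.
    pnn50_denominator:
        ``"intervals"`` divides NN50 by the element count, ``"pairs"`` by the
        number of successive differences.
    excess_kurtosis:
        Report excess kurtosis (normal -> 0) instead of Pearson (normal -> 3).
    """

    n_max: int = 3
    vlf_band: tuple[float, float] = (0.0, 0.04)
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    embedding_dim: int = 2
    tolerance_frac: float = 0.2
    dfa_scales_short: tuple[int, int] = (4, 16)
    dfa_scales_long: tuple[int, int] = (16, 64)
    tri_bin_width_ms: float = 1000.0 / 128.0
    sample_sd: bool = True
    pnn50_denominator: str = "intervals"
    excess_kurtosis: bool = False

    def __post_init__(self):
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        edges = [*self.vlf_band, self.lf_band[1], self.hf_band[1]]
        if not all(b > a for a, b in zip(edges, edges[1:])):
            raise ValueError("band edges must be strictly increasing")
        if self.pnn50_denominator not in ("intervals", "pairs"):
            raise ValueError("pnn50_denominator must be 'intervals' or 'pairs'")

    def validate_for(self, series: RRSeries) -> None:
        if self.n_max > len(series):
            raise ValueError(f"n_max={self.n_max} exceeds series length {len(series)}")
        if self.n_max > len(series) / 10:
            warnings.warn(
                f"n_max={self.n_max} is large relative to series length "
                f"{len(series)}; composite sequences will be very short",
                stacklevel=2,
            )


def build_rrnim(parent: RRSeries, n: int, m: int) -> DerivedRRSeries:
    """Construct the RRnIm sequence: windows of ``n`` adjacent intervals, stride ``m``.

    Element ``k`` is the exact sum of parent intervals ``[k*m, k*m + n)``;
    the number of elements is ``floor((N - n) / m) + 1``.  Trailing intervals
    that do not fill a complete window are dropped.  ``m = n`` is accepted as
    an alias of the non-overlapping RRnI construction.
    """
    N = len(parent)
    if n < 1 or n > N:
        raise ValueError(f"n={n} out of range for series of length {N}")
    if not (1 <= m <= n):
        raise ValueError(f"require 1 <= m <= n, got m={m}, n={n}")
    count = (N - n) // m + 1
    if count < 2:
        raise SequenceTooShortError(
            f"RRnIm(n={n}, m={m}) on {N} intervals yields {count} element(s); need >= 2"
        )
    starts = np.arange(count) * m
    # direct window sums (not cumsum differences): n = 1 reproduces the
    # parent bit-for-bit and every composite is an exact sum of constituents
    windows = np.lib.stride_tricks.sliding_window_view(parent.intervals, n)[::m]
    composite = windows.sum(axis=1)
    t_end = parent.t_end[starts + n - 1]
    return DerivedRRSeries(
        n=n,
        m=m,
        intervals=composite,
        t_end=t_end,
        label=sequence_label(n, m),
        source_id=parent.source_id,
    )


def build_rrni(parent: RRSeries, n: int) -> DerivedRRSeries:
    """Construct the non-overlapping RRnI sequence (stride equal to width)."""
    return build_rrnim(parent, n, n)


def n_sequences(n_max: int) -> int:
    """Total distinct sequences for a sweep up to ``n_max``:
    HRV + (n_max - 1) non-overlapping + n_max*(n_max - 1)/2 overlapping."""
    return 1 + (n_max - 1) + n_max * (n_max - 1) // 2


def enumerate_sequences(parent: RRSeries, cfg: HRnVConfig) -> list[DerivedRRSeries]:
    """All HRnV sequences up to ``cfg.n_max`` in deterministic order.

    Order: HRV, then HR{n}V for n = 2..N, then HR{n}V{m} for n = 2..N,
    m = 1..n-1.  For N = 3 this is HRV, HR2V, HR3V, HR2V1, HR3V1, HR3V2.
    """
    cfg.validate_for(parent)
    out = [build_rrnim(parent, 1, 1)]
    for n in range(2, cfg.n_max + 1):
        out.append(build_rrni(parent, n))
    for n in range(2, cfg.n_max + 1):
        for m in range(1, n):
            out.append(build_rrnim(parent, n, m))
    return out
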