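"""Nonlinear HRV/HRnV parameters: Poincaré descriptors, approximate and
sample entropy, and detrended fluctuation analysis.

Entropy tolerances scale with the SD of the sequence being analysed, so
composite (HRnV) sequences automatically get a composite-scale tolerance
and both entropies are invariant under affine transforms of the intervals.

Sample entropy is undefined when no template pair of length m+1 matches
(A = 0), which genuinely happens on short composite sequences; this module
returns NaN in that case rather than a sentinel blow-up, and downstream
tables carry an ``sampen_undefined`` flag.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["poincare", "apen", "sampen", "dfa", "nonlinear_params"]


def _values(seq) -> np.ndarray:
    return np.asarray(getattr(seq, "intervals", seq), dtype=float)


def poincare(seq, *, sample: bool = True) -> tuple[float, float]:
    """Short- and long-axis dispersions (SD1, SD2) of the lag-1 Poincaré plot.

    Computed from lag-1 difference/variance formulas, which are algebraically
    identical to fitting the scatter ellipse.  The transverse coordinate is
    taken about zero (successive NN differences have negligible mean), so
    under the population convention SD1 equals RMSSD/sqrt(2) exactly.  SD2 is
    derived from ``2 * SDNN**2 - SD1**2`` with the matching variance
    convention, floored at zero.
    """
    x = _values(seq)
    if x.size < 3:
        raise ValueError("need at least 3 elements")
    d = np.diff(x)
    denom = d.size - 1 if sample else d.size
    sd1_sq = 0.5 * float(np.sum(d * d)) / denom
    var_x = float(np.var(x, ddof=1 if sample else 0))
    sd2_sq = max(0.0, 2.0 * var_x - sd1_sq)
    return math.sqrt(sd1_sq), math.sqrt(sd2_sq)


def _pair_matches(x: np.ndarray, m: int, r: float, n_templates: int) -> float:
    """Number of ordered template pairs (i != j) of length ``m`` within
    Chebyshev distance ``r``, with i, j restricted to the first
    ``n_templates`` templates (the SampEn index convention)."""
    templ = sliding_window_view(x, m)[:n_templates]
    dist = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
    return float((dist <= r).sum() - n_templates)  # subtract self-pairs


def apen(seq, m_dim: int = 2, r_frac: float = 0.2) -> float:
    """Approximate entropy with tolerance ``r = r_frac * SD``, self-matches
    included, Chebyshev distance.

    ApEn = phi(m) - phi(m+1) where phi(m) is the mean of log C_i^m and
    C_i^m is the fraction of templates within r of template i.
    """
    x = _values(seq)
    if x.size < m_dim + 2:
        raise ValueError(f"need at least {m_dim + 2} elements")
    r = r_frac * float(np.std(x))

    def phi(m: int) -> float:
        templ = sliding_window_view(x, m)
        dist = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=-1)
        c = (dist <= r).sum(axis=1) / templ.shape[0]
        return float(np.mean(np.log(c)))

    return phi(m_dim) - phi(m_dim + 1)


def sampen(seq, m_dim: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy ``-ln(A/B)`` with self-matches excluded.

    A and B count matching template pairs of lengths m+1 and m over the same
    index range.  Returns NaN (with a warning) when A = 0; a constant series
    returns 0 exactly (A = B > 0).
    """
    x = _values(seq)
    if x.size < m_dim + 2:
        raise ValueError(f"need at least {m_dim + 2} elements")
    r = r_frac * float(np.std(x))
    K = x.size - m_dim  # both lengths use templates 0 .. K-1
    b = _pair_matches(x, m_dim, r, K)
    a = _pair_matches(x, m_dim + 1, r, K)
    if a == 0 or b == 0:
        warnings.warn("sample entropy undefined: no template matches", stacklevel=2)
        return math.nan
    return -math.log(a / b)


def dfa(seq, scales_short: tuple[int, int] = (4, 16),
        scales_long: tuple[int, int] = (16, 64)) -> tuple[float, float]:
    """Detrended fluctuation analysis slopes (alpha1, alpha2).

    The series is mean-centred and integrated; each box size s gets a
    per-box linear detrend over non-overlapping boxes and an RMS fluctuation
    F(s); alphas are least-squares slopes of log F vs log s over the short
    (default 4-16 beats) and long (16-64) ranges.  When the series is too
    short for a range (fewer than 4 boxes of 2 at the largest usable scale),
    the range is restricted with a warning; alpha is NaN if fewer than two
    scales survive.
    """
    x = _values(seq)
    if x.size < 2 * scales_short[0]:
        raise ValueError("series too short for DFA")
    profile = np.cumsum(x - np.mean(x))

    def fluctuation(s: int) -> float:
        nboxes = profile.size // s
        seg = profile[: nboxes * s].reshape(nboxes, s)
        t = np.arange(s, dtype=float)
        # per-box linear fit via closed-form least squares
        tm = t.mean()
        denom = np.sum((t - tm) ** 2)
        slope = (seg @ (t - tm)) / denom
        inter = seg.mean(axis=1) - slope * tm
        resid = seg - (inter[:, None] + slope[:, None] * t)
        return math.sqrt(float(np.mean(resid**2)))

    def alpha(lo: int, hi: int) -> float:
        usable = [s for s in range(lo, hi + 1) if profile.size // s >= 2]
        if len(usable) < len(range(lo, hi + 1)):
            warnings.warn(
                f"series of length {x.size} too short for DFA scales up to {hi}; "
                f"restricting", stacklevel=3)
        if len(usable) < 2:
            return math.nan
        logs = np.log([float(s) for s in usable])
        logf = np.log([fluctuation(s) for s in usable])
        return float(np.polyfit(logs, logf, 1)[0])

    return alpha(*scales_short), alpha(*scales_long)


def nonlinear_params(seq, *, sample_sd: bool = True, m_dim: int = 2,
                     r_frac: float = 0.2,
                     scales_short: tuple[int, int] = (4, 16),
                     scales_long: tuple[int, int] = (16, 64)) -> dict:
    """Full nonlinear row: SD1/SD2, SampEn, ApEn, DFA alpha1/alpha2."""
    sd1, sd2 = poincare(seq, sample=sample_sd)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = sampen(seq, m_dim, r_frac)
        a1, a2 = dfa(seq, scales_short, scales_long)
    return {
        "sd1": sd1,
        "sd2": sd2,
        "sampen": se,
        "apen": apen(seq, m_dim, r_frac),
        "dfa_alpha1": a1,
        "dfa_alpha2": a2,
    }
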