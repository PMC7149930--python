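"""Spectral analysis of unevenly sampled (composite) RR-interval series.

Beat-to-beat interval sequences are sampled at the beat times themselves,
which are not uniform, and the HRnV composites inherit irregular timestamps
from their constituent beats.  The spectral estimator is therefore a
Lomb-Scargle periodogram evaluated directly on the native timestamps — no
resampling — with the density scaled so that numerically integrating it
over the frequency grid returns power on the variance scale (ms²).

Band powers use the conventional cut-offs: VLF (0, 0.04], LF (0.04, 0.15],
HF (0.15, 0.4] Hz.  The edges are half-open on the left so no grid point is
counted in two bands, and they are deliberately *not* rescaled with the
HRnV window width n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

__all__ = ["PowerSpectrum", "FreqDomainParams", "estimate_psd", "band_powers",
           "freq_domain_params"]

#: Conventional band edges, Hz (half-open on the left).
DEFAULT_BANDS = {"vlf": (0.0, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.4)}


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided spectral density estimate: ``freqs`` (Hz, increasing) and
    ``density`` (ms²/Hz, nonnegative)."""

    freqs: np.ndarray
    density: np.ndarray
    method: str = "lomb-scargle"


@dataclass(frozen=True)
class FreqDomainParams:
    total_power: float
    vlf_power: float
    lf_power: float
    hf_power: float
    lf_norm: float
    hf_norm: float
    lf_hf_ratio: float

    def as_dict(self) -> dict:
        return {
            "total_power": self.total_power,
            "vlf_power": self.vlf_power,
            "lf_power": self.lf_power,
            "hf_power": self.hf_power,
            "lf_norm": self.lf_norm,
            "hf_norm": self.hf_norm,
            "lf_hf_ratio": self.lf_hf_ratio,
        }


def estimate_psd(seq, *, oversample: int = 4, f_max: float | None = None) -> PowerSpectrum:
    """Lomb-Scargle periodogram of the mean-subtracted interval series.

    The grid runs from ``1 / (oversample * T)`` (T = time span) up to half
    the median beat rate, extended to at least 0.4 Hz so the conventional HF
    band is always covered.  Scaling is chosen so that the trapezoidal
    integral of the density over the full grid approximates the series
    variance (a Parseval-style normalisation): with N samples over span T,
    the raw periodogram is multiplied by ``2 T / N``.

    Detrending is mean subtraction only; VLF power is sensitive to this
    choice.
    """
    y = np.asarray(seq.intervals, dtype=float)
    t = np.asarray(seq.t_end, dtype=float) / 1000.0  # seconds
    if y.size < 8:
        raise ValueError("need at least 8 elements for spectral estimation")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    T = t[-1] - t[0]
    median_interval = float(np.median(np.diff(t)))
    nyquist = 0.5 / median_interval
    if f_max is None:
        f_max = max(0.4 + 1e-9, nyquist)
    df = 1.0 / (oversample * T)
    freqs = np.arange(df, f_max + df / 2, df)
    power = lombscargle(t, y - y.mean(), 2 * np.pi * freqs)
    density = power * (2.0 * T / y.size)
    return PowerSpectrum(freqs=freqs, density=density)


def _band_integral(spec: PowerSpectrum, lo: float, hi: float) -> float:
    mask = (spec.freqs > lo) & (spec.freqs <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(spec.density[mask], spec.freqs[mask]))


def band_powers(spec: PowerSpectrum, bands: dict | None = None) -> FreqDomainParams:
    """Integrate the density within each half-open band (trapezoid rule).

    Total power is defined as VLF + LF + HF under the band partition, so the
    decomposition is exact by construction.  Normalised units express LF and
    HF as percentages of (LF + HF); ``hf_norm`` is computed as
    ``100 - lf_norm`` so the two always sum to exactly 100.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    vlf = _band_integral(spec, *bands["vlf"])
    lf = _band_integral(spec, *bands["lf"])
    hf = _band_integral(spec, *bands["hf"])
    total = vlf + lf + hf
    if lf + hf > 0:
        lf_norm = 100.0 * lf / (lf + hf)
        hf_norm = 100.0 - lf_norm
    else:
        lf_norm = hf_norm = math.nan
    if hf > 0:
        ratio = lf / hf
    else:
        warnings.warn("HF power is zero: LF/HF ratio undefined", stacklevel=2)
        ratio = math.nan
    return FreqDomainParams(total, vlf, lf, hf, lf_norm, hf_norm, ratio)


def freq_domain_params(seq, bands: dict | None = None) -> dict:
    """Convenience wrapper: PSD estimation followed by band integration."""
    return band_powers(estimate_psd(seq), bands).as_dict()
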