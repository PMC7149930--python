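"""Single-lead ECG front-end: QRS detection and NN-interval cleaning.

The detector follows the classic derivative-based recipe: bandpass filter
around the QRS energy band, differentiate, square, moving-window integrate,
then pick peaks above an adaptive threshold with a 200 ms refractory
period.  It is intended for short (minutes-long) lead-II strips of the kind
acquired at triage, not for ambulatory-length records.

Cleaning enforces physiological bounds and an ectopic rule: intervals
outside [300, 2000] ms, or deviating more than 20% from the running median
of the last five accepted intervals, are excised (not interpolated), which
leaves honest gaps in the time axis that the Lomb spectral estimator
tolerates by construction.  Records losing more than 20% of their intervals
are rejected as non-sinus or too noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .series import RRSeries

__all__ = ["ECGTrace", "detect_beats", "clean_nn", "UnusableSignalError",
           "NonSinusError"]


class UnusableSignalError(ValueError):
    """Flatline, saturated or otherwise undetectable input."""


class NonSinusError(ValueError):
    """Too many intervals removed: rhythm not analysable as sinus."""


@dataclass(frozen=True)
class ECGTrace:
    """A sampled single-lead voltage trace (mV) at sampling rate ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def detect_beats(ecg: ECGTrace, *, refractory_s: float = 0.2) -> np.ndarray:
    """R-peak times (seconds) from a derivative/energy QRS detector.

    Requires fs >= 100 Hz and at least 10 s of signal.  Raises
    :class:`UnusableSignalError` on flat or saturated traces.
    """
    if ecg.fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz")
    if ecg.duration < 10:
        raise ValueError("need at least 10 s of signal")
    x = ecg.samples
    if np.ptp(x) < 1e-6:
        raise UnusableSignalError("flatline input")
    sat = np.mean(np.abs(x) >= 0.999 * np.max(np.abs(x))) if np.max(np.abs(x)) else 0
    if sat > 0.5:
        raise UnusableSignalError("saturated input")

    # bandpass 5-15 Hz isolates QRS energy
    sos = signal.butter(3, [5.0, 15.0], btype="bandpass", fs=ecg.fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(filt) * ecg.fs
    energy = deriv**2
    win = max(1, int(round(0.15 * ecg.fs)))
    mwi = np.convolve(energy, np.ones(win) / win, mode="same")

    thresh = 0.25 * np.quantile(mwi, 0.99)
    peaks, _ = signal.find_peaks(
        mwi, height=thresh, distance=max(1, int(round(refractory_s * ecg.fs)))
    )
    if peaks.size < 3:
        raise UnusableSignalError("no usable QRS complexes detected")

    # refine each detection to the local R-wave apex of the raw trace
    half = int(round(0.05 * ecg.fs))
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    beats = np.unique(refined) / ecg.fs
    return beats


def clean_nn(beats, *, lo_ms: float = 300.0, hi_ms: float = 2000.0,
             median_window: int = 5, deviation_frac: float = 0.2,
             max_removed_frac: float = 0.2, source_id: str = "") -> RRSeries:
    """Turn beat times (s) into a cleaned NN :class:`RRSeries` (ms).

    An interval is rejected when it falls outside ``[lo_ms, hi_ms]`` or
    deviates more than ``deviation_frac`` from the running median of the
    last ``median_window`` accepted intervals.  Rejected intervals are
    excised — never merged into neighbours — so the cumulative end-times of
    the survivors stay on the true time axis.  Raises
    :class:`NonSinusError` when more than ``max_removed_frac`` of the
    intervals are removed.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size < 3:
        raise ValueError("need at least 3 beats")
    rr = np.diff(beats) * 1000.0
    t_end = beats[1:] * 1000.0

    kept_idx: list[int] = []
    recent: list[float] = []
    for i, iv in enumerate(rr):
        ok = lo_ms <= iv <= hi_ms
        if ok and recent:
            med = float(np.median(recent[-median_window:]))
            ok = abs(iv - med) <= deviation_frac * med
        if ok:
            kept_idx.append(i)
            recent.append(float(iv))
    removed_frac = 1.0 - len(kept_idx) / rr.size
    if removed_frac > max_removed_frac:
        raise NonSinusError(
            f"{removed_frac:.0%} of intervals removed: non-sinus or noisy record"
        )
    series = RRSeries(rr[kept_idx], source_id=source_id, t_end=t_end[kept_idx])
    object.__setattr__(series, "removed_fraction", removed_frac)
    return series
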