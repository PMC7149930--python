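"""Plain-text readers and writers.

Supported formats:

* RR text — one interval per line in milliseconds, ``#`` comments allowed.
* RR CSV — columns ``t_end_ms,interval_ms`` (timestamps preserved, so a
  cleaned series with excised beats keeps its true time axis).
* ECG CSV — header line ``fs=<Hz>`` (as a comment) followed by one voltage
  sample (mV) per line; or two columns ``fs`` in a header row.
* Cohort CSV — one row per patient with an ``outcome`` column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ecg import ECGTrace
from .series import RRSeries

__all__ = ["read_rr", "write_rr", "read_ecg_csv", "write_ecg_csv",
           "read_cohort", "write_cohort"]


def read_rr(path) -> RRSeries:
    """Read an RR series from text (one interval/line) or CSV
    (``t_end_ms,interval_ms``); format detected from the first data line."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()]
    data = [ln for ln in lines if ln and not ln.startswith("#")]
    if not data:
        raise ValueError(f"{path}: no data lines")
    first = data[0]
    if "," in first:
        header = 0 if any(c.isalpha() for c in first) else None
        df = pd.read_csv(path, comment="#", header=header,
                         names=None if header == 0 else ["t_end_ms", "interval_ms"])
        df.columns = [c.strip().lower() for c in df.columns]
        if "interval_ms" not in df.columns:
            raise ValueError(f"{path}: expected columns t_end_ms,interval_ms")
        return RRSeries(df["interval_ms"].to_numpy(float),
                        t_end=df["t_end_ms"].to_numpy(float),
                        source_id=path.stem)
    return RRSeries(np.array([float(v) for v in data]), source_id=path.stem)


def write_rr(series: RRSeries, path, *, with_timestamps: bool = True) -> None:
    path = Path(path)
    if with_timestamps:
        pd.DataFrame({"t_end_ms": series.t_end,
                      "interval_ms": series.intervals}).to_csv(path, index=False)
    else:
        path.write_text("\n".join(f"{v:.6g}" for v in series.intervals) + "\n")


def read_ecg_csv(path) -> ECGTrace:
    """Voltage-per-line CSV with a ``# fs=<Hz>`` header comment."""
    path = Path(path)
    fs = None
    samples = []
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln:
            continue
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if body.lower().startswith("fs"):
                fs = float(body.split("=", 1)[1])
            continue
        samples.append(float(ln))
    if fs is None:
        raise ValueError(f"{path}: missing '# fs=<Hz>' header")
    return ECGTrace(samples=np.array(samples), fs=fs)


def write_ecg_csv(ecg: ECGTrace, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={ecg.fs}\n")
        for v in ecg.samples:
            fh.write(f"{v:.6g}\n")


def read_cohort(path, outcome: str = "outcome") -> pd.DataFrame:
    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise ValueError(f"{path}: missing outcome column {outcome!r}")
    vals = set(df[outcome].dropna().unique())
    if vals - {0, 1}:
        raise ValueError(f"{path}: outcome must be binary 0/1")
    if df[outcome].isna().any():
        raise ValueError(f"{path}: outcome must not be missing")
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
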