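"""Assembly of the full HRnV parameter panel.

For a sweep up to ``n_max`` the panel contains one parameter set per
sequence: 21 parameters for conventional HRV (n = 1) and 23 for every HRnV
set (the extra two being the threshold-scaled NN50n / pNN50n).  With
``n_max = 3`` this gives 6 sequence sets and 21 + 5 x 23 = 136 columns.

Column names join the sequence label and parameter name with an
underscore, e.g. ``HR2V1_sampen``.  Undefined values (e.g. sample entropy
on a too-short composite sequence) are NaN and listed in a ``flags``
sidecar entry.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .frequency import band_powers, estimate_psd
from .nonlinear import nonlinear_params
from .series import DerivedRRSeries, HRnVConfig, RRSeries, enumerate_sequences
from .time_domain import time_domain_params

__all__ = ["PARAM_ORDER", "compute_params", "compute_panel", "n_param_columns"]

#: Parameter order of one sequence set; nn50n/pnn50n are omitted for n = 1.
PARAM_ORDER = [
    "mean_nn", "sdnn", "rmssd", "skewness", "kurtosis", "triangular_index",
    "nn50", "pnn50", "nn50n", "pnn50n",
    "total_power", "vlf_power", "lf_power", "hf_power",
    "lf_norm", "hf_norm", "lf_hf_ratio",
    "sd1", "sd2", "sampen", "apen", "dfa_alpha1", "dfa_alpha2",
]


def n_param_columns(n_max: int) -> int:
    """Total parameter columns: 21 + (n_max(n_max+1)/2 - 1) * 23."""
    return 21 + (n_max * (n_max + 1) // 2 - 1) * 23


def compute_params(seq: DerivedRRSeries, cfg: HRnVConfig | None = None) -> dict:
    """All parameters of one (composite) sequence, in :data:`PARAM_ORDER`."""
    cfg = cfg or HRnVConfig()
    out: dict[str, float] = {}
    out.update(time_domain_params(
        seq, seq.n, sample_sd=cfg.sample_sd, excess_kurtosis=cfg.excess_kurtosis,
        pnn50_denominator=cfg.pnn50_denominator, tri_bin_width=cfg.tri_bin_width_ms,
    ))
    bands = {"vlf": cfg.vlf_band, "lf": cfg.lf_band, "hf": cfg.hf_band}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out.update(band_powers(estimate_psd(seq), bands).as_dict())
    out.update(nonlinear_params(
        seq, sample_sd=cfg.sample_sd, m_dim=cfg.embedding_dim,
        r_frac=cfg.tolerance_frac, scales_short=cfg.dfa_scales_short,
        scales_long=cfg.dfa_scales_long,
    ))
    order = [p for p in PARAM_ORDER if seq.n > 1 or p not in ("nn50n", "pnn50n")]
    return {p: out[p] for p in order}


def compute_panel(series: RRSeries, cfg: HRnVConfig | None = None) -> dict:
    """The wide panel row for one record: ``{label}_{param}`` columns for
    every sequence up to ``cfg.n_max``, plus a ``flags`` list naming the
    undefined entries."""
    cfg = cfg or HRnVConfig()
    row: dict[str, float] = {}
    flags: list[str] = []
    for seq in enumerate_sequences(series, cfg):
        for param, value in compute_params(seq, cfg).items():
            key = f"{seq.label}_{param}"
            row[key] = value
            if isinstance(value, float) and (math.isnan(value) or np.isnan(value)):
                flags.append(f"{key}_undefined")
    row["flags"] = ";".join(flags)
    return row
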