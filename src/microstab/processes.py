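"""Derived ecosystem-process rates and the multifunctionality index.

Six microbial-mediated functions are carried per sample: C mineralization
(basal respiration), substrate-induced respiration (SIR), the metabolic
quotient qCO2 (respiration per unit biomass; higher = less efficient),
total hydrolytic enzyme activity (sum of BG, LAP, NAG, AP), and the net N
mineralization and net nitrification rates from inorganic-N accumulation
over an incubation interval. Net N rates may legitimately be negative
(immobilization / denitrification) and are never truncated.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import ProcessTable

FUNCTIONS = (
    "c_mineralization",
    "sir",
    "qco2",
    "total_enzyme",
    "n_mineralization",
    "nitrification",
)


def metabolic_quotient(respiration, biomass):
    """qCO2 = respiration / biomass; NA (with a warning) where biomass <= 0."""
    r = np.asarray(respiration, dtype=float)
    b = np.asarray(biomass, dtype=float)
    bad = b <= 0
    if np.any(bad):
        warnings.warn(f"{int(np.sum(bad))} sample(s) with biomass <= 0: qCO2 set to NA")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(bad, np.nan, r / np.where(bad, np.nan, b))
    return q if q.ndim else float(q)


def net_n_rates(nh4_t0, no3_t0, nh4_t1, no3_t1, days):
    """Net N mineralization and net nitrification rates (mg N kg-1 d-1).

    Mineralization is the accumulation rate of total inorganic N
    (NH4-N + NO3-N); nitrification is the accumulation rate of NO3-N.
    """
    days = np.asarray(days, dtype=float)
    if np.any(days <= 0):
        raise ValueError("incubation interval must be > 0 days")
    nh4_t0, no3_t0, nh4_t1, no3_t1 = (np.asarray(v, dtype=float) for v in (nh4_t0, no3_t0, nh4_t1, no3_t1))
    n_min = ((nh4_t1 + no3_t1) - (nh4_t0 + no3_t0)) / days
    nitrif = (no3_t1 - no3_t0) / days
    return n_min, nitrif


def total_enzyme(bg, lap, nag, ap):
    """Sum of the four hydrolytic enzyme rates; NA propagates."""
    return np.asarray(bg, dtype=float) + np.asarray(lap, dtype=float) + np.asarray(nag, dtype=float) + np.asarray(ap, dtype=float)


def derive_functions(proc: ProcessTable) -> pd.DataFrame:
    """Assemble the six-function table from measured inputs."""
    f = proc.frame
    n_min, nitrif = net_n_rates(
        f["nh4_t0"], f["no3_t0"], f["nh4_t1"], f["no3_t1"], f["interval_days"]
    )
    out = pd.DataFrame(
        {
            "c_mineralization": f["respiration"].to_numpy(dtype=float),
            "sir": f["sir"].to_numpy(dtype=float),
            "qco2": metabolic_quotient(f["respiration"], f["biomass"]),
            "total_enzyme": total_enzyme(f["bg"], f["lap"], f["nag"], f["ap"]),
            "n_mineralization": n_min,
            "nitrification": nitrif,
        },
        index=f.index,
    )
    return out


def multifunctionality(
    funcs: pd.DataFrame, selected=FUNCTIONS, ddof: int = 1
) -> pd.Series:
    """Mean z-scaled rate across the selected functions, per sample.

    Each function is centered and scaled across samples (sample sd by
    default); the index is the unweighted mean of the z-scores, so it is
    invariant to affine rescaling of any input function.
    """
    selected = list(selected)
    sub = funcs[selected]
    if len(sub) < 2:
        raise ValueError("multifunctionality needs >= 2 samples")
    sd = sub.std(ddof=ddof)
    zero_var = sd.index[(sd == 0) | sd.isna()]
    if len(zero_var):
        raise ValueError(f"zero-variance function(s): {zero_var.tolist()}")
    z = (sub - sub.mean()) / sd
    out = z.mean(axis=1)
    out.name = "multifunctionality"
    return out
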