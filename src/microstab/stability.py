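"""Orwin-Wardle resistance index of ecosystem functions under stress.

For a function with control-group value C0 and stressed-group value P0,
let D0 = C0 - P0. Then

    RS = 1 - 2|D0| / (|C0| + |D0|)

is bounded in (-1, 1]: RS = 1 means no stress-induced change, and RS
approaches -1 as the change dwarfs the control value. |C0| keeps the index
well-defined for functions with legitimately negative control means (net N
fluxes); the absolute value is logged when it bites.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_core import SampleMetadata
from .processes import FUNCTIONS


def resistance(c0: float, p0: float) -> float:
    """RS = 1 - 2|D0|/(|C0| + |D0|) with D0 = c0 - p0; NA if both are zero."""
    c0 = float(c0)
    p0 = float(p0)
    d0 = c0 - p0
    denom = abs(c0) + abs(d0)
    if denom == 0:
        warnings.warn("resistance undefined for C0 = P0 = 0; returning NA")
        return float("nan")
    if c0 < 0:
        warnings.warn("negative control mean: using |C0| in the resistance denominator")
    return 1.0 - 2.0 * abs(d0) / denom


def resistance_table(
    funcs: pd.DataFrame,
    meta: SampleMetadata,
    functions=FUNCTIONS,
    mode: str = "cell_mean",
) -> pd.DataFrame:
    """Resistance per (land use x diversity level x function).

    ``mode="cell_mean"`` compares within-cell control and stressed means
    (one RS per cell); ``mode="replicate"`` pairs each stressed replicate
    against the cell's control mean (one RS per stressed replicate,
    bootstrap-friendly). Cells missing either group yield NA rows with a
    warning.
    """
    if mode not in ("cell_mean", "replicate"):
        raise ValueError(f"unknown mode {mode!r}")
    mf = meta.frame.loc[funcs.index]
    rows = []
    for (lu, dl), cell in mf.groupby(["land_use", "diversity_level"], observed=True):
        ctrl_ids = cell.index[cell["stress"] == "control"]
        strs_ids = cell.index[cell["stress"] == "stressed"]
        for fn in functions:
            c_vals = funcs.loc[ctrl_ids, fn].dropna()
            p_vals = funcs.loc[strs_ids, fn].dropna()
            if len(c_vals) == 0 or len(p_vals) == 0:
                warnings.warn(f"cell ({lu}, {dl}) lacks control or stressed samples for {fn}")
                rows.append((lu, dl, fn, np.nan, np.nan, np.nan, np.nan, len(c_vals), len(p_vals), np.nan))
                continue
            c0 = float(c_vals.mean())
            if mode == "cell_mean":
                p0 = float(p_vals.mean())
                rows.append((lu, dl, fn, c0, p0, c0 - p0, resistance(c0, p0), len(c_vals), len(p_vals), np.nan))
            else:
                for rep_id, p0 in p_vals.items():
                    rows.append(
                        (lu, dl, fn, c0, float(p0), c0 - float(p0), resistance(c0, float(p0)),
                         len(c_vals), len(p_vals), mf.loc[rep_id, "replicate"])
                    )
    out = pd.DataFrame(
        rows,
        columns=["land_use", "diversity_level", "function", "C0", "P0", "D0", "RS",
                 "n_control", "n_stressed", "replicate"],
    )
    if mode == "cell_mean":
        out = out.drop(columns="replicate")
    return out
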