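"""Alpha diversity by repeated rarefaction.

Sequencing depth varies among samples, and both richness and (to a lesser
degree) the Shannon index increase with depth. Depth is standardized by
rarefying — drawing a fixed number of reads per sample without replacement
(multivariate hypergeometric) — and, because a single rarefaction discards
data arbitrarily, the draw is repeated many times and the metrics averaged
over iterations.

Per-iteration streams are seeded from (seed, sample_id, iteration), so
results do not depend on sample order and samples can be processed in any
schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import substream_rng
from .io_core import CountTable


@dataclass
class DiversityResult:
    """Mean/sd over rarefaction iterations of Shannon H' and richness S."""

    frame: pd.DataFrame  # columns: mean_shannon, sd_shannon, mean_richness, sd_richness
    depth: int
    n_iter: int
    seed: int
    excluded: list[str]
    log_base: str = "e"


def shannon(counts_vector, base: float | None = None) -> float:
    """Shannon index H' = -sum p_i log p_i over taxa with p_i > 0.

    Natural log (nats) by default; pass ``base=2`` for bits.
    """
    x = np.asarray(counts_vector, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = x[x > 0] / total
    h = -np.sum(p * np.log(p))
    if base is not None:
        h /= np.log(base)
    return float(h)


def rarefy_once(sample, depth: int, rng: np.random.Generator | int) -> np.ndarray:
    """Draw exactly ``depth`` reads without replacement from one sample."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    x = np.asarray(sample)
    if not np.issubdtype(x.dtype, np.integer):
        raise ValueError("rarefaction requires integer counts")
    total = int(x.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below rarefaction depth {depth}")
    # Multivariate hypergeometric = exhaustive urn draw without replacement.
    return rng.multivariate_hypergeometric(x, depth)


def repeated_rarefaction(
    table: CountTable, depth: int | None = None, n_iter: int = 1000, seed: int = 0
) -> DiversityResult:
    """Average Shannon and richness over ``n_iter`` independent rarefactions.

    Samples with fewer than ``depth`` reads are excluded with a warning (and
    listed in the result) rather than erroring. ``depth=None`` uses the
    smallest sample total.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    totals = table.sample_totals()
    if depth is None:
        depth = int(totals.min())
    retained = totals.index[totals >= depth].tolist()
    excluded = totals.index[totals < depth].tolist()
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) below depth {depth} excluded: {excluded[:5]}"
        )
    if not retained:
        raise ValueError(f"all samples fall below rarefaction depth {depth}")
    rows = {}
    for sid in retained:
        x = table.counts.loc[sid].to_numpy()
        h = np.empty(n_iter)
        s = np.empty(n_iter)
        for it in range(n_iter):
            sub = rarefy_once(x, depth, substream_rng(seed, sid, it))
            s[it] = np.count_nonzero(sub)
            h[it] = shannon(sub)
        rows[sid] = (h.mean(), h.std(ddof=1) if n_iter > 1 else 0.0,
                     s.mean(), s.std(ddof=1) if n_iter > 1 else 0.0)
    frame = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["mean_shannon", "sd_shannon", "mean_richness", "sd_richness"],
    )
    frame.index.name = "sample_id"
    return DiversityResult(frame=frame, depth=depth, n_iter=n_iter, seed=seed, excluded=excluded)


def rarefaction_curve(
    table: CountTable, depths, n_iter: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean rarefied richness per sample over an ascending depth grid."""
    depths = list(depths)
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ValueError("depth grid must be ascending")
    out = {}
    for d in depths:
        totals = table.sample_totals()
        col = {}
        for sid in table.sample_ids:
            if totals[sid] < d:
                col[sid] = np.nan
                continue
            x = table.counts.loc[sid].to_numpy()
            col[sid] = float(
                np.mean(
                    [
                        np.count_nonzero(rarefy_once(x, d, substream_rng(seed, sid, d, it)))
                        for it in range(n_iter)
                    ]
                )
            )
        out[d] = col
    curve = pd.DataFrame(out)
    curve.index.name = "sample_id"
    curve.columns.name = "depth"
    return curve
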