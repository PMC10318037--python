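"""Bray-Curtis dissimilarity and the abundance-based Raup-Crick null model.

Ordinary dissimilarity metrics are confounded with alpha diversity: two
random draws from the same species pool look more dissimilar when they are
species-poor. The Raup-Crick standardization removes this by ranking the
observed Bray-Curtis dissimilarity of a sample pair within a null
distribution of dissimilarities between probabilistically assembled
communities that preserve each sample's observed richness and total
abundance, and the pool-wide occurrence frequencies and relative
abundances of taxa.

Null assembly is the classic two-step scheme:

1. *Membership*: draw S distinct taxa from the regional pool without
   replacement, with selection probability proportional to occurrence
   frequency (the fraction of empirical samples containing the taxon).
2. *Abundance*: place one individual in each drawn taxon, then distribute
   the remaining N - S individuals among the drawn taxa with probability
   proportional to their pooled relative abundances.

Step 1 is implemented with the Gumbel-top-k construction (take the S
largest of ``log w_i + Gumbel(0,1)`` perturbations), which yields exactly
the sequential renormalized without-replacement distribution.

With obs the observed Bray-Curtis value and the null values BC_k,

    alpha = [#(BC_k < obs - tol) + 0.5 #(|BC_k - obs| <= tol)] / n_null
    RC    = 2 alpha - 1  in [-1, 1],

so RC near -1 means the pair is far more similar than the null expects
(deterministically assembled from the same pool), near +1 far more
dissimilar, and near 0 indistinguishable from stochastic assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._util import substream_rng
from .io_core import CountTable

DEFAULT_TIE_TOL = 1e-10


@dataclass
class DissimilarityMatrix:
    """Square symmetric pairwise dissimilarities keyed by sample id."""

    data: pd.DataFrame
    metric: str
    n_null: int | None = None
    seed: int | None = None
    tie_tol: float | None = None

    def __post_init__(self) -> None:
        if not self.data.index.equals(self.data.columns):
            raise ValueError("dissimilarity matrix rows and columns must agree")
        arr = self.data.to_numpy(dtype=float)
        if not np.allclose(arr, arr.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric (tol 1e-12)")

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()


@dataclass
class RegionalPool:
    """Occurrence frequencies and pooled relative abundances of taxa.

    Only taxa observed in at least one pool sample are retained (taxa with
    zero occurrence cannot be drawn in step 1).
    """

    taxon_ids: list[str]
    occurrence: np.ndarray  # fraction of samples containing the taxon, > 0
    rel_abundance: np.ndarray  # pooled relative abundance, sums to 1
    n_samples: int = 0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.occurrence = np.asarray(self.occurrence, dtype=float)
        self.rel_abundance = np.asarray(self.rel_abundance, dtype=float)
        if (self.occurrence <= 0).any():
            raise ValueError("pool occurrence frequencies must be > 0")
        self._index = {t: i for i, t in enumerate(self.taxon_ids)}

    @property
    def size(self) -> int:
        return len(self.taxon_ids)


def build_pool(table: CountTable, sample_ids=None) -> RegionalPool:
    """Build the regional pool from all samples (default) or a subset."""
    counts = table.counts if sample_ids is None else table.counts.loc[list(sample_ids)]
    present = counts.to_numpy() > 0
    occurrence = present.mean(axis=0)
    keep = occurrence > 0
    totals = counts.to_numpy(dtype=float).sum(axis=0)
    return RegionalPool(
        taxon_ids=[t for t, k in zip(counts.columns, keep) if k],
        occurrence=occurrence[keep],
        rel_abundance=totals[keep] / totals[keep].sum(),
        n_samples=len(counts),
    )


def bray_curtis(x, y) -> float:
    """BC = sum|x_i - y_i| / sum(x_i + y_i) on abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("Bray-Curtis undefined for a zero-total vector")
    return float(np.abs(x - y).sum() / (x + y).sum())


def _null_batch(pool: RegionalPool, S: int, N: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Assemble ``n`` null communities of richness S and total N, as rows."""
    P = pool.size
    if S > P:
        raise ValueError(f"requested richness {S} exceeds pool size {P}")
    if N < S:
        raise ValueError(f"total {N} below richness {S}")
    if S < 1:
        raise ValueError("richness must be >= 1")
    log_w = np.log(pool.occurrence)
    keys = log_w + rng.gumbel(size=(n, P))
    if S == P:
        drawn = np.tile(np.arange(P), (n, 1))
    else:
        drawn = np.argpartition(-keys, S - 1, axis=1)[:, :S]
    out = np.zeros((n, P), dtype=np.int64)
    rows = np.repeat(np.arange(n), S)
    out[rows, drawn.ravel()] = 1
    if N > S:
        for i in range(n):
            p = pool.rel_abundance[drawn[i]]
            out[i, drawn[i]] += rng.multinomial(N - S, p / p.sum())
    return out


def assemble_null_pair(
    pool: RegionalPool, S_x: int, N_x: int, S_y: int, N_y: int, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble one independent null community per sample of a pair.

    Returns two vectors over ``pool.taxon_ids`` with richness exactly S and
    total exactly N for each sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = _null_batch(pool, S_x, N_x, 1, rng)[0]
    y = _null_batch(pool, S_y, N_y, 1, rng)[0]
    return x, y


def rc_bray_pair(
    x,
    y,
    pool: RegionalPool,
    n_null: int = 1000,
    seed=0,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> float:
    """Raup-Crick standardized Bray-Curtis for one sample pair."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x)
    y = np.asarray(y)
    obs = bray_curtis(x, y)
    S_x, N_x = int(np.count_nonzero(x)), int(x.sum())
    S_y, N_y = int(np.count_nonzero(y)), int(y.sum())
    nx = _null_batch(pool, S_x, N_x, n_null, rng).astype(float)
    ny = _null_batch(pool, S_y, N_y, n_null, rng).astype(float)
    null_bc = np.abs(nx - ny).sum(axis=1) / (nx + ny).sum(axis=1)
    below = np.count_nonzero(null_bc < obs - tie_tol)
    ties = np.count_nonzero(np.abs(null_bc - obs) <= tie_tol)
    alpha = (below + 0.5 * ties) / n_null
    return float(2.0 * alpha - 1.0)


def rc_bray_matrix(
    table: CountTable,
    n_null: int = 1000,
    seed: int = 0,
    pool: RegionalPool | None = None,
    tie_tol: float = DEFAULT_TIE_TOL,
) -> DissimilarityMatrix:
    """RC_Bray over all unordered sample pairs.

    Each pair runs on its own substream keyed by the (sorted) sample ids,
    so the matrix is invariant to sample order and to any parallel
    schedule. The diagonal is -1: a sample is maximally more similar to
    itself than any null pair.
    """
    ids = table.sample_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    if pool is None:
        pool = build_pool(table)
    counts = table.counts.reindex(columns=pool.taxon_ids, fill_value=0)
    dropped = table.counts.drop(columns=pool.taxon_ids, errors="ignore")
    if (dropped.to_numpy() > 0).any():
        raise ValueError("table contains taxa absent from the regional pool")
    mat = np.full((len(ids), len(ids)), -1.0)
    for (i, sid), (j, sjd) in combinations(enumerate(ids), 2):
        a, b = sorted((sid, sjd))
        rng = substream_rng(seed, "rcbray", a, b)
        # pass the pair in sorted-id order so the draw stream, and hence the
        # value, is invariant to the row order of the input table
        rc = rc_bray_pair(
            counts.loc[a].to_numpy(), counts.loc[b].to_numpy(),
            pool, n_null=n_null, seed=rng, tie_tol=tie_tol,
        )
        mat[i, j] = mat[j, i] = rc
    frame = pd.DataFrame(mat, index=pd.Index(ids), columns=pd.Index(ids))
    return DissimilarityMatrix(
        data=frame, metric="rc_bray", n_null=n_null, seed=seed, tie_tol=tie_tol
    )


def bray_curtis_matrix(table: CountTable) -> DissimilarityMatrix:
    """Plain Bray-Curtis over all sample pairs (zero diagonal)."""
    ids = table.sample_ids
    arr = table.counts.to_numpy(dtype=float)
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mat[i, j] = mat[j, i] = bray_curtis(arr[i], arr[j])
    frame = pd.DataFrame(mat, index=pd.Index(ids), columns=pd.Index(ids))
    return DissimilarityMatrix(data=frame, metric="bray_curtis")


def write_dissimilarity(dm: DissimilarityMatrix, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metric: {dm.metric}\n")
        if dm.n_null is not None:
            fh.write(f"# n_null: {dm.n_null}\n# seed: {dm.seed}\n# tie_tol: {dm.tie_tol}\n")
        dm.data.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.17g")


def read_dissimilarity(path) -> DissimilarityMatrix:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition(":")
            meta[key.strip()] = val.strip()
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    frame.columns.name = None
    frame.index.name = None
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return DissimilarityMatrix(
        data=frame,
        metric=meta.get("metric", "unknown"),
        n_null=int(meta["n_null"]) if "n_null" in meta else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
        tie_tol=float(meta["tie_tol"]) if "tie_tol" in meta else None,
    )
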