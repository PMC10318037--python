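"""Principal-coordinates analysis and permutational multivariate ANOVA.

Raup-Crick matrices carry -1 on the diagonal and can be negative
off-diagonal; before eigendecomposition they are shifted by subtracting
the minimum off-diagonal value (a monotone transform that preserves rank
order) and zeroing the diagonal. The applied shift is recorded on the
result. Negative eigenvalues are reported, not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ._util import substream_rng
from .io_core import SampleMetadata
from .nullmodel import DissimilarityMatrix


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x positive-eigenvalue axes (PCoA1..)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis, of positive-eigenvalue mass
    negative_mass: float  # |sum of negative eigenvalues|
    shift: float  # off-diagonal shift applied before decomposition

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axis_scores(self, k: int = 3) -> pd.DataFrame:
        """First ``k`` axes as named predictors PCoA1..k."""
        k = min(k, self.n_axes)
        return self.coordinates.iloc[:, :k]


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # per term: df, sum_sq, r2, pseudo_f, p_value
    n_perm: int
    seed: int


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _prepare(arr: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Shift signed matrices (e.g. RC) to a zero-diagonal non-negative form."""
    n = arr.shape[0]
    off = arr[~np.eye(n, dtype=bool)]
    if off.size and (off.min() < 0 or np.abs(np.diag(arr)).max() > tol):
        shift = float(off.min())
        work = arr - shift
        np.fill_diagonal(work, 0.0)
        return work, shift
    return arr.copy(), 0.0


def pcoa(d: DissimilarityMatrix, symmetry_tol: float = 1e-8) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Double-centers -0.5 * J D^2 J, eigendecomposes, and scales each
    positive-eigenvalue eigenvector by sqrt(eigenvalue) so coordinate
    distances approximate the input.
    """
    arr = d.data.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=symmetry_tol):
        raise ValueError("asymmetric dissimilarity matrix")
    work, shift = _prepare(arr, symmetry_tol)
    b = _gower_center(work**2)
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    tol = max(np.abs(vals).max(), 1.0) * 1e-12
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    cols = [f"PCoA{i + 1}" for i in range(pos.sum())]
    pos_sum = vals[pos].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.data.index, columns=cols),
        eigenvalues=vals,
        proportion_explained=(vals[pos] / pos_sum) if pos.any() else np.array([]),
        negative_mass=float(-vals[vals < -tol].sum()),
        shift=shift,
    )


def euclidean_matrix(frame: pd.DataFrame) -> DissimilarityMatrix:
    """Euclidean distances between rows (e.g. z-scaled function profiles)."""
    d = squareform(pdist(frame.to_numpy(dtype=float)))
    return DissimilarityMatrix(
        data=pd.DataFrame(d, index=frame.index, columns=frame.index), metric="euclidean"
    )


def _model_matrices(meta: pd.DataFrame, terms: list[str], n: int) -> list[np.ndarray]:
    """Cumulative design matrices: intercept, then each term added in order."""
    mats = [np.ones((n, 1))]
    for term in terms:
        levels = meta[term].astype(str)
        uniq = levels.unique()
        if len(uniq) < 2:
            raise ValueError(f"factor {term!r} has fewer than 2 levels")
        if len(uniq) == n:
            raise ValueError(f"factor {term!r} is confounded with sample identity")
        dummies = pd.get_dummies(levels, dtype=float).to_numpy()
        mats.append(np.hstack([mats[-1], dummies]))
    return mats


def permanova(
    d: DissimilarityMatrix,
    meta: SampleMetadata,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Sequential (type-I) PERMANOVA with free row permutation.

    Partitions the Gower-centered matrix trace into sequential term sums of
    squares; the permutation p-value is (1 + #(F_perm >= F_obs)) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    ids = d.sample_ids
    mf = meta.frame.loc[ids]
    n = len(ids)
    arr = d.data.to_numpy(dtype=float)
    work, _ = _prepare(arr)
    g = _gower_center(work**2)
    mats = _model_matrices(mf, terms, n)
    hats = []
    ranks = []
    for x in mats:
        # H = X (X'X)^- X' via pinv; rank for dfs
        hats.append(x @ np.linalg.pinv(x))
        ranks.append(np.linalg.matrix_rank(x))
    dfs = [ranks[k + 1] - ranks[k] for k in range(len(terms))]
    df_res = n - ranks[-1]
    if df_res < 1:
        raise ValueError("no residual degrees of freedom")
    ss_total = float(np.trace(g))

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        model_ss = np.array([float(np.sum(h * gmat)) for h in hats])  # tr(H G), H symmetric
        term_ss = np.diff(model_ss)
        ss_res = float(np.trace(gmat)) - model_ss[-1]
        if abs(ss_res) < 1e-10 * max(abs(ss_total), 1.0):
            ss_res = 0.0  # perfect fit up to round-off; F becomes infinite
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (term_ss / np.array(dfs)) / (ss_res / df_res)
        return f, ss_res

    f_obs, ss_res_obs = stats_for(g)
    term_ss_obs = np.diff([float(np.sum(h * g)) for h in hats])
    rng = substream_rng(seed, "permanova", *terms)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        f_perm, _ = stats_for(g[np.ix_(p, p)])
        exceed += f_perm >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    tab = pd.DataFrame(
        {
            "df": dfs,
            "sum_sq": term_ss_obs,
            "r2": term_ss_obs / ss_total,
            "pseudo_f": f_obs,
            "p_value": pvals,
        },
        index=pd.Index(terms, name="term"),
    )
    tab.loc["Residual"] = [df_res, ss_res_obs, ss_res_obs / ss_total, np.nan, np.nan]
    if abs(tab["r2"].sum() - 1.0) > 1e-8:
        warnings.warn("term + residual R2 does not sum to 1 (ill-conditioned design)")
    return PermanovaResult(table=tab, n_perm=n_perm, seed=seed)
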