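"""Taxonomic aggregation, relative abundances, and derived community traits.

Counts aggregated at a rank (ASVs lacking an assignment pool into
"Unclassified" so sample sums are conserved), pseudo-counted phylum
ratios, the abundance-weighted community-mean 16S operon number, and a
simple fold-change + rank-test screen for responder taxa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import RANKS, UNCLASSIFIED, CountTable, SampleMetadata


@dataclass
class RelAbundTable:
    """Samples x taxa-at-rank relative abundances; rows sum to 1."""

    data: pd.DataFrame
    rank: str

    def __post_init__(self) -> None:
        sums = self.data.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums.index[~np.isclose(sums, 1.0, atol=1e-9)][0]
            raise ValueError(f"relative abundances of sample {bad!r} do not sum to 1")


def aggregate_rank(table: CountTable, rank: str) -> RelAbundTable:
    """Sum counts within labels at ``rank`` and divide by sample totals."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    totals = table.sample_totals()
    if (totals == 0).any():
        zero = totals.index[totals == 0][0]
        raise ValueError(f"sample {zero!r} has zero total count")
    labels = table.taxonomy[rank].reindex(table.counts.columns).fillna(UNCLASSIFIED)
    agg = table.counts.T.groupby(labels.values).sum().T
    rel = agg.div(totals, axis=0)
    return RelAbundTable(data=rel, rank=rank)


def phylum_ratio(
    rel: RelAbundTable,
    numerator: str = "Proteobacteria",
    denominator: str = "Actinobacteria",
    pseudo: float = 1e-6,
) -> pd.Series:
    """Per-sample (p_num + pseudo) / (p_den + pseudo).

    The pseudo-count keeps the ratio finite when the denominator taxon is
    absent; labels missing from the table count as zero columns.
    """
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    num = rel.data.get(numerator, pd.Series(0.0, index=rel.data.index))
    den = rel.data.get(denominator, pd.Series(0.0, index=rel.data.index))
    out = (num + pseudo) / (den + pseudo)
    out.name = f"{numerator}:{denominator}"
    return out


def mean_operon_number(table: CountTable, copy_numbers: dict[str, float]) -> pd.DataFrame:
    """Abundance-weighted mean 16S operon number per community.

    Weights are renormalized over the taxa with a known copy number; the
    covered fraction of each community is reported alongside.
    """
    known = [t for t in table.counts.columns if t in copy_numbers]
    if not known:
        raise ValueError("no taxon in the table has a known 16S copy number")
    bad = [t for t in known if copy_numbers[t] < 1]
    if bad:
        raise ValueError(f"copy numbers must be >= 1; offending taxa: {bad[:5]}")
    c = np.array([copy_numbers[t] for t in known], dtype=float)
    counts_known = table.counts[known].to_numpy(dtype=float)
    totals = table.sample_totals().to_numpy(dtype=float)
    known_totals = counts_known.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_op = (counts_known * c).sum(axis=1) / known_totals
        coverage = np.where(totals > 0, known_totals / totals, np.nan)
    return pd.DataFrame(
        {"mean_operon_number": mean_op, "coverage": coverage}, index=table.counts.index
    )


def responder_screen(
    rel: RelAbundTable,
    meta: SampleMetadata,
    group_col: str,
    group_a: str,
    group_b: str,
    min_fc: float = 1.0,
    alpha: float = 0.05,
    pseudo: float = 1e-6,
) -> pd.DataFrame:
    """Flag taxa shifted between two sample groups.

    For each taxon: log2((mean_a + pseudo)/(mean_b + pseudo)), a two-sided
    Wilcoxon rank-sum p, and a Benjamini-Hochberg q. Flagged when
    ``|log2FC| >= min_fc`` and ``q <= alpha``. Output is sorted by q then
    descending |log2FC|. This is a deliberately simple screen, not a
    count-model differential-abundance test.
    """
    ids_a = meta.frame.index[meta.frame[group_col] == group_a]
    ids_b = meta.frame.index[meta.frame[group_col] == group_b]
    ids_a = ids_a.intersection(rel.data.index)
    ids_b = ids_b.intersection(rel.data.index)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(ids_a)} {group_a!r}, {len(ids_b)} {group_b!r})"
        )
    a = rel.data.loc[ids_a]
    b = rel.data.loc[ids_b]
    log2fc = np.log2((a.mean(axis=0) + pseudo) / (b.mean(axis=0) + pseudo))
    pvals = {}
    for taxon in rel.data.columns:
        if np.ptp(np.concatenate([a[taxon], b[taxon]])) == 0:
            pvals[taxon] = 1.0  # identical values carry no evidence
        else:
            pvals[taxon] = stats.mannwhitneyu(a[taxon], b[taxon], alternative="two-sided").pvalue
    p = pd.Series(pvals)
    q = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=p.index)
    out = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "q_value": q,
            "flagged": (log2fc.abs() >= min_fc) & (q <= alpha),
        }
    )
    out.index.name = rel.rank
    return out.sort_values(["q_value", "log2_fold_change"], key=lambda s: s.abs() if s.name == "log2_fold_change" else s, ascending=[True, False])
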