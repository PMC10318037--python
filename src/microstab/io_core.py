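"""Tabular input/output, validation, and the shared data model.

All artifacts are UTF-8 TSV. ``#``-prefixed header comment lines carry
free-text metadata (units, seeds). Missing values are written as ``NA``.
Count tables are accepted taxa-as-rows (the common amplicon convention) or
samples-as-rows, and normalized internally to samples x taxa.
"""

from __future__ import annotations

import dataclasses
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "Unclassified"


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


# ---------------------------------------------------------------------------
# Count table
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Samples x taxa integer count matrix with an ASV taxonomy.

    ``counts`` is indexed by sample id with taxon ids as columns.
    ``taxonomy`` is indexed by taxon id with one column per rank in
    :data:`RANKS`; missing ranks are NA. ``report`` collects non-fatal
    validation findings (e.g. all-zero taxa).
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    report: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample identifiers: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon identifiers: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            bad = np.argwhere(~np.isfinite(arr) | (np.mod(arr, 1) != 0))
            if bad.size:
                r, c = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {self.counts.index[r]!r}, "
                    f"taxon {self.counts.columns[c]!r}: {arr[r, c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[r]!r}, "
                f"taxon {self.counts.columns[c]!r}"
            )
        present = self.counts.columns[arr.sum(axis=0) > 0]
        missing_tax = present.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValidationError(
                f"taxa with nonzero counts missing from taxonomy: {missing_tax.tolist()[:5]}"
            )
        empty = self.counts.columns[arr.sum(axis=0) == 0].tolist()
        for t in empty:
            self.report.append(f"taxon {t!r} has zero count in every sample (retained)")

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def taxon_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _parse_numeric_matrix(df: pd.DataFrame, path: str, integer: bool) -> pd.DataFrame:
    """Parse a matrix of strings to numbers, naming any offending cell."""
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col].where(df[col].notna() & (df[col] != "NA")), errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col] != "NA")
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if integer:
            if vals.isna().any():
                row = df.index[vals.isna().to_numpy().nonzero()[0][0]]
                raise ValidationError(f"{path}: missing count at row {row!r}, column {col!r}")
            frac = np.mod(vals.to_numpy(dtype=float), 1) != 0
            if frac.any():
                row = df.index[frac.nonzero()[0][0]]
                raise ValidationError(
                    f"{path}: non-integer count at row {row!r}, column {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            vals = vals.astype(np.int64)
        out[col] = vals
    return pd.DataFrame(out, index=df.index)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read taxon -> semicolon-delimited lineage into a ranks DataFrame."""
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    lineage_col = raw.columns[0]
    rows = {}
    for taxon, lineage in raw[lineage_col].items():
        parts = [] if pd.isna(lineage) else [p.strip() for p in str(lineage).split(";")]
        parts = parts + [None] * (len(RANKS) - len(parts))
        rows[taxon] = parts[: len(RANKS)]
    tax = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    if tax.index.has_duplicates:
        dups = tax.index[tax.index.duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate taxon identifiers: {dups}")
    return tax


def read_count_table(
    path: str | Path,
    taxonomy_path: str | Path,
    orientation: str = "taxa_rows",
) -> CountTable:
    """Read a TSV count matrix plus taxonomy into a validated CountTable.

    ``orientation`` declares the on-disk layout: ``"taxa_rows"`` (rows are
    taxa, the amplicon convention) or ``"samples_rows"``.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    mat = _parse_numeric_matrix(raw, str(path), integer=True)
    if orientation == "taxa_rows":
        mat = mat.T
    mat.index.name = None
    mat.columns.name = None
    taxonomy = read_taxonomy(taxonomy_path)
    return CountTable(counts=mat, taxonomy=taxonomy)


def write_count_table(table: CountTable, counts_path: str | Path, taxonomy_path: str | Path) -> None:
    """Write counts (taxa-as-rows) and taxonomy as TSV."""
    table.counts.T.to_csv(counts_path, sep="\t", index_label="taxon_id")
    lineages = table.taxonomy.apply(
        lambda r: ";".join("" if pd.isna(v) else str(v) for v in r).rstrip(";"), axis=1
    )
    pd.DataFrame({"lineage": lineages}).to_csv(taxonomy_path, sep="\t", index_label="taxon_id")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample design factors: land use, diversity level, stress, replicate."""

    frame: pd.DataFrame
    diversity_levels: tuple[str, ...] = ("D0", "D1", "D2")
    stress_levels: tuple[str, ...] = ("control", "stressed")

    def __post_init__(self) -> None:
        f = self.frame
        required = {"land_use", "diversity_level", "stress", "replicate"}
        missing = required - set(f.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample identifiers in metadata: {dups}")
        bad_div = set(f["diversity_level"]) - set(self.diversity_levels)
        if bad_div:
            raise ValidationError(f"unknown diversity levels: {sorted(bad_div)}")
        bad_stress = set(f["stress"]) - set(self.stress_levels)
        if bad_stress:
            raise ValidationError(f"unknown stress levels: {sorted(bad_stress)}")
        if (f["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be >= 1")
        f = f.copy()
        f["diversity_level"] = pd.Categorical(
            f["diversity_level"], categories=list(self.diversity_levels), ordered=True
        )
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()


def read_sample_metadata(path: str | Path, **kwargs) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={"replicate": int})
    return SampleMetadata(frame=frame, **kwargs)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Process / covariate table
# ---------------------------------------------------------------------------

#: Default units written into process-table headers.
DEFAULT_UNITS = {
    "biomass": "ug C g-1",
    "dna_yield": "ng uL-1",
    "abund_16s": "copies g-1",
    "abund_its": "copies g-1",
    "aoa": "copies g-1",
    "aob": "copies g-1",
    "tetw": "copies g-1",
    "tetm": "copies g-1",
    "mean_operon_number": "copies cell-1",
    "respiration": "ug CO2-C g-1 d-1",
    "sir": "ug CO2-C g-1 h-1",
    "bg": "nmol g-1 h-1",
    "lap": "nmol g-1 h-1",
    "nag": "nmol g-1 h-1",
    "ap": "nmol g-1 h-1",
    "nh4_t0": "mg N kg-1",
    "no3_t0": "mg N kg-1",
    "nh4_t1": "mg N kg-1",
    "no3_t1": "mg N kg-1",
    "interval_days": "d",
}

#: Covariates that are physically non-negative.
_NONNEGATIVE = (
    "biomass",
    "dna_yield",
    "abund_16s",
    "abund_its",
    "aoa",
    "aob",
    "tetw",
    "tetm",
    "nh4_t0",
    "no3_t0",
    "nh4_t1",
    "no3_t1",
)


@dataclass
class ProcessTable:
    """Per-sample measured covariates and process inputs with unit metadata.

    NA marks missing measurements; downstream stages declare their own NA
    policy. ``units`` maps column -> unit string and is round-tripped
    through ``#``-comment headers.
    """

    frame: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample identifiers in process table: {dups}")
        if "interval_days" in f.columns:
            iv = f["interval_days"].dropna()
            if (iv <= 0).any():
                raise ValidationError("interval_days must be > 0")
        if "mean_operon_number" in f.columns:
            op = f["mean_operon_number"].dropna()
            if (op < 1).any():
                raise ValidationError("mean_operon_number must be >= 1")
        for col in _NONNEGATIVE:
            if col in f.columns and (f[col].dropna() < 0).any():
                bad = f.index[(f[col] < 0).fillna(False)][0]
                raise ValidationError(f"negative value of {col!r} at sample {bad!r}")
        self.units = {**{c: DEFAULT_UNITS.get(c, "") for c in f.columns}, **self.units}

    @property
    def sample_ids(self) -> list[str]:
        return self.frame.index.tolist()


def read_process_table(path: str | Path) -> ProcessTable:
    units = {}
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("# unit:"):
            name, _, unit = line[len("# unit:") :].strip().partition("=")
            units[name.strip()] = unit.strip()
        elif not line.startswith("#"):
            break
    raw = pd.read_csv(io.StringIO(text), sep="\t", comment="#", index_col=0, dtype=str)
    frame = _parse_numeric_matrix(raw, str(path), integer=False)
    return ProcessTable(frame=frame, units=units)


def write_process_table(proc: ProcessTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, unit in proc.units.items():
            fh.write(f"# unit: {name} = {unit}\n")
        proc.frame.to_csv(fh, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings; seeds are recorded in every output artifact."""

    rarefaction_depth: int | None = None  # None -> smallest retained sample total
    rarefaction_iters: int = 1000
    null_iters: int = 1000
    rf_trees: int = 10_000
    rf_shuffles: int = 30
    n_permutations: int = 999
    pcoa_axes: int = 3
    seed: int = 0
    output_dir: str = "microstab_out"

    def __post_init__(self) -> None:
        for name in ("rarefaction_iters", "null_iters", "rf_trees", "rf_shuffles", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.rarefaction_depth is not None and self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Joining
# ---------------------------------------------------------------------------


def join_sample_frames(
    counts: CountTable, meta: SampleMetadata, proc: ProcessTable
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Inner-join metadata and process measurements on sample id.

    Returns the joined frame (sorted by sample id; includes each sample's
    total sequence count) and a report of ids dropped from each input.
    """
    ids_counts = set(counts.sample_ids)
    ids_meta = set(meta.sample_ids)
    ids_proc = set(proc.sample_ids)
    common = sorted(ids_counts & ids_meta & ids_proc)
    if not common:
        raise ValidationError("no sample ids shared among counts, metadata, and process table")
    report = {
        "dropped_from_counts": sorted(ids_counts - set(common)),
        "dropped_from_metadata": sorted(ids_meta - set(common)),
        "dropped_from_process": sorted(ids_proc - set(common)),
    }
    for side, dropped in report.items():
        if dropped:
            warnings.warn(f"{len(dropped)} sample(s) {side.replace('_', ' ')}: {dropped[:5]}")
    joined = meta.frame.loc[common].join(proc.frame.loc[common])
    joined.insert(0, "total_count", counts.sample_totals().loc[common])
    return joined, report
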