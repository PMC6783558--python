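"""Count-table, metadata and composition I/O.

The canonical in-memory containers are thin wrappers around pandas
DataFrames in a fixed taxa x samples orientation.  Readers accept tables in
either orientation and normalise; taxonomy lineages (semicolon-delimited,
domain -> genus, optional ``g__``-style rank prefixes) ride along as a
pandas Series aligned to the taxon axis.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "GROUPS",
    "CountTable",
    "CompositionTable",
    "read_count_table",
    "write_count_table",
    "read_biom_json",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_abundance_series",
    "write_abundance_series",
    "aggregate_to_rank",
    "relative_abundance",
]

#: Taxonomic ranks recognised in lineage strings, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: The three disturbance groups: never flooded, currently flooded, and
#: previously flooded but re-exposed at sampling time.
GROUPS = ("reference", "flooding", "recovery")

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


def _check_axes(df: pd.DataFrame) -> None:
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon identifiers: {dups}")
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample identifiers: {dups}")


@dataclass
class CountTable:
    """A taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon id with sample ids as columns.
    taxonomy
        Optional Series mapping taxon id -> semicolon-delimited lineage.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.counts)
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values % 1 != 0):
                bad = np.argwhere(~np.isfinite(values) | (values % 1 != 0))
                r, c = bad[0]
                raise ValueError(
                    "non-integer count at taxon "
                    f"{self.counts.index[r]!r}, sample {self.counts.columns[c]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if np.any(values < 0):
            bad = np.argwhere(values < 0)
            r, c = bad[0]
            raise ValueError(
                f"negative count at taxon {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}"
            )
        col_sums = values.sum(axis=0)
        if np.any(col_sums == 0):
            empty = self.counts.columns[col_sums == 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[:, list(sample_ids)].copy(), self.taxonomy)


@dataclass
class CompositionTable:
    """Relative abundances: same axes as :class:`CountTable`, columns sum to 1."""

    proportions: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        _check_axes(self.proportions)
        values = self.proportions.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        col_sums = values.sum(axis=0)
        if np.any(np.abs(col_sums - 1.0) > 1e-9):
            bad = self.proportions.columns[np.abs(col_sums - 1.0) > 1e-9].tolist()
            raise ValueError(f"sample columns do not sum to 1: {bad}")
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.proportions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)

    def subset_samples(self, sample_ids) -> "CompositionTable":
        return CompositionTable(
            self.proportions.loc[:, list(sample_ids)].copy(), self.taxonomy
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path, orientation: str = "taxa_by_samples") -> CountTable:
    """Read a tab-delimited count table.

    The file has one header row of sample (or taxon) ids and a first column
    of taxon (or sample) ids; an optional trailing ``taxonomy`` column
    (case-insensitive header) carries lineage strings.

    Parameters
    ----------
    orientation
        ``"taxa_by_samples"`` (rows are taxa, the canonical layout) or
        ``"samples_by_taxa"`` (rows are samples; the matrix is transposed
        on read).
    """
    if orientation not in ("taxa_by_samples", "samples_by_taxa"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    # keep_default_na=False: "NA" is a legitimate identifier (e.g. a study
    # area label), not a missing value
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False, na_values=[""])
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        if orientation == "samples_by_taxa":
            raise ValueError("taxonomy column only valid in taxa_by_samples layout")
        taxonomy = df.iloc[:, -1].astype(str)
        df = df.iloc[:, :-1]

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna().to_numpy()
        r, c = np.argwhere(mask)[0]
        raise ValueError(
            f"non-numeric count {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    frac = (numeric.to_numpy(dtype=float) % 1) != 0
    if frac.any():
        r, c = np.argwhere(frac)[0]
        raise ValueError(
            f"non-integer count {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )
    counts = numeric.astype(np.int64)
    if orientation == "samples_by_taxa":
        counts = counts.T
    counts.index.name = "taxon_id"
    return CountTable(counts, taxonomy)


def write_count_table(table: CountTable, path) -> None:
    """Write a :class:`CountTable` as TSV (taxa x samples; taxonomy last)."""
    out = table.counts.copy()
    out.index.name = "taxon_id"
    if table.taxonomy is not None:
        out["taxonomy"] = table.taxonomy
    out.to_csv(path, sep="\t")


def read_biom_json(path) -> CountTable:
    """Read a BIOM table in the JSON dialect (sparse or dense matrices)."""
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    taxon_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    matrix = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "sparse":
        for r, c, v in doc["data"]:
            matrix[int(r), int(c)] = int(v)
    else:
        matrix[:] = np.asarray(doc["data"], dtype=np.int64)
    taxonomy = None
    lineages = {}
    for row in doc["rows"]:
        md = row.get("metadata") or {}
        tax = md.get("taxonomy")
        if tax is not None:
            if isinstance(tax, (list, tuple)):
                tax = ";".join(str(t) for t in tax)
            lineages[row["id"]] = tax
    if lineages:
        taxonomy = pd.Series(lineages).reindex(taxon_ids)
    counts = pd.DataFrame(matrix, index=taxon_ids, columns=sample_ids)
    counts.index.name = "taxon_id"
    return CountTable(counts, taxonomy)


_METADATA_REQUIRED = ("sample_id", "area", "group")
_METADATA_OPTIONAL = ("elevation_m", "flooding_duration_days")


def read_sample_metadata(path) -> pd.DataFrame:
    """Read per-sample metadata (TSV) into a validated DataFrame.

    Required columns: sample_id, area, group; optional: elevation_m,
    flooding_duration_days.  Group labels are validated case-insensitively
    against :data:`GROUPS` and normalised to lowercase.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _METADATA_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    out = df.copy()
    for col in ("sample_id", "area", "group"):
        out[col] = out[col].astype(str).str.strip()
    out["group"] = out["group"].str.lower()
    bad = sorted(set(out["group"]) - set(GROUPS))
    if bad:
        raise ValueError(
            f"unknown group labels {bad}; allowed labels are {list(GROUPS)}"
        )
    if out["sample_id"].duplicated().any():
        dups = out.loc[out["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups}")
    for col in _METADATA_OPTIONAL:
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="raise")
    if "flooding_duration_days" in out.columns:
        if (out["flooding_duration_days"].dropna() < 0).any():
            raise ValueError("flooding_duration_days must be non-negative")
    return out.set_index("sample_id", drop=False)


def write_sample_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_abundance_series(path) -> pd.Series:
    """Read a per-sample total-abundance series (TSV: sample_id, abundance)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     keep_default_na=False, na_values=[""])
    series = pd.Series(
        pd.to_numeric(df.iloc[:, 1]).to_numpy(),
        index=df.iloc[:, 0].astype(str).str.strip(),
        name=df.columns[1],
    )
    return series


def write_abundance_series(series: pd.Series, path, name: str = "abundance") -> None:
    df = pd.DataFrame({"sample_id": series.index, name: series.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def parse_lineage(lineage: str) -> list[str]:
    """Split a semicolon-delimited lineage, stripping ``g__``-style prefixes."""
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return []
    parts = [p.strip() for p in str(lineage).split(";")]
    return [_RANK_PREFIX.sub("", p) for p in parts]


def aggregate_to_rank(table: CountTable, rank: str) -> CountTable:
    """Sum counts over taxa sharing the same name at ``rank``.

    Taxa unresolved at that rank are pooled per parent lineage under an
    ``unclassified_<parent>`` row, so per-sample totals are conserved
    exactly.  The aggregated table's taxonomy holds lineages truncated at
    ``rank``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {list(RANKS)}")
    if table.taxonomy is None or table.taxonomy.isna().any():
        raise ValueError("aggregate_to_rank requires taxonomy for all taxa")
    level = RANKS.index(rank)

    labels = []
    lineages = {}
    for taxon in table.taxon_ids:
        parts = parse_lineage(table.taxonomy.loc[taxon])
        name = parts[level] if level < len(parts) else ""
        if name and not name.lower().startswith("unclassified"):
            label = name
            lineages[label] = ";".join(parts[: level + 1])
        else:
            resolved = [p for p in parts[:level] if p]
            parent = resolved[-1] if resolved else "root"
            label = f"unclassified_{parent}"
            lineages[label] = ";".join(resolved + [label])
        labels.append(label)

    grouped = table.counts.groupby(pd.Index(labels, name="taxon_id"), sort=True).sum()
    taxonomy = pd.Series({t: lineages[t] for t in grouped.index})
    return CountTable(grouped, taxonomy)


def relative_abundance(table: CountTable) -> CompositionTable:
    """Convert counts to per-sample proportions (columns sum to one)."""
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        empty = sums.index[sums == 0].tolist()
        raise ValueError(f"cannot normalise zero-sum samples: {empty}")
    props = table.counts.astype(float).div(sums, axis=1)
    return CompositionTable(props, table.taxonomy)
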