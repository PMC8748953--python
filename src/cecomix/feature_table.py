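"""ASV feature tables: reading, validation, rank aggregation, relative abundance.

The root input of the pipeline is an ASV-by-sample table of non-negative
integer counts with a per-ASV taxonomic lineage (phylum … genus).  Any rank
may carry the sentinel ``"unclassified"``; ASVs sharing that sentinel at a
rank are pooled into a single ``unclassified`` row when aggregating at that
rank.  Relative abundances are percentages of a sample's total at the chosen
rank, with the unclassified bin kept in both numerator and denominator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Taxonomic ranks recognised in taxonomy columns, coarsest to finest.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Sentinel used for missing assignments at any rank.
UNCLASSIFIED = "unclassified"


class FeatureTableError(ValueError):
    """Raised when a feature table fails validation or parsing."""


@dataclass
class FeatureTable:
    """ASV × sample integer counts plus per-ASV taxonomy.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, index = ASV ids, columns = sample ids.
    taxonomy : pandas.DataFrame
        One row per ASV, columns a subset of :data:`RANKS`.  Missing ranks or
        missing values are filled with :data:`UNCLASSIFIED`.
    sequences : dict, optional
        ASV id → nucleotide string.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    sequences: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FeatureTableError("duplicate ASV ids in counts")
        if self.counts.columns.has_duplicates:
            raise FeatureTableError("duplicate sample ids in counts")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FeatureTableError("counts must be numeric")
        if values.size:
            if (values < 0).any():
                bad = self.counts.index[np.where(values < 0)[0][0]]
                raise FeatureTableError(f"negative count for ASV {bad!r}")
            if not np.allclose(values, np.round(values)):
                raise FeatureTableError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        # Align taxonomy to the count index; fill gaps with the sentinel.
        tax = self.taxonomy.reindex(self.counts.index)
        for rank in RANKS:
            if rank not in tax.columns:
                tax[rank] = UNCLASSIFIED
        tax = tax[list(RANKS)].fillna(UNCLASSIFIED)
        tax = tax.where(tax.astype(str).apply(lambda c: c.str.strip()) != "",
                        UNCLASSIFIED)
        self.taxonomy = tax.astype(str)
        # canonical (nameless) axes so round-tripped tables compare equal
        for df in (self.counts, self.taxonomy):
            df.index.name = None
            df.columns.name = None

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def library_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)


@dataclass
class RelativeAbundanceTable:
    """Taxon × sample percentages at a single rank.

    Every column sums to 100 (to within 1e-9); all-zero samples are rejected
    upstream.  ``taxa`` may include the ``unclassified`` bin.
    """

    rank: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if vals.size:
            if (vals < 0).any():
                raise FeatureTableError("relative abundances must be >= 0")
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 100.0, atol=1e-9):
                bad = self.values.columns[int(np.argmax(np.abs(sums - 100)))]
                raise FeatureTableError(
                    f"column {bad!r} sums to {sums.max():.6f}, not 100")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def proportions(self) -> pd.DataFrame:
        """Values on the 0–1 proportion scale (percent / 100)."""
        return self.values / 100.0


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, format: str | None = None) -> FeatureTable:
    """Read a feature table from TSV or BIOM-JSON (v1.0).

    TSV layout: first column ASV id, then one column per sample, then trailing
    taxonomy columns named by rank (``phylum`` … ``genus``, any subset,
    case-insensitive).  When ``format`` is None it is inferred from the file
    suffix (``.biom``/``.json`` → BIOM-JSON, otherwise TSV).
    """
    path = Path(path)
    if not path.exists():
        raise FeatureTableError(f"no such file: {path}")
    if format is None:
        format = "biom-json" if path.suffix in {".biom", ".json"} else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise FeatureTableError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> FeatureTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FeatureTableError(f"cannot parse {path}: {exc}") from exc
    lower = {c.lower(): c for c in df.columns}
    tax_cols = [lower[r] for r in RANKS if r in lower]
    sample_cols = [c for c in df.columns if c not in tax_cols]
    taxonomy = df[tax_cols].rename(columns={lower[r]: r for r in RANKS
                                            if r in lower})
    counts = df[sample_cols]
    numeric = counts.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = next(zip(*np.where(numeric.isna().to_numpy())))
        raise FeatureTableError(
            f"non-numeric count at ASV {counts.index[row]!r}, "
            f"sample {counts.columns[col]!r}")
    return FeatureTable(counts=numeric, taxonomy=taxonomy)


def _read_biom_json(path: Path) -> FeatureTable:
    """Minimal reader for the BIOM v1.0 JSON schema (dense or sparse)."""
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FeatureTableError(f"cannot parse {path}: {exc}") from exc
    for key in ("rows", "columns", "data", "shape", "matrix_type"):
        if key not in doc:
            raise FeatureTableError(f"BIOM file missing field {key!r}")
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    mat = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise FeatureTableError(f"unknown matrix_type {doc['matrix_type']!r}")
    tax_rows = {}
    for r in doc["rows"]:
        meta = (r.get("metadata") or {})
        lineage = meta.get("taxonomy", {})
        if isinstance(lineage, list):
            lineage = dict(zip(RANKS, lineage))
        tax_rows[r["id"]] = {rank: lineage.get(rank, UNCLASSIFIED)
                             for rank in RANKS}
    counts = pd.DataFrame(mat, index=asv_ids, columns=sample_ids)
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")
    return FeatureTable(counts=counts, taxonomy=taxonomy)


def write_feature_table_tsv(table: FeatureTable, path: str | Path) -> None:
    out = table.counts.copy()
    for rank in RANKS:
        out[rank] = table.taxonomy[rank]
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t")


def write_feature_table_biom(table: FeatureTable, path: str | Path) -> None:
    """Write the BIOM v1.0 JSON (dense) encoding of a table."""
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "cecomix",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [len(table.asv_ids), len(table.sample_ids)],
        "rows": [
            {"id": asv,
             "metadata": {"taxonomy": table.taxonomy.loc[asv].to_dict()}}
            for asv in table.asv_ids
        ],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": table.counts.to_numpy().tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def read_sample_metadata(path: str | Path) -> pd.Series:
    """Read a two-column TSV mapping sample_id → group label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FeatureTableError("metadata needs sample_id and group columns")
    meta = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")
    if meta.index.has_duplicates:
        raise FeatureTableError("duplicate sample ids in metadata")
    return meta


# ---------------------------------------------------------------------------
# Aggregation and relative abundance
# ---------------------------------------------------------------------------

def aggregate_by_rank(table: FeatureTable, rank: str) -> pd.DataFrame:
    """Sum ASV counts into taxa at ``rank`` (sentinel pools into one row).

    Column sums are conserved: at every rank, each sample keeps its library
    size.  Rank ``"asv"`` returns a copy of the ASV counts.
    """
    if rank == "asv":
        return table.counts.copy()
    if rank not in RANKS:
        raise FeatureTableError(f"unknown rank {rank!r}")
    labels = table.taxonomy[rank]
    agg = table.counts.groupby(labels).sum()
    agg.index.name = rank
    # Stable, readable ordering: by decreasing total, unclassified last.
    totals = agg.sum(axis=1)
    order = sorted(agg.index,
                   key=lambda t: (t == UNCLASSIFIED, -totals[t], t))
    return agg.loc[order]


def relative_abundance(counts: pd.DataFrame, rank: str = "asv") -> RelativeAbundanceTable:
    """Convert a taxon × sample count matrix to percentages per sample.

    Each taxon's counts are divided by the sample's total across all taxa at
    the rank (unclassified included) and multiplied by 100.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise FeatureTableError(
            f"sample(s) with zero total counts: {list(zero.index)}")
    values = counts.div(totals, axis=1) * 100.0
    return RelativeAbundanceTable(rank=rank, values=values)


def observed_richness(table: FeatureTable) -> pd.Series:
    """Per-sample count of distinct ASVs present (count > 0).

    ASVs whose entire lineage is unclassified are excluded, mirroring the
    convention of excluding unassignable sequences from observed richness.
    """
    fully_unclassified = (table.taxonomy == UNCLASSIFIED).all(axis=1)
    counts = table.counts.loc[~fully_unclassified]
    rich = (counts > 0).sum(axis=0)
    rich.name = "observed_richness"
    return rich


def fb_ratio(relab: RelativeAbundanceTable,
             firmicutes: str = "Firmicutes",
             bacteroidetes: str = "Bacteroidetes") -> pd.Series:
    """Per-sample Firmicutes:Bacteroidetes ratio from a phylum-rank table.

    Samples with zero Bacteroidetes get ``NaN`` (undefined), never infinity.
    """
    if relab.rank != "phylum":
        raise FeatureTableError("fb_ratio requires a phylum-rank table")
    for name in (firmicutes, bacteroidetes):
        if name not in relab.values.index:
            raise FeatureTableError(f"missing phylum row {name!r}")
    f = relab.values.loc[firmicutes]
    b = relab.values.loc[bacteroidetes]
    ratio = f / b.where(b > 0)
    ratio.name = "fb_ratio"
    return ratio
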