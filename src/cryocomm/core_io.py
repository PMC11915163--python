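"""Core data model and I/O for marker-gene community tables.

The universal object is the :class:`CountTable`: a taxa-by-samples matrix of
non-negative values carrying a unit tag (``reads``, ``relative_fraction`` or
``copies_per_ml``).  Around it sit a taxonomy table (ZOTU -> ranked lineage),
a per-sample qPCR table (16S / 18S gene copies per mL) and per-sample period
metadata.  Readers accept tab-separated files and BIOM-style JSON; writers
emit TSV.  Organelle filtering and qPCR absolute-abundance integration live
here because every downstream stage consumes their output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

VALID_UNITS = frozenset({"reads", "relative_fraction", "copies_per_ml"})

ORGANELLE_MARKERS = ("chloroplast", "mitochondria")


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the offending field."""


@dataclass(frozen=True)
class CountTable:
    """Taxa x samples abundance matrix with a unit tag.

    ``data`` is a pandas DataFrame indexed by taxon id with sample-id
    columns; values are non-negative floats.  Row and column order are
    preserved from the source.
    """

    data: pd.DataFrame
    unit: str = "reads"

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("count table must have at least one taxon and one sample")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("count table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at taxon {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.unit == "relative_fraction":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.columns[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(f"relative fractions of sample {bad!r} do not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in table: {missing}")
        return replace(self, data=self.data[list(samples)])

    def subset_taxa(self, taxa: Sequence[str]) -> "CountTable":
        missing = [t for t in taxa if t not in self.data.index]
        if missing:
            raise ValidationError(f"taxa not in table: {missing}")
        return replace(self, data=self.data.loc[list(taxa)])

    def drop_taxa(self, taxa: Sequence[str]) -> "CountTable":
        keep = [t for t in self.data.index if t not in set(taxa)]
        if not keep:
            raise ValidationError("dropping these taxa would empty the table")
        return replace(self, data=self.data.loc[keep])


@dataclass(frozen=True)
class TaxonomyTable:
    """taxon id -> lineage mapping over the six standard ranks."""

    lineages: pd.DataFrame  # index: taxon id; columns: RANKS

    def __post_init__(self) -> None:
        if self.lineages.index.has_duplicates:
            raise ValidationError("duplicate taxon ids in taxonomy")
        missing = [r for r in RANKS if r not in self.lineages.columns]
        if missing:
            raise ValidationError(f"taxonomy missing ranks: {missing}")

    def lineage(self, taxon_id: str) -> dict[str, str]:
        return self.lineages.loc[taxon_id, list(RANKS)].to_dict()

    def rank_of(self, taxon_id: str, rank: str) -> str:
        return str(self.lineages.at[taxon_id, rank])

    def taxa_in(self, rank: str, label: str) -> list[str]:
        col = self.lineages[rank].astype(str)
        return list(self.lineages.index[col == label])

    def require(self, taxa: Sequence[str]) -> None:
        missing = [t for t in taxa if t not in self.lineages.index]
        if missing:
            raise ValidationError(f"taxa missing from taxonomy: {missing}")


@dataclass(frozen=True)
class QpcrTable:
    """Per-sample 16S and 18S rRNA gene copies per millilitre."""

    copies: pd.DataFrame  # index: sample id; columns: marker_16S, marker_18S

    def __post_init__(self) -> None:
        for col in ("marker_16S", "marker_18S"):
            if col not in self.copies.columns:
                raise ValidationError(f"qPCR table missing column {col!r}")
        if (self.copies[["marker_16S", "marker_18S"]].to_numpy() < 0).any():
            raise ValidationError("qPCR copies must be non-negative")

    def marker(self, sample_id: str, marker: str) -> float:
        return float(self.copies.at[sample_id, marker])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample period labels (e.g. accumulation / melt / late_melt)."""

    periods: pd.Series  # index: sample id; values: period label
    period_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.periods.index.has_duplicates:
            raise ValidationError("duplicate sample ids in metadata")
        order = self.period_order or tuple(dict.fromkeys(self.periods))
        object.__setattr__(self, "period_order", tuple(order))

    def period_of(self, sample_id: str) -> str:
        return str(self.periods.at[sample_id])

    def samples_in(self, period: str) -> list[str]:
        return list(self.periods.index[self.periods == period])

    def require(self, samples: Sequence[str]) -> None:
        missing = [s for s in samples if s not in self.periods.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, format: str = "tsv", unit: str = "reads") -> CountTable:
    """Read a taxa-by-samples table from TSV or BIOM-style JSON.

    TSV dialect: UTF-8, tab-separated, first column taxon id, header row of
    sample ids.  BIOM-JSON: the minimal dense/sparse JSON layout with
    ``rows``, ``columns`` and ``data`` keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        non_numeric = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(non_numeric):
            raise ParseError(f"non-numeric values in column(s) {list(non_numeric)} of {path}")
        df = df.astype(float)
    elif format == "biom-json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        for key in ("rows", "columns", "data"):
            if key not in doc:
                raise ParseError(f"BIOM JSON {path} missing key {key!r}")
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(mat, index=taxa, columns=samples)
    else:
        raise ValueError(f"unsupported format {format!r}")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns.name = None
    return CountTable(data=df, unit=unit)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read a taxonomy TSV: either one column per rank, or a QIIME-style
    semicolon-separated lineage string in a single ``lineage``/``taxonomy``
    column (``d__Bacteria;p__Cyanobacteria;...`` prefixes tolerated)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("unclassified")
    df.index = df.index.astype(str)
    df.index.name = None
    cols_lower = {c.lower(): c for c in df.columns}
    if all(r in cols_lower for r in RANKS):
        out = df.rename(columns={cols_lower[r]: r for r in RANKS})[list(RANKS)]
    elif "lineage" in cols_lower or "taxonomy" in cols_lower:
        col = cols_lower.get("lineage", cols_lower.get("taxonomy"))
        parsed = []
        for lin in df[col]:
            parts = [p.strip() for p in str(lin).split(";")]
            parts = [p.split("__", 1)[1] if "__" in p else p for p in parts]
            parts = [(p if p else "unclassified") for p in parts]
            parts = (parts + ["unclassified"] * len(RANKS))[: len(RANKS)]
            parsed.append(parts)
        out = pd.DataFrame(parsed, index=df.index, columns=list(RANKS))
    else:
        raise ParseError(
            f"taxonomy file {path} must provide rank columns {RANKS} or a 'lineage' column"
        )
    return TaxonomyTable(lineages=out)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    df = tax.lineages.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_qpcr(path: str | Path) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return QpcrTable(copies=df)


def write_qpcr(qpcr: QpcrTable, path: str | Path) -> None:
    df = qpcr.copies.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "period" not in df.columns:
        raise ParseError(f"metadata file {path} must have a 'period' column")
    return SampleMetadata(periods=df["period"])


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.periods.to_frame("period")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def filter_organelles(table: CountTable, tax: TaxonomyTable) -> CountTable:
    """Drop taxa whose lineage names chloroplasts or mitochondria.

    Matching is case-insensitive substring search at every rank, so lineages
    annotated e.g. at the order rank as ``Chloroplast`` are caught.
    Idempotent by construction.
    """
    tax.require(table.taxon_ids)
    lin = tax.lineages.loc[table.taxon_ids].astype(str)
    joined = lin.apply(lambda row: ";".join(row).lower(), axis=1)
    is_organelle = joined.str.contains("|".join(ORGANELLE_MARKERS), regex=True)
    keep = [t for t, bad in zip(table.taxon_ids, is_organelle) if not bad]
    if not keep:
        raise ValidationError("all taxa are organelle-annotated; nothing left")
    return replace(table, data=table.data.loc[keep])


def to_relative(table: CountTable) -> CountTable:
    """Normalise each sample column to relative fractions summing to 1."""
    values = table.values
    sums = values.sum(axis=0)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValidationError(f"all-zero sample(s): {[table.sample_ids[i] for i in zero]}")
    frac = values / sums
    return CountTable(data=pd.DataFrame(frac, index=table.data.index, columns=table.data.columns),
                      unit="relative_fraction")


def integrate_qpcr(prok: CountTable, euk: CountTable, qpcr: QpcrTable) -> CountTable:
    """Scale per-marker relative fractions by qPCR gene copies per mL.

    Prokaryote fractions are scaled by each sample's 16S copies/mL and
    eukaryote fractions by its 18S copies/mL; the two tables are then
    row-concatenated.  Per sample, the output total equals
    ``marker_16S + marker_18S`` exactly.
    """
    if list(prok.sample_ids) != list(euk.sample_ids):
        raise ValidationError("prokaryote and eukaryote tables must share sample ids in order")
    overlap = set(prok.taxon_ids) & set(euk.taxon_ids)
    if overlap:
        raise ValidationError(f"overlapping taxon ids between markers: {sorted(overlap)}")
    missing = [s for s in prok.sample_ids if s not in qpcr.copies.index]
    if missing:
        raise ValidationError(f"samples missing from qPCR table: {missing}")

    blocks = []
    for tbl, marker in ((prok, "marker_16S"), (euk, "marker_18S")):
        rel = tbl if tbl.unit == "relative_fraction" else to_relative(tbl)
        scale = qpcr.copies.loc[list(tbl.sample_ids), marker].to_numpy(dtype=float)
        blocks.append(pd.DataFrame(rel.values * scale, index=tbl.data.index,
                                   columns=tbl.data.columns))
    merged = pd.concat(blocks, axis=0)
    return CountTable(data=merged, unit="copies_per_ml")


def aggregate_by_rank(table: CountTable, tax: TaxonomyTable, rank: str) -> CountTable:
    """Sum rows within identical rank labels.

    ``unclassified`` labels are kept distinct per parent lineage (an
    unclassified phylum under Bacteria is not pooled with one under
    Eukaryota), written as ``unclassified (<parent lineage>)``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; must be one of {RANKS}")
    tax.require(table.taxon_ids)
    idx = RANKS.index(rank)
    labels = []
    for t in table.taxon_ids:
        label = tax.rank_of(t, rank)
        if label.lower() == "unclassified":
            parent = ";".join(str(tax.rank_of(t, r)) for r in RANKS[:idx])
            label = f"unclassified ({parent})" if parent else "unclassified"
        labels.append(label)
    grouped = table.data.groupby(pd.Index(labels, name=rank), sort=False).sum()
    return replace(table, data=grouped)
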