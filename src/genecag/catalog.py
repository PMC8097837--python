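"""Gene catalog and translated-alignment table I/O.

The gene catalog is the deduplicated set of protein-coding sequences used
as the alignment reference. Each entry carries the amino-acid length (used
for depth normalization) and optional taxonomic / functional annotations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

ALIGNMENT_COLUMNS = [
    "specimen",
    "read_id",
    "gene_id",
    "score",
    "gene_start",
    "gene_end",
    "aligned_bases",
]


class GeneCatalog:
    """Deduplicated protein-coding gene reference.

    Parameters
    ----------
    table:
        DataFrame with columns ``gene_id``, ``length_aa`` and optionally
        ``taxon`` and ``function``. ``gene_id`` must be unique and
        ``length_aa`` a positive integer (amino acids).
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "gene_id" not in table.columns or "length_aa" not in table.columns:
            raise ValueError("catalog requires 'gene_id' and 'length_aa' columns")
        if table["gene_id"].duplicated().any():
            dups = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene_id(s) in catalog: {dups[:5]}")
        if (table["length_aa"] < 1).any():
            raise ValueError("length_aa must be >= 1 for every gene")
        for col in ("taxon", "function"):
            if col not in table.columns:
                table[col] = pd.NA
        self.table = table.set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def length_aa(self, gene_id: str) -> int:
        try:
            return int(self.table.at[gene_id, "length_aa"])
        except KeyError:
            raise KeyError(f"gene_id not in catalog: {gene_id!r}") from None

    def lengths(self) -> pd.Series:
        """Amino-acid lengths indexed by gene_id."""
        return self.table["length_aa"].astype(int)

    def validate_gene_ids(self, gene_ids: Iterable[str]) -> None:
        unknown = pd.Index(pd.unique(pd.Series(list(gene_ids)))).difference(self.table.index)
        if len(unknown):
            raise KeyError(f"gene_id(s) not in catalog: {sorted(unknown)[:5]}")

    def genes_with_label(self, label: str, kind: str) -> pd.Index:
        """Gene ids annotated with `label` under `kind` ('taxon'|'function')."""
        if kind not in ("taxon", "function"):
            raise ValueError("kind must be 'taxon' or 'function'")
        col = self.table[kind]
        return self.table.index[col == label]


def read_catalog(path: str | Path) -> GeneCatalog:
    """Read a catalog from a tab-separated table (gzip transparently handled).

    Expected columns: gene_id, length_aa[, taxon, function].
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return GeneCatalog(table)


def catalog_from_fasta(fasta_path: str | Path, annotations: pd.DataFrame | None = None) -> GeneCatalog:
    """Build a catalog from a protein FASTA, lengths taken from the sequences.

    `annotations`, if given, is a sidecar table with gene_id plus
    taxon/function columns merged onto the FASTA-derived entries.
    """
    from Bio import SeqIO

    rows = [
        {"gene_id": rec.id, "length_aa": len(rec.seq)}
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    table = pd.DataFrame(rows)
    if annotations is not None:
        table = table.merge(annotations, on="gene_id", how="left")
    return GeneCatalog(table)


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Read a translated-alignment table (TSV, gzip tolerated).

    Columns: specimen, read_id, gene_id, score, gene_start, gene_end,
    aligned_bases. Coordinates are 1-based inclusive on the amino-acid
    axis of the gene; aligned_bases counts nucleotides.
    """
    aln = pd.read_csv(path, sep="\t", dtype={"specimen": str, "read_id": str, "gene_id": str})
    missing = [c for c in ALIGNMENT_COLUMNS if c not in aln.columns]
    if missing:
        raise ValueError(f"alignment table missing column(s): {missing}")
    return aln[ALIGNMENT_COLUMNS]


def validate_alignments(aln: pd.DataFrame, catalog: GeneCatalog) -> None:
    """Check coordinate and unit invariants of an alignment table."""
    catalog.validate_gene_ids(aln["gene_id"])
    if (aln["aligned_bases"] <= 0).any():
        raise ValueError("aligned_bases must be positive")
    if (aln["gene_start"] < 1).any():
        raise ValueError("gene_start must be >= 1 (1-based inclusive)")
    if (aln["gene_end"] < aln["gene_start"]).any():
        raise ValueError("gene_end must be >= gene_start")
    lengths = catalog.lengths().reindex(aln["gene_id"]).to_numpy()
    if (aln["gene_end"].to_numpy() > lengths).any():
        raise ValueError("alignment extends past the end of the gene")
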