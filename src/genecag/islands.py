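"""Genomic island detection from gene-to-genome alignments.

Member genes of outcome-associated CAGs are aligned against reference
genomes; rather than scattering, they tend to concentrate in contiguous
regions ("islands", typically tens of kilobases). This module summarizes
how much of each genome is covered by associated genes, merges nearby
alignments into islands, attaches reference GFF3 annotations, and
classifies CAGs as core (present in essentially all reference genomes of
the focal taxon) or accessory / strain-specific.

All coordinates are 1-based inclusive nucleotide positions (GFF
convention); the gap between intervals [.., e1] and [s2, ..] is
s2 - e1 - 1, so abutting intervals have gap 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOME_ALIGNMENT_COLUMNS = [
    "gene_id",
    "genome_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "pct_identity",
]

GFF3_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


@dataclass
class GenomeSummary:
    genome_id: str
    total_length: int
    aligned_associated_bases: int
    proportion_associated: float


@dataclass
class Island:
    genome_id: str
    contig_id: str
    start: int
    end: int
    member_genes: set[str]
    cag_ids: set[str]
    features: list[dict] = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class OccurrenceProfile:
    cag_id: str
    genomes_present: float
    specimens_present: float
    classification: str


def _union_length(intervals: np.ndarray) -> int:
    """Total bases covered by a set of 1-based inclusive intervals."""
    if len(intervals) == 0:
        return 0
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    total = 0
    cur_s, cur_e = intervals[order[0]]
    for i in order[1:]:
        s, e = intervals[i]
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return int(total)


def summarize_genome(
    alignments: pd.DataFrame, associated_genes: set[str], total_length: int
) -> GenomeSummary:
    """Fraction of one genome covered by alignments of associated genes.

    Overlapping alignment intervals are counted once (union semantics);
    the union is taken per contig.
    """
    if total_length <= 0:
        raise ValueError("total_length must be positive")
    genome_ids = alignments["genome_id"].unique()
    if len(genome_ids) > 1:
        raise ValueError("summarize_genome expects records of a single genome")
    assoc = alignments[alignments["gene_id"].isin(associated_genes)]
    covered = sum(
        _union_length(sub[["start", "end"]].to_numpy(dtype=np.int64))
        for _, sub in assoc.groupby("contig_id")
    )
    return GenomeSummary(
        genome_id=str(genome_ids[0]) if len(genome_ids) else "",
        total_length=int(total_length),
        aligned_associated_bases=int(covered),
        proportion_associated=covered / total_length,
    )


def detect_islands(
    alignments: pd.DataFrame,
    max_gap: int = 5000,
    gene_to_cag: dict[str, str] | None = None,
) -> list[Island]:
    """Merge nearby alignments of associated genes into islands.

    Single-linkage along each contig: consecutive alignments whose
    interval gap (start2 - end1 - 1) is <= max_gap join the same island.
    Strand is ignored — an island is a physical region and genes on either
    strand co-locate. Islands never span contigs. Results are sorted by
    (genome, contig, start), so output is independent of input order.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    islands: list[Island] = []
    for (genome, contig), sub in alignments.groupby(["genome_id", "contig_id"], sort=True):
        sub = sub.sort_values(["start", "end", "gene_id"], kind="mergesort")
        cur: Island | None = None
        for row in sub.itertuples(index=False):
            if cur is not None and row.start - cur.end - 1 <= max_gap:
                cur.end = max(cur.end, int(row.end))
                cur.member_genes.add(row.gene_id)
            else:
                if cur is not None:
                    islands.append(cur)
                cur = Island(
                    genome_id=str(genome),
                    contig_id=str(contig),
                    start=int(row.start),
                    end=int(row.end),
                    member_genes={row.gene_id},
                    cag_ids=set(),
                )
            if cur is not None:
                cur.end = max(cur.end, int(row.end))
        if cur is not None:
            islands.append(cur)
    if gene_to_cag:
        for isl in islands:
            isl.cag_ids = {gene_to_cag[g] for g in isl.member_genes if g in gene_to_cag}
    return islands


def classify_core_accessory(
    cag_id: str,
    genome_hits: pd.Series | dict,
    specimen_detection: pd.Series | dict,
    core_genome_fraction: float = 0.9,
) -> OccurrenceProfile:
    """Classify a CAG as core or accessory by reference-genome occurrence.

    `genome_hits` maps genome_id -> bool (any member-gene alignment);
    `specimen_detection` maps specimen -> bool (CAG detected). A CAG found
    in at least `core_genome_fraction` of the evaluated genomes of the
    focal taxon is core; otherwise accessory (strain-specific).
    """
    gh = pd.Series(genome_hits, dtype=bool)
    sd = pd.Series(specimen_detection, dtype=bool)
    if len(gh) == 0:
        raise ValueError("at least one genome must be evaluated")
    genomes_present = float(gh.mean())
    specimens_present = float(sd.mean()) if len(sd) else 0.0
    cls = "core" if genomes_present >= core_genome_fraction else "accessory"
    return OccurrenceProfile(cag_id, genomes_present, specimens_present, cls)


def read_gff3(path) -> pd.DataFrame:
    """Read a GFF3 feature table, raising on malformed lines with line numbers.

    Only the 9 standard columns are interpreted; attributes are parsed as
    key=value pairs with 'product' and 'ID' lifted into columns.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"malformed GFF3 line {lineno}: expected 9 columns, got {len(parts)}")
            rec = dict(zip(GFF3_COLUMNS, parts))
            try:
                rec["start"] = int(rec["start"])
                rec["end"] = int(rec["end"])
            except ValueError:
                raise ValueError(f"malformed GFF3 line {lineno}: non-integer coordinates") from None
            if rec["end"] < rec["start"] or rec["start"] < 1:
                raise ValueError(f"malformed GFF3 line {lineno}: bad interval {rec['start']}..{rec['end']}")
            attrs = dict(
                kv.split("=", 1) for kv in rec["attributes"].split(";") if "=" in kv
            )
            rec["feature_id"] = attrs.get("ID", "")
            rec["product"] = attrs.get("product", "")
            rows.append(rec)
    return pd.DataFrame(rows, columns=GFF3_COLUMNS + ["feature_id", "product"])


def annotate_islands(islands: list[Island], features: pd.DataFrame) -> list[Island]:
    """Attach overlapping GFF3 features (>= 1 bp, inclusive bounds) to islands."""
    for isl in islands:
        sub = features[features["seqid"] == isl.contig_id]
        hit = sub[(sub["start"] <= isl.end) & (sub["end"] >= isl.start)]
        isl.features = [
            {
                "type": r.type,
                "start": int(r.start),
                "end": int(r.end),
                "feature_id": r.feature_id,
                "product": r.product,
            }
            for r in hit.itertuples(index=False)
        ]
    return islands


def islands_to_frame(islands: list[Island]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": i.genome_id,
            "contig_id": i.contig_id,
            "start": i.start,
            "end": i.end,
            "span_bp": i.span_bp,
            "n_genes": len(i.member_genes),
            "member_genes": ",".join(sorted(i.member_genes)),
            "cag_ids": ",".join(sorted(i.cag_ids)),
        }
        for i in islands
    ]
    return pd.DataFrame(
        rows,
        columns=["genome_id", "contig_id", "start", "end", "span_bp", "n_genes", "member_genes", "cag_ids"],
    )
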