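"""Per-specimen gene depth and relative abundance.

Raw translated alignments of short reads against a protein gene catalog
contain multi-mapping reads: reads aligning comparably well to several
homologous genes. These are resolved to a single gene per read by an
iterative expectation-maximization procedure whose target metric is
evenness of sequencing coverage along each gene: genes that are genuinely
present accumulate even coverage from many reads, while spurious homologs
show patchy coverage concentrated in the conserved region that attracted
the multi-mapping reads.

Depth is then the classic length-normalized measure: aligned bases divided
by gene length (in nucleotides, i.e. 3x the amino-acid length of the
catalog entry), and relative abundance is depth normalized to sum to one
within each specimen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import GeneCatalog, validate_alignments


class AbundanceMatrix:
    """Specimen x gene depth and relative abundance.

    ``depth`` is length-normalized sequencing depth (aligned nucleotides /
    nucleotide gene length); ``rel_abund`` divides each specimen row by its
    total so rows of detected specimens sum to 1.
    """

    def __init__(self, depth: pd.DataFrame, rel_abund: pd.DataFrame | None = None):
        self.depth = depth
        self.rel_abund = rel_abund

    @property
    def specimens(self) -> pd.Index:
        return self.depth.index

    @property
    def genes(self) -> pd.Index:
        return self.depth.columns

    def detected_genes(self, specimen: str) -> set[str]:
        """Genes with positive post-resolution depth in `specimen`."""
        if specimen not in self.depth.index:
            raise KeyError(f"unknown specimen: {specimen!r}")
        row = self.depth.loc[specimen]
        return set(row.index[row > 0])


def _coverage_scores(
    aln: pd.DataFrame,
    weights: np.ndarray,
    gene_index: pd.Index,
    offsets: np.ndarray,
    slice_lengths: np.ndarray,
) -> np.ndarray:
    """Score each gene as (mean coverage) / (1 + CV of per-position coverage).

    Coverage is accumulated per amino-acid position from weighted candidate
    alignments using a difference-array trick over one concatenated vector
    (each gene's slice has length_aa + 1 slots; the +w/-w pairs cancel
    within a slice so a single cumsum is safe).
    """
    total = int(offsets[-1] + slice_lengths[-1])
    diff = np.zeros(total)
    gpos = offsets[aln["_gene_pos"].to_numpy()]
    np.add.at(diff, gpos + aln["gene_start"].to_numpy() - 1, weights)
    np.add.at(diff, gpos + aln["gene_end"].to_numpy(), -weights)
    cov = np.cumsum(diff)

    starts = offsets
    ends = offsets + slice_lengths - 1  # last slot of each slice is padding
    idx = np.empty(2 * len(starts), dtype=np.int64)
    idx[0::2] = starts
    idx[1::2] = ends
    sums = np.add.reduceat(cov, idx)[0::2]
    sq = np.add.reduceat(cov * cov, idx)[0::2]
    n = (slice_lengths - 1).astype(float)
    mean = sums / n
    var = np.maximum(sq / n - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
    return np.where(mean > 0, mean / (1.0 + cv), 0.0)


def _resolve_one_specimen(
    aln: pd.DataFrame, catalog: GeneCatalog, max_iter: int, tol: float
) -> pd.DataFrame:
    genes = pd.Index(np.sort(aln["gene_id"].unique()))
    lengths = catalog.lengths().reindex(genes).to_numpy(dtype=np.int64)
    slice_lengths = lengths + 1
    offsets = np.concatenate([[0], np.cumsum(slice_lengths)[:-1]])
    aln = aln.copy()
    aln["_gene_pos"] = genes.get_indexer(aln["gene_id"])

    # initial weights proportional to alignment score, normalized per read
    score = aln["score"].to_numpy(dtype=float)
    per_read_total = aln.groupby("read_id")["score"].transform("sum").to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        weights = np.where(per_read_total > 0, score / per_read_total, np.nan)
    # all-zero-score reads: uniform over candidates
    n_cand = aln.groupby("read_id")["score"].transform("size").to_numpy()
    weights = np.where(np.isnan(weights), 1.0 / n_cand, weights)

    chosen_prev: np.ndarray | None = None
    for _ in range(max_iter):
        gene_scores = _coverage_scores(aln, weights, genes, offsets, slice_lengths)
        aln["_gscore"] = gene_scores[aln["_gene_pos"].to_numpy()]
        # winner per read: highest coverage-evenness score, ties to the
        # lexicographically smaller gene_id
        order = aln.sort_values(
            ["read_id", "_gscore", "gene_id"], ascending=[True, False, True], kind="mergesort"
        )
        winners = order.drop_duplicates("read_id")
        chosen = winners.index.to_numpy()
        new_weights = np.zeros(len(aln))
        new_weights[aln.index.get_indexer(chosen)] = 1.0
        if chosen_prev is not None and np.array_equal(chosen, chosen_prev):
            break
        if np.abs(new_weights - weights).max() < tol:
            weights = new_weights
            break
        weights = new_weights
        chosen_prev = chosen

    keep = aln.loc[weights > 0.5] if (weights > 0.5).any() else aln.iloc[:0]
    return keep[["specimen", "read_id", "gene_id", "aligned_bases"]]


def resolve_multimappers(
    alignments: pd.DataFrame,
    catalog: GeneCatalog,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Resolve each read to a single catalog gene per specimen.

    Parameters
    ----------
    alignments:
        Candidate alignment records (specimen, read_id, gene_id, score,
        gene_start, gene_end, aligned_bases); a read may appear on several
        genes. Resolution is independent per specimen.
    catalog:
        Reference catalog; every gene_id must be present (unknown ids raise).
    max_iter, tol:
        Iteration cap and weight-change convergence tolerance.

    Returns
    -------
    DataFrame of resolved assignments (specimen, read_id, gene_id,
    aligned_bases), one row per retained read. Uniquely-mapped reads are
    always retained on their sole gene; the procedure is deterministic
    given input order (ties broken lexicographically by gene_id).
    """
    if len(alignments) == 0:
        return pd.DataFrame(columns=["specimen", "read_id", "gene_id", "aligned_bases"])
    validate_alignments(alignments, catalog)
    parts = [
        _resolve_one_specimen(group.reset_index(drop=True), catalog, max_iter, tol)
        for _, group in alignments.groupby("specimen", sort=True)
    ]
    out = pd.concat(parts, ignore_index=True)
    return out


def compute_depth(assignments: pd.DataFrame, catalog: GeneCatalog) -> AbundanceMatrix:
    """Length-normalized sequencing depth per specimen and gene.

    depth(s, g) = sum of aligned_bases of reads of specimen s assigned to g,
    divided by the nucleotide gene length 3 * length_aa(g). Genes of the
    catalog with no assigned reads get depth 0.
    """
    catalog.validate_gene_ids(assignments["gene_id"]) if len(assignments) else None
    base_sums = (
        assignments.groupby(["specimen", "gene_id"], sort=True)["aligned_bases"].sum().unstack(fill_value=0)
        if len(assignments)
        else pd.DataFrame()
    )
    depth = base_sums.reindex(columns=catalog.gene_ids.sort_values(), fill_value=0).astype(float)
    nt_len = 3.0 * catalog.lengths().reindex(depth.columns).to_numpy()
    depth = depth / nt_len
    depth.index.name = "specimen"
    depth.columns.name = "gene_id"
    return AbundanceMatrix(depth)


def compute_relative_abundance(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Fill rel_abund: each specimen's depths divided by its total depth.

    A specimen with all-zero depth cannot be normalized and raises.
    """
    totals = matrix.depth.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"specimen(s) with zero total depth cannot be normalized: {list(zero)[:5]}")
    rel = matrix.depth.div(totals, axis=0)
    matrix.rel_abund = rel
    return matrix


def detected_genes(matrix: AbundanceMatrix, specimen: str) -> set[str]:
    """Genes with depth > 0 in one specimen (no minimum-depth threshold)."""
    return matrix.detected_genes(specimen)
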