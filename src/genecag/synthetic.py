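"""Seeded synthetic-data generator with recorded ground truth.

Emulates the data model the pipeline consumes: a deduplicated gene
catalog, block-structured co-abundant gene profiles across specimens, a
binary outcome shifting CAG relative abundance on the logit scale with
beta-binomial overdispersion, multi-mapping alignment ambiguity between
homologous genes, and reference genomes carrying planted contiguous
islands of CAG member genes.

The community model: each CAG c gets a log-normal baseline proportion
mu_c. Per specimen s, biological variability multiplies each CAG's
proportion by an independent log-normal factor (this is what makes the
profiles of distinct CAGs uncorrelated across specimens, hence separable
by cosine distance, while genes within a CAG stay parallel); a
proportion q_sc ~ Beta with that mean and intra-class correlation phi is
then drawn per CAG, supplying the count-level overdispersion the
association model expects. For specimens in the case group, associated
CAGs have their odds multiplied by exp(effect) before the noise layers.
Associated CAGs are drawn from the lower-abundance half of the community
and half of them shift up, half down — mirroring real cohorts, where
outcome-associated elements (e.g. accessory islands) are a small share
of total community mass and associations occur in both directions; this
also keeps compositional renormalization from bleeding planted effects
into null CAGs. Reads are allocated multinomially to genes with
within-CAG gene weights proportional to gene length times a small fixed
log-normal factor.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .catalog import GeneCatalog


@dataclass
class ExperimentConfig:
    """Study conditions for a synthetic experiment.

    Defaults are the package's canonical benchmark community: 500 genes in
    60 CAGs over 40 + 40 specimens, 30 CAGs associated with the outcome at
    effect 1.5 on the logit scale. Noise defaults (biological log-normal
    sigma 0.8, Beta-layer dispersion phi 0.002, 5000 catalog-assigned
    reads per specimen) are calibrated so that the planted effect is
    statistically identifiable for CAGs across the abundance range: the
    per-specimen logit noise is ~sqrt(sigma^2 + phi/mu), about 1.3 for
    the rarest planted CAGs, giving Wald z around 5 at 40 + 40 specimens.
    """

    n_genes: int = 500
    n_cags: int = 60
    n_specimens_per_group: tuple[int, int] = (40, 40)
    n_associated: int = 30
    effect_size: float = 1.5
    phi: float = 0.002
    reads_per_specimen: int = 5000
    read_length_nt: int = 150
    multimap_fraction: float = 0.05
    min_gene_length_aa: int = 100
    max_gene_length_aa: int = 500
    baseline_sigma: float = 1.0  # log-normal spread of CAG baseline proportions
    biological_sigma: float = 0.8  # per-(specimen, CAG) log-normal variability
    gene_weight_sigma: float = 0.05  # within-CAG gene-to-gene abundance spread
    n_taxa: int = 12
    n_functions: int = 8

    def __post_init__(self) -> None:
        if self.n_cags > self.n_genes:
            raise ValueError("need at least one gene per CAG")
        if self.n_associated > self.n_cags:
            raise ValueError("n_associated exceeds n_cags")
        if not (0 <= self.multimap_fraction < 1):
            raise ValueError("multimap_fraction must be in [0, 1)")
        if self.min_gene_length_aa * 3 < self.read_length_nt:
            raise ValueError("genes must be at least one read long")


@dataclass
class SyntheticTruth:
    gene_to_cag: dict[str, str]
    cag_ids: list[str]
    associated_cags: list[str]
    associated_effects: pd.Series  # cag -> signed logit shift
    baseline_mu: pd.Series  # cag -> baseline proportion
    effect_size: float
    phi: float
    read_source: pd.DataFrame  # specimen, read_id, gene_id (true origin)
    cag_proportions: pd.DataFrame  # specimen x cag realized proportions
    homolog_partner: dict[str, str]


@dataclass
class SyntheticExperiment:
    catalog: GeneCatalog
    alignments: pd.DataFrame
    manifest: pd.DataFrame
    truth: SyntheticTruth

    @property
    def covariates(self) -> pd.DataFrame:
        return self.manifest.drop_duplicates("specimen").set_index("specimen")[["outcome"]]


def _partition_sizes(n_items: int, n_groups: int, rng: np.random.Generator) -> np.ndarray:
    """Random sizes >= 1 summing to n_items (Dirichlet-multinomial-ish)."""
    extra = rng.multinomial(n_items - n_groups, np.full(n_groups, 1.0 / n_groups))
    return extra + 1


def make_catalog(config: ExperimentConfig, rng: np.random.Generator) -> tuple[GeneCatalog, dict[str, str]]:
    """Gene catalog plus the planted gene -> CAG assignment."""
    width = len(str(config.n_genes))
    gene_ids = [f"gene_{i:0{width}d}" for i in range(config.n_genes)]
    lengths = rng.integers(config.min_gene_length_aa, config.max_gene_length_aa + 1, size=config.n_genes)
    sizes = _partition_sizes(config.n_genes, config.n_cags, rng)
    cag_of = {}
    pos = 0
    cag_names = [f"tcag_{i:03d}" for i in range(config.n_cags)]
    for cag, size in zip(cag_names, sizes):
        for g in gene_ids[pos : pos + size]:
            cag_of[g] = cag
        pos += size
    taxa = [f"taxon_{i:02d}" for i in rng.integers(0, config.n_taxa, size=config.n_cags)]
    funcs = [f"fn_{i:02d}" for i in rng.integers(0, config.n_functions, size=config.n_cags)]
    cag_taxon = dict(zip(cag_names, taxa))
    cag_fn = dict(zip(cag_names, funcs))
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_aa": lengths,
            "taxon": [cag_taxon[cag_of[g]] for g in gene_ids],
            "function": [cag_fn[cag_of[g]] for g in gene_ids],
        }
    )
    return GeneCatalog(table), cag_of


def _draw_cag_proportions(
    mu: np.ndarray, phi: float, rng: np.random.Generator, biological_sigma: float = 0.0
) -> np.ndarray:
    """One specimen's CAG proportions: biological log-normal variability
    around the baseline, then independent Beta draws, renormalized."""
    if biological_sigma > 0:
        mu = mu * rng.lognormal(0.0, biological_sigma, size=len(mu))
        mu = mu / mu.sum()
    if phi <= 0:
        q = mu.copy()
    else:
        r = (1.0 - phi) / phi
        q = rng.beta(np.maximum(mu * r, 1e-8), np.maximum((1.0 - mu) * r, 1e-8))
        q = np.maximum(q, 1e-12)
    return q / q.sum()


def generate_depth_matrix(
    n_genes: int,
    n_cags: int,
    n_specimens: int,
    seed: int,
    phi: float = 0.02,
    baseline_sigma: float = 1.0,
    biological_sigma: float = 1.0,
    gene_noise_sigma: float = 0.02,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene x specimen depth matrix with planted co-abundance blocks.

    Returns (depth_profiles, truth) where truth maps gene_id to its
    planted CAG label. Genes of one CAG share the CAG's specimen profile
    up to small multiplicative noise; profiles of distinct CAGs are
    independent, so between-block cosine distances are large.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"gene_{i:0{width}d}" for i in range(n_genes)]
    sizes = _partition_sizes(n_genes, n_cags, rng)
    labels = np.repeat(np.arange(n_cags), sizes)
    mu = rng.lognormal(0.0, baseline_sigma, size=n_cags)
    mu = mu / mu.sum()
    profiles = np.vstack(
        [_draw_cag_proportions(mu, phi, rng, biological_sigma) for _ in range(n_specimens)]
    ).T  # cag x specimen
    gene_factor = rng.lognormal(0.0, 0.05, size=n_genes)
    noise = rng.lognormal(0.0, gene_noise_sigma, size=(n_genes, n_specimens))
    depth = profiles[labels] * gene_factor[:, None] * noise
    df = pd.DataFrame(depth, index=pd.Index(genes, name="gene_id"),
                      columns=[f"S{j:03d}" for j in range(n_specimens)])
    truth = pd.Series([f"tcag_{c:03d}" for c in labels], index=df.index, name="cag")
    return df, truth


def generate_experiment(config: ExperimentConfig | None = None, seed: int = 0) -> SyntheticExperiment:
    """Full synthetic experiment: catalog, alignments, manifest, truth."""
    config = config or ExperimentConfig()
    rng = np.random.default_rng(seed)
    catalog, cag_of = make_catalog(config, rng)
    cag_ids = sorted(set(cag_of.values()))
    n_cags = len(cag_ids)

    mu = rng.lognormal(0.0, config.baseline_sigma, size=n_cags)
    mu = mu / mu.sum()
    baseline = pd.Series(mu, index=cag_ids, name="baseline_mu")
    low_half = [cag_ids[i] for i in np.argsort(mu)[: max(n_cags // 2, config.n_associated)]]
    associated = sorted(rng.choice(low_half, size=config.n_associated, replace=False))
    signs = np.where(np.arange(config.n_associated) % 2 == 0, 1.0, -1.0)
    effects = pd.Series(config.effect_size * signs, index=associated, name="effect")

    genes = list(catalog.gene_ids)
    lengths = catalog.lengths().to_numpy()
    cag_index = {c: i for i, c in enumerate(cag_ids)}
    gene_cag_idx = np.array([cag_index[cag_of[g]] for g in genes])
    gene_weight = lengths * rng.lognormal(0.0, config.gene_weight_sigma, size=len(genes))

    # homologs: random disjoint pairing used for spurious secondary alignments
    perm = rng.permutation(len(genes))
    homolog = {}
    for a, b in zip(perm[0::2], perm[1::2]):
        homolog[genes[a]] = genes[b]
        homolog[genes[b]] = genes[a]

    n0, n1 = config.n_specimens_per_group
    specimens = [f"S{j:03d}" for j in range(n0 + n1)]
    outcome = ["progressor"] * n0 + ["responder"] * n1
    delta = np.array([effects.get(c, 0.0) for c in cag_ids])
    span_aa = config.read_length_nt // 3

    aln_parts = []
    src_parts = []
    props = np.zeros((len(specimens), n_cags))
    for s_idx, (spec, grp) in enumerate(zip(specimens, outcome)):
        mu_s = mu.copy()
        if grp == "responder" and config.effect_size != 0:
            mu_s = expit(logit(mu) + delta)
            mu_s = mu_s / mu_s.sum()
        q = _draw_cag_proportions(mu_s, config.phi, rng, config.biological_sigma)
        props[s_idx] = q
        gene_p = q[gene_cag_idx] * gene_weight
        gene_p = gene_p / gene_p.sum()
        counts = rng.multinomial(config.reads_per_specimen, gene_p)

        src_gene_idx = np.repeat(np.arange(len(genes)), counts)
        n_reads = len(src_gene_idx)
        read_ids = np.array([f"{spec}:r{i:06d}" for i in range(n_reads)])
        glen = lengths[src_gene_idx]
        starts = rng.integers(1, glen - span_aa + 2)
        primary = pd.DataFrame(
            {
                "specimen": spec,
                "read_id": read_ids,
                "gene_id": np.array(genes, dtype=object)[src_gene_idx],
                "score": 100.0,
                "gene_start": starts,
                "gene_end": starts + span_aa - 1,
                "aligned_bases": config.read_length_nt,
            }
        )
        aln_parts.append(primary)
        src_parts.append(primary[["specimen", "read_id", "gene_id"]])

        if config.multimap_fraction > 0 and n_reads:
            n_mm = int(round(config.multimap_fraction * n_reads))
            mm_rows = rng.choice(n_reads, size=n_mm, replace=False)
            partners = np.array([homolog[genes[i]] for i in src_gene_idx[mm_rows]], dtype=object)
            plen = catalog.lengths().reindex(partners).to_numpy()
            pstart = rng.integers(1, plen - span_aa + 2)
            secondary = pd.DataFrame(
                {
                    "specimen": spec,
                    "read_id": read_ids[mm_rows],
                    "gene_id": partners,
                    "score": 100.0,
                    "gene_start": pstart,
                    "gene_end": pstart + span_aa - 1,
                    "aligned_bases": config.read_length_nt,
                }
            )
            aln_parts.append(secondary)

    alignments = pd.concat(aln_parts, ignore_index=True)
    # stable global order: by specimen then read then gene
    alignments = alignments.sort_values(["specimen", "read_id", "gene_id"], kind="mergesort").reset_index(drop=True)
    read_source = pd.concat(src_parts, ignore_index=True)

    manifest = pd.DataFrame(
        {
            "specimen": specimens,
            "R1": [f"reads/{s}_R1.fastq.gz" for s in specimens],
            "R2": [f"reads/{s}_R2.fastq.gz" for s in specimens],
            "outcome": outcome,
        }
    )
    truth = SyntheticTruth(
        gene_to_cag=cag_of,
        cag_ids=cag_ids,
        associated_cags=list(associated),
        associated_effects=effects,
        baseline_mu=baseline,
        effect_size=config.effect_size,
        phi=config.phi,
        read_source=read_source,
        cag_proportions=pd.DataFrame(props, index=specimens, columns=cag_ids),
        homolog_partner=homolog,
    )
    return SyntheticExperiment(catalog=catalog, alignments=alignments, manifest=manifest, truth=truth)


def generate_decoy_scenario(
    seed: int = 7,
    n_reads: int = 500,
    n_spurious: int = 20,
    length_aa: int = 300,
    read_length_nt: int = 150,
) -> tuple[pd.DataFrame, GeneCatalog, str, str]:
    """One specimen, one true source gene, one decoy homolog.

    All reads originate from gene A (even coverage); `n_spurious` of them
    also align to decoy gene B, which receives no unique reads. Returns
    (alignments, catalog, true_gene, decoy_gene).
    """
    rng = np.random.default_rng(seed)
    true_gene, decoy = "geneA", "geneB"
    catalog = GeneCatalog(
        pd.DataFrame({"gene_id": [true_gene, decoy], "length_aa": [length_aa, length_aa]})
    )
    span = read_length_nt // 3
    starts = rng.integers(1, length_aa - span + 2, size=n_reads)
    rows = pd.DataFrame(
        {
            "specimen": "S0",
            "read_id": [f"r{i:04d}" for i in range(n_reads)],
            "gene_id": true_gene,
            "score": 100.0,
            "gene_start": starts,
            "gene_end": starts + span - 1,
            "aligned_bases": read_length_nt,
        }
    )
    # the spurious cross-mapping hits the conserved stretch of the decoy
    mm = rng.choice(n_reads, size=n_spurious, replace=False)
    dstart = rng.integers(1, span + 50, size=n_spurious)
    spurious = pd.DataFrame(
        {
            "specimen": "S0",
            "read_id": rows["read_id"].to_numpy()[mm],
            "gene_id": decoy,
            "score": 100.0,
            "gene_start": dstart,
            "gene_end": dstart + span - 1,
            "aligned_bases": read_length_nt,
        }
    )
    aln = pd.concat([rows, spurious], ignore_index=True)
    aln = aln.sort_values(["read_id", "gene_id"], kind="mergesort").reset_index(drop=True)
    return aln, catalog, true_gene, decoy


# ---------------------------------------------------------------------------
# reference genomes with planted islands


@dataclass
class IslandSpec:
    """One planted island: `n_genes` members of `cag_id` within ~`span_bp`."""

    cag_id: str
    n_genes: int
    span_bp: int


@dataclass
class SyntheticGenome:
    genome_id: str
    total_length: int
    sequence: str  # random DNA, generated lazily in tests that need FASTA
    alignments: pd.DataFrame
    gff: pd.DataFrame
    true_islands: pd.DataFrame  # contig_id, start, end, cag_id


def generate_genome(
    genome_id: str,
    islands: list[IslandSpec],
    cag_members: dict[str, list[str]],
    catalog: GeneCatalog,
    seed: int,
    background_genes: list[str] | None = None,
    background_gap: int = 15000,
    island_separation: int = 25000,
    with_sequence: bool = False,
    special_feature: tuple[str, str] | None = ("type II secretion system", "island0"),
) -> SyntheticGenome:
    """Lay out planted islands and scattered background genes on one contig.

    Island genes are placed consecutively with equal gaps chosen so that
    the island spans ~span_bp; islands and background genes are separated
    by distances far exceeding any sensible merge gap. Every placement is
    emitted both as a gene-to-genome alignment record and as a GFF3 CDS
    row; `special_feature` plants an extra named feature inside the chosen
    island (by index name "island<i>") for annotation tests.
    """
    rng = np.random.default_rng(seed)
    contig = f"{genome_id}_c1"
    aln_rows, gff_rows, truth_rows = [], [], []
    pos = 5001
    for isl_idx, spec in enumerate(islands):
        members = cag_members[spec.cag_id][: spec.n_genes]
        if len(members) < spec.n_genes:
            raise ValueError(f"CAG {spec.cag_id} has fewer than {spec.n_genes} genes")
        nt_lens = [3 * catalog.length_aa(g) for g in members]
        total_gene = sum(nt_lens)
        if total_gene > spec.span_bp:
            raise ValueError(f"island span {spec.span_bp} too small for {spec.n_genes} genes ({total_gene} nt)")
        gap = (spec.span_bp - total_gene) // max(len(members) - 1, 1)
        start0 = pos
        for j, (g, L) in enumerate(zip(members, nt_lens)):
            end = pos + L - 1
            strand = "+" if j % 2 == 0 else "-"
            aln_rows.append((g, genome_id, contig, pos, end, strand, float(rng.uniform(95, 100))))
            gff_rows.append((contig, "synthetic", "CDS", pos, end, ".", strand, "0", f"ID={g};product=hypothetical protein"))
            last_end = end
            pos = end + 1 + gap
        truth_rows.append((contig, start0, last_end, spec.cag_id))
        if special_feature and special_feature[1] == f"island{isl_idx}":
            mid = start0 + (last_end - start0) // 3
            gff_rows.append(
                (contig, "synthetic", "misc_feature", mid, min(mid + 2000, last_end), ".", "+", ".",
                 f"ID=feat_{genome_id}_{isl_idx};product={special_feature[0]}")
            )
        pos = last_end + 1 + island_separation
    for g in background_genes or []:
        L = 3 * catalog.length_aa(g)
        end = pos + L - 1
        aln_rows.append((g, genome_id, contig, pos, end, "+", float(rng.uniform(95, 100))))
        gff_rows.append((contig, "synthetic", "CDS", pos, end, ".", "+", "0", f"ID={g};product=hypothetical protein"))
        pos = end + 1 + background_gap
    total_length = pos + 5000
    seq = ""
    if with_sequence:
        seq = "".join(rng.choice(list("ACGT"), size=total_length))
    alignments = pd.DataFrame(
        aln_rows, columns=["gene_id", "genome_id", "contig_id", "start", "end", "strand", "pct_identity"]
    )
    gff = pd.DataFrame(
        gff_rows,
        columns=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    attrs = gff["attributes"].str.extract(r"ID=([^;]*)")[0].fillna("")
    prods = gff["attributes"].str.extract(r"product=([^;]*)")[0].fillna("")
    gff["feature_id"] = attrs
    gff["product"] = prods
    truth = pd.DataFrame(truth_rows, columns=["contig_id", "start", "end", "cag_id"])
    return SyntheticGenome(genome_id, total_length, seq, alignments, gff, truth)


def generate_strain_panel(
    catalog: GeneCatalog,
    cag_members: dict[str, list[str]],
    core_cag: str,
    island_cag: str,
    n_genomes: int = 10,
    n_island_carriers: int = 2,
    seed: int = 0,
) -> list[SyntheticGenome]:
    """Panel of strain genomes: a core CAG on all, a strain island on a few.

    The first `n_island_carriers` genomes carry the accessory island; every
    genome carries the core CAG's genes as background placements.
    """
    genomes = []
    core_genes = cag_members[core_cag]
    for i in range(n_genomes):
        islands = []
        if i < n_island_carriers:
            islands.append(IslandSpec(island_cag, min(len(cag_members[island_cag]), 8), 15000))
        genomes.append(
            generate_genome(
                f"G{i:02d}", islands, cag_members, catalog, seed=seed + i,
                background_genes=core_genes, special_feature=None,
            )
        )
    return genomes
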