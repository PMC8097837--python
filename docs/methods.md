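# Methods

This note records the models implemented in `genecag`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic-data generator does and does not emulate.

## Multi-mapping read resolution

Translated alignment of short reads against a protein gene catalog leaves
a fraction of reads mapping comparably well to several homologous genes.
Resolution is per specimen and iterative:

- Each read's candidate weights are initialized proportional to alignment
  score (uniform if all scores are zero).
- Per iteration, per-gene coverage is accumulated at amino-acid resolution
  from the weighted candidate intervals, and each gene is scored
  `mean(coverage) / (1 + CV(coverage))`, where the coefficient of
  variation is taken over all positions of the gene (zeros included).
  The score rewards genes that are both deeply and evenly covered; a
  spurious homolog that attracts cross-mapping reads only in its conserved
  stretch has high CV and low mean, and loses.
- Each read then moves its full weight to its best-scoring candidate,
  ties broken by lexicographically smaller `gene_id` (all tie-breaks in
  the package are lexicographic, for determinism).
- Iteration stops at a fixed point of the assignment, when the maximum
  weight change falls below `tol` (default 1e-6), or at `max_iter`
  (default 100).

Every read is retained on exactly one gene; uniquely-mapped reads are
trivially fixed points. The procedure is a hard-assignment EM in the
sense that the E-step re-scores genes under the current assignment and
the M-step reassigns reads greedily; it is deterministic given the input.

Assumptions and limits: coverage is treated as piecewise-constant per
amino acid; alignment quality beyond the initial score ranking is
ignored; a gene whose true coverage is genuinely uneven (e.g. a partial
gene call) can be penalized unfairly.

## Depth and relative abundance

Depth divides summed aligned nucleotides by the nucleotide gene length
`3 · length_aa` — the catalog is amino-acid, the reads are nucleotide, and
one unit system had to be fixed. Relative abundance normalizes depths to
sum to one per specimen; a specimen with no assigned reads is an error,
not a silent zero row. A gene is "detected" iff its post-resolution depth
is positive; no minimum-depth threshold is applied.

## CAG clustering

Exact average-linkage clustering is quadratic in memory and cubic in
time, so the scalable path shards:

- Rounds `1 .. n_rounds−1` (default 5 rounds total): genes (later,
  cluster centroids) are ordered by a deterministic MD5 hash of
  (seed, round, representative id) and chunked into shards of
  `shard_size`. Each shard is clustered by average linkage under cosine
  distance at threshold `τ/2` — the doubled stringency in pre-rounds
  means early, locally-decided merges are only ever merges the final
  threshold would also have made, at the price of deferring borderline
  ones. Each cluster is then replaced by the unweighted mean depth
  profile of its member genes (the representative id is the smallest
  member gene id).
- Final round: all surviving centroids are clustered globally at `τ`,
  with candidate pairs restricted to the `ann_neighbors` cosine nearest
  neighbours of each centroid (union over both directions). Distances for
  retrieved candidates are always computed exactly, so the neighbour
  restriction can only cause missed merges, never wrong merges;
  `exact_final=True` removes the restriction entirely.

The agglomeration itself merges the pair at minimum average distance
while that minimum is ≤ threshold (inclusive), with Lance–Williams
updates; forbidden (non-candidate) pairs carry `+inf`, which propagates
through the update. `τ` is deliberately a required parameter with no
default. Genes never detected in any specimen are excluded before
clustering. CAG ids are assigned by rank: descending member count, ties
by smallest member gene id.

CAG abundance is the summed member-gene depth divided by total detected
depth per specimen; rows sum to one by construction.

Numerical notes: the brute-force path (`average_linkage_cluster`) is
retained as the reference implementation and is cross-checked in the
tests against an independent hierarchical-clustering implementation
(scipy `linkage`/`fcluster`); ties in the merge order are broken by the
smallest index pair. Cosine distance is clipped to [0, 1] against
round-off; zero profiles are an error rather than a convention.

## Beta-binomial association model

Counts `W_sc` (reads of specimen `s` resolved to genes of CAG `c`) out of
`M_s` (all resolved reads of `s`) follow
`W ~ BetaBinomial(M, μ, φ)` with shapes `a = μ(1−φ)/φ`,
`b = (1−μ)(1−φ)/φ`, covariates on `logit(μ)` via a Wilkinson formula over
the manifest columns, and a single φ per CAG (no dispersion covariates:
the formula models the mean only). Fitting is maximum likelihood with
L-BFGS-B and the analytic gradient, warm-started at the binomial logistic
MLE with φ initialized at 0.01 on an internal logit scale. φ is bounded
to [1e-8, 1−1e-6]: below the floor the model is numerically
indistinguishable from the binomial while the shape parameters overflow
the `betaln` difference. Standard errors come from the observed
information, computed by central differences of the analytic gradient
(finite differences of the log-likelihood itself proved too inaccurate at
the optimum). Wald p-values use the normal reference; at n ≈ 50 this
shows the expected mild finite-sample inflation (measured type-I error
≈ 0.055–0.07 at nominal 0.05 in the suite's calibration test). Degenerate
count vectors (all zero, or all equal to `M`) are flagged as separated
and excluded from fitting and from FDR adjustment, as are non-converged
fits. FDR control is Benjamini–Hochberg step-up (delegated to
statsmodels; an independent brute-force implementation of the step-up
definition serves as the test oracle). M is the number of
catalog-assigned reads, not total sequenced reads — abundance is relative
to the assayed gene content.

## Errors-in-response aggregation

For a taxon or function label, every converged CAG containing at least
one gene with that label contributes its coefficient estimate and SE; a
CAG whose genes carry several labels contributes to each. The model is
intercept-only with known sampling variances:
`y_c = β₀ + ε_c + u_c`, `u_c ~ N(0, se_c²)`, `ε_c ~ N(0, σ²)`.
(β₀, σ²) are estimated by profile maximum likelihood (β₀ is the
precision-weighted mean at any σ², leaving a 1-D bounded optimization in
σ² ≥ 0, with the boundary value snapped to exactly zero when it is a
maximizer); the test of β₀ = 0 is Wald with σ² plugged in and
`se₀ = (Σ w_c)^{−1/2}`, `w_c = 1/(σ² + se_c²)`. With σ² = 0 this is
fixed-effect inverse-variance meta-analysis; the implementation is
cross-checked against an independent random-effects meta-analysis
implementation (R `metafor`, ML) in the tests. ML (not REML) is used, so
σ² is mildly biased downward for very small numbers of CAGs; with a
single contributing CAG the label estimate is the CAG estimate itself.

A reporting (not fitting) convention: volcano-style views downstream
should filter to CAGs with at least five member genes.

## Genomic islands

All coordinates are 1-based inclusive nucleotides; the gap between
`[.., e₁]` and `[s₂, ..]` is `s₂ − e₁ − 1`. Island detection is
single-linkage along each contig: consecutive alignments of associated
genes merge while the gap is ≤ `max_gap`. The default `max_gap` of
5,000 bp is an explicit, exposed choice: intergenic spacing within an
island is typically hundreds of bp, while unrelated placements are tens
of kb apart, so the result is insensitive to the default over a wide
range. Strand is recorded but ignored for contiguity — an island is a
physical region. Genome summaries report the unioned (double-counting
free) bases covered by associated genes over the genome length.
Core/accessory classification compares the fraction of evaluated
reference genomes containing any member-gene alignment against
`core_genome_fraction` (default 0.9). GFF3 features overlapping an island
by ≥ 1 bp are attached verbatim (type and product text); malformed GFF
lines fail loudly with their line number. Alignment-quality filters for
counting a gene as present (`min_identity` 90, `min_coverage` 50) are the
caller's responsibility when preparing the alignment table; the detection
and summary operations take the table as given.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
with all randomness derived from one seed:

- **Community.** Each CAG draws a log-normal baseline proportion
  (σ = 1.0). Per specimen, each CAG's proportion is multiplied by an
  independent log-normal biological factor (σ = 0.8) — this is what makes
  distinct CAGs' profiles uncorrelated across specimens and therefore
  separable by cosine distance — then a Beta draw with intra-class
  correlation φ = 0.002 adds the count-level overdispersion the
  association model expects, and reads are allocated multinomially
  (5,000 catalog-assigned reads per specimen, 150 nt each). Within a CAG,
  gene weights are proportional to gene length times a small fixed
  log-normal factor (σ = 0.05), so member genes are parallel up to
  sampling noise.
- **Outcome effect.** The benchmark community is 500 genes in 60 CAGs
  over 40 + 40 specimens with 30 associated CAGs at |effect| = 1.5 on the
  logit scale. Associated CAGs are drawn from the lower-abundance half of
  the community and half shift up, half down. Both choices mirror real
  cohorts — outcome-associated elements are a small share of community
  mass, and associations occur in both directions — and both are needed
  for the planted truth to be well-defined: proportions are
  compositional, so shifting a large mass fraction in one direction would
  bleed opposite-signed "effects" into every null CAG. The noise defaults
  were calibrated once so the planted effect is statistically
  identifiable across the abundance range (per-specimen logit noise
  ≈ `sqrt(σ² + φ/μ)` ≈ 1.3 for the rarest planted CAGs, i.e. Wald z ≈ 5
  at 40 + 40 specimens) and then frozen.
- **Multi-mapping.** A configurable fraction (default 5%) of reads gains
  a second, equally-scored alignment to a fixed random homolog partner of
  its source gene. A dedicated decoy scenario plants one true gene with
  even coverage and one decoy receiving only cross-mapped reads
  concentrated in a short "conserved" stretch.
- **Genomes.** Islands are laid out as consecutive member genes of one
  CAG with equal gaps filling a requested span (defaults in the 14–20 kb
  range), separated from background placements by distances far above any
  sensible merge gap; each placement is emitted as both an alignment
  record and a GFF3 CDS row, with an optional planted named feature. A
  strain-panel helper puts a core CAG on every genome and an accessory
  island on a subset.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: sequencing error and read
QC; assembly fragmentation and chimeric gene calls; catalog redundancy
beyond simple homolog pairs; phylogenetic correlation between CAGs;
compositional coupling beyond renormalization; uneven coverage along
genes (GC bias, edge effects); specimen library-size confounding with
outcome. Benchmarks on this generator measure algorithmic correctness
and statistical calibration under the stated model, not field
performance.

## Problem sizes in the test suite

The suite exercises the exact-vs-sharded equivalence at up to 200 genes,
sharded recovery at 2,000 genes / 120 CAGs (ARI ≥ 0.95), Wald
calibration with 1,000 null replicates at n = 50 and effect recovery
with 200 replicates at n = 200, and the full pipeline on the 500-gene
benchmark community. These sizes keep a full run at roughly a minute on
one CPU while leaving each statistical check enough replicates for its
Monte-Carlo error to be small relative to its tolerance.

## Known limitations

- The dispersion φ is shared across specimens within a CAG; dispersion
  covariates are not supported.
- Wald inference (per-CAG and label-level) is first-order; no
  small-sample or resampling correction is applied.
- The nearest-neighbour prefilter in the final clustering round uses an
  exact k-NN index; on catalogs of millions of genes an approximate index
  would be substituted behind the same candidate-mask interface.
- Island detection assumes the alignment table is already filtered to
  trusted placements; it applies no identity/coverage thresholds itself.
- The HDF5 store uses pandas/pytables fixed-format tables; layouts are
  stable within a pandas major version but not guaranteed across them.
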