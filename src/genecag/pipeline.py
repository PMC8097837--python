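"""End-to-end orchestration: abundance -> CAGs -> association -> islands.

Each stage consumes the previous stage's tables and everything lands in a
single HDF5 results store together with the parameters and seeds used, so
a rerun with identical inputs reproduces every deterministic table
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import abundance as ab
from . import cluster as cl
from . import islands as isl
from . import stats as st
from .catalog import GeneCatalog
from .manifest import Manifest
from .store import ResultsStore


@dataclass
class PipelineParams:
    tau: float
    formula: str
    fdr: float = 0.01
    max_gap: int = 5000
    seed: int = 0
    n_rounds: int = 5
    shard_size: int = 1000
    ann_neighbors: int = 20
    exact_final: bool = False
    max_iter: int = 100
    tol: float = 1e-6


@dataclass
class PipelineResult:
    store: ResultsStore
    partition: cl.CAGPartition
    fits: pd.DataFrame
    significant: tuple[list[str], list[str]]
    islands: list = field(default_factory=list)


def run_pipeline(
    manifest: Manifest | pd.DataFrame,
    alignments: pd.DataFrame,
    catalog: GeneCatalog,
    params: PipelineParams,
    output: str | Path,
    genome_alignments: pd.DataFrame | None = None,
    genome_lengths: dict[str, int] | None = None,
    gff: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run every analysis stage and populate the results store.

    `manifest` supplies the specimen covariates for the design formula;
    island detection runs only when `genome_alignments` is given. On a
    stage failure the partially-written store records the error under
    /meta/status before the exception propagates.
    """
    out = Path(output)
    if out.exists():
        out.unlink()
    store = ResultsStore(out)
    covariates = manifest.covariates if isinstance(manifest, Manifest) else manifest
    params_record = {
        "tau": params.tau,
        "formula": params.formula,
        "fdr": params.fdr,
        "max_gap": params.max_gap,
        "seed": params.seed,
        "n_rounds": params.n_rounds,
        "shard_size": params.shard_size,
        "ann_neighbors": params.ann_neighbors,
        "exact_final": params.exact_final,
    }
    stage = "start"
    try:
        stage = "abundance"
        resolved = ab.resolve_multimappers(alignments, catalog, params.max_iter, params.tol)
        matrix = ab.compute_depth(resolved, catalog)
        matrix = ab.compute_relative_abundance(matrix)
        store.write_table("/abund/depth", matrix.depth)
        store.write_table("/abund/rel", matrix.rel_abund)

        stage = "clustering"
        detected = matrix.depth.columns[(matrix.depth > 0).any(axis=0)]
        profiles = matrix.depth[detected].T  # gene x specimen
        cparams = cl.ClusteringParams(
            tau=params.tau,
            n_rounds=params.n_rounds,
            shard_size=params.shard_size,
            ann_neighbors=params.ann_neighbors,
            seed=params.seed,
            exact_final=params.exact_final,
        )
        partition = cl.sharded_cluster(profiles, cparams)
        cag_abund = cl.compute_cag_abundance(partition, matrix)
        store.write_table("/cags/partition", partition.as_frame())
        store.write_table("/cags/abund", cag_abund.abund)

        stage = "association"
        counts = st.build_count_table(resolved, partition)
        X = st.build_design_matrix(covariates.loc[counts.W.index], params.formula)
        fits = st.fit_all_cags(counts, X)
        store.write_table("/stats/cag_fits", fits)
        aggs = []
        for kind in ("taxon", "function"):
            if catalog.table[kind].notna().any():
                agg = st.aggregate_by_annotation(fits, partition, catalog, kind)
                agg = agg.assign(kind=kind)
                aggs.append(agg)
        aggregates = pd.concat(aggs) if aggs else pd.DataFrame(
            columns=["beta0_hat", "se0", "sigma2_hat", "p0", "n_cags", "sigma2_clamped", "kind"]
        )
        store.write_table("/stats/aggregates", aggregates)
        significant = st.significant_cags(fits, params.fdr)

        islands_found: list = []
        if genome_alignments is not None:
            stage = "islands"
            assoc_cags = set(significant[0]) | set(significant[1])
            assoc_genes = {g for g, c in partition.gene_to_cag.items() if c in assoc_cags}
            sub = genome_alignments[genome_alignments["gene_id"].isin(assoc_genes)]
            islands_found = isl.detect_islands(sub, params.max_gap, partition.gene_to_cag)
            if gff is not None:
                islands_found = isl.annotate_islands(islands_found, gff)
            store.write_table("/islands/records", isl.islands_to_frame(islands_found))

        store.write_params({**params_record, "status": "ok"})
        return PipelineResult(store, partition, fits, significant, islands_found)
    except Exception as exc:
        store.write_params({**params_record, "status": f"error in {stage}: {exc}"})
        raise
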