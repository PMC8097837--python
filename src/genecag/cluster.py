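"""Co-abundant gene group (CAG) clustering.

Genes whose length-normalized depths rise and fall together across
specimens are grouped into CAGs by average-linkage agglomerative
clustering under the cosine distance. Because all-against-all clustering
of a large catalog is intractable, clustering proceeds in sharded rounds:
genes are partitioned into shards, each shard is clustered at half the
user's distance threshold (stringency doubled to avoid locking in
sub-optimal early merges), clusters are replaced by their mean depth
profile, and the survivors are re-sharded. Only the final, global round
applies the user-specified threshold, restricted to candidate pairs
retrieved from a nearest-neighbour index so that the approximation can
only miss merges, never create wrong ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .abundance import AbundanceMatrix


@dataclass
class ClusteringParams:
    """Knobs of the sharded clustering scheme.

    tau: final-round cosine-distance threshold in (0, 1] (required; the
    pre-clustering rounds use tau / 2). n_rounds counts total rounds
    including the final global one. shard_size bounds the per-shard
    problem; ann_neighbors is the number of candidates retrieved per
    profile in the final round; seed drives shard assignment.
    """

    tau: float
    n_rounds: int = 5
    shard_size: int = 1000
    ann_neighbors: int = 20
    seed: int = 0
    exact_final: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.tau <= 1):
            raise ValueError("tau must be in (0, 1]")
        if self.shard_size < 2:
            raise ValueError("shard_size must be >= 2")
        if self.ann_neighbors < 1:
            raise ValueError("ann_neighbors must be >= 1")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


class CAGPartition:
    """Disjoint, exhaustive assignment of detected genes to CAGs.

    CAG ids are assigned by rank: descending member count, ties broken by
    the lexicographically smallest member gene_id.
    """

    def __init__(self, members: dict[str, list[str]]):
        self.members = {c: sorted(ms) for c, ms in members.items()}
        self.gene_to_cag: dict[str, str] = {}
        for cag, ms in self.members.items():
            if not ms:
                raise ValueError(f"empty CAG: {cag}")
            for g in ms:
                if g in self.gene_to_cag:
                    raise ValueError(f"gene {g} assigned to more than one CAG")
                self.gene_to_cag[g] = cag

    @classmethod
    def from_clusters(cls, clusters: list[list[str]]) -> "CAGPartition":
        ranked = sorted(clusters, key=lambda ms: (-len(ms), min(ms)))
        width = max(5, len(str(max(len(ranked), 1))))
        return cls({f"CAG{i:0{width}d}": ms for i, ms in enumerate(ranked)})

    @property
    def cag_ids(self) -> list[str]:
        return list(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def labels(self, genes: pd.Index) -> np.ndarray:
        """Integer cluster labels aligned to `genes` (for e.g. ARI)."""
        ids = {c: i for i, c in enumerate(self.members)}
        return np.array([ids[self.gene_to_cag[g]] for g in genes])

    def as_frame(self) -> pd.DataFrame:
        rows = [(g, c) for c, ms in self.members.items() for g in ms]
        return pd.DataFrame(rows, columns=["gene_id", "cag_id"]).sort_values("gene_id").reset_index(drop=True)

    def sizes(self) -> pd.Series:
        return pd.Series({c: len(ms) for c, ms in self.members.items()}, name="size")


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); 0 for parallel non-negative profiles, 1 for disjoint support."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("profiles must have the same length")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero profile")
    d = 1.0 - float(np.dot(u, v) / (nu * nv))
    return min(max(d, 0.0), 1.0)


def _pairwise_cosine(profiles: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(profiles, axis=1, keepdims=True)
    unit = profiles / norms
    d = 1.0 - unit @ unit.T
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    return d


def _agglomerate(dist: np.ndarray, threshold: float) -> list[list[int]]:
    """Average-linkage agglomeration on a precomputed distance matrix.

    Repeatedly merges the pair of clusters at minimum average pairwise
    distance while that minimum is <= threshold (inclusive), using
    Lance-Williams updates. Entries of `dist` may be +inf to forbid a
    merge (candidate-restricted mode); inf propagates so restricted pairs
    can only fail to merge, never merge wrongly. Ties are broken by the
    smallest (i, j) index pair for determinism.
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(n)
    members: list[list[int] | None] = [[i] for i in range(n)]
    active = np.ones(n, dtype=bool)

    while active.sum() > 1:
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        flat = np.argmin(block)
        i_s, j_s = divmod(flat, block.shape[1])
        dmin = block[i_s, j_s]
        if not (dmin <= threshold):
            break
        i, j = sorted((sub[i_s], sub[j_s]))
        ni, nj = sizes[i], sizes[j]
        # average linkage: d(k, i+j) = (ni*d(k,i) + nj*d(k,j)) / (ni+nj)
        new_row = (ni * d[i, :] + nj * d[j, :]) / (ni + nj)
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = np.inf
        d[j, :] = np.inf
        d[:, j] = np.inf
        sizes[i] = ni + nj
        members[i] = members[i] + members[j]  # type: ignore[operator]
        members[j] = None
        active[j] = False

    return [m for m in members if m is not None]


def average_linkage_cluster(depth_profiles: pd.DataFrame, threshold: float) -> CAGPartition:
    """Exact (non-sharded) average-linkage clustering at `threshold`.

    `depth_profiles` is gene x specimen; every row must have a positive
    norm (genes never detected are excluded upstream). This is the
    brute-force reference path; `sharded_cluster` is the scalable one.
    """
    if len(depth_profiles) == 0:
        return CAGPartition({})
    profiles = depth_profiles.to_numpy(dtype=float)
    if (np.linalg.norm(profiles, axis=1) == 0).any():
        raise ValueError("all-zero depth profile: exclude undetected genes first")
    dist = _pairwise_cosine(profiles)
    clusters = _agglomerate(dist, threshold)
    genes = depth_profiles.index
    return CAGPartition.from_clusters([[genes[i] for i in c] for c in clusters])


def _shard_of(key: str, round_idx: int, seed: int) -> int:
    h = hashlib.md5(f"{seed}:{round_idx}:{key}".encode()).hexdigest()
    return int(h[:12], 16)


def _candidate_mask(profiles: np.ndarray, k: int) -> np.ndarray:
    """Boolean candidate-pair mask from a cosine nearest-neighbour index."""
    n = len(profiles)
    k_eff = min(k + 1, n)
    nn = NearestNeighbors(n_neighbors=k_eff, metric="cosine", algorithm="brute")
    nn.fit(profiles)
    _, idx = nn.kneighbors(profiles)
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_eff)
    cols = idx.ravel()
    mask[rows, cols] = True
    mask |= mask.T  # symmetrize: a pair is a candidate if either side retrieves it
    np.fill_diagonal(mask, True)
    return mask


def sharded_cluster(depth_profiles: pd.DataFrame, params: ClusteringParams) -> CAGPartition:
    """Multi-round sharded clustering of gene depth profiles into CAGs.

    Rounds 1..n_rounds-1 cluster within shards at tau/2, replace each
    cluster by the unweighted mean profile of its member genes, and
    re-shard (deterministic hash of the cluster's representative id with
    the round index and seed). The final round clusters all surviving
    centroids at tau, with pairs restricted to nearest-neighbour
    candidates unless exact_final is set.
    """
    if len(depth_profiles) == 0:
        return CAGPartition({})
    profiles = depth_profiles.to_numpy(dtype=float)
    if (np.linalg.norm(profiles, axis=1) == 0).any():
        raise ValueError("all-zero depth profile: exclude undetected genes first")
    genes = list(depth_profiles.index)

    # each working cluster: (representative id = smallest member gene, member row indices)
    clusters: list[tuple[str, list[int]]] = [(g, [i]) for i, g in enumerate(genes)]

    def centroid(rows: list[int]) -> np.ndarray:
        return profiles[rows].mean(axis=0)

    pre_tau = params.tau / 2.0
    for rnd in range(params.n_rounds - 1):
        if len(clusters) <= 1:
            break
        order = sorted(range(len(clusters)), key=lambda i: _shard_of(clusters[i][0], rnd, params.seed))
        shards = [order[i : i + params.shard_size] for i in range(0, len(order), params.shard_size)]
        merged: list[tuple[str, list[int]]] = []
        for shard in shards:
            if len(shard) == 1:
                merged.append(clusters[shard[0]])
                continue
            cents = np.vstack([centroid(clusters[i][1]) for i in shard])
            dist = _pairwise_cosine(cents)
            for grp in _agglomerate(dist, pre_tau):
                rows = [r for g in grp for r in clusters[shard[g]][1]]
                rep = min(clusters[shard[g]][0] for g in grp)
                merged.append((rep, rows))
        clusters = sorted(merged, key=lambda c: c[0])

    if len(clusters) > 1:
        cents = np.vstack([centroid(rows) for _, rows in clusters])
        dist = _pairwise_cosine(cents)
        if not params.exact_final:
            mask = _candidate_mask(cents, params.ann_neighbors)
            dist = np.where(mask, dist, np.inf)
        final = _agglomerate(dist, params.tau)
        clusters = [
            (min(clusters[i][0] for i in grp), [r for i in grp for r in clusters[i][1]])
            for grp in final
        ]

    return CAGPartition.from_clusters([[genes[r] for r in rows] for _, rows in clusters])


class CAGAbundanceMatrix:
    """Specimen x CAG proportional abundance (rows sum to 1)."""

    def __init__(self, abund: pd.DataFrame):
        self.abund = abund


def compute_cag_abundance(partition: CAGPartition, matrix: AbundanceMatrix) -> CAGAbundanceMatrix:
    """CAG abundance: summed member-gene depth over total detected depth.

    cag_abund(s, c) = sum_{g in c} depth(s, g) / sum_g depth(s, g).
    """
    totals = matrix.depth.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"specimen(s) with zero total depth: {list(zero)[:5]}")
    cols = {}
    for cag, members in partition.members.items():
        present = [g for g in members if g in matrix.depth.columns]
        cols[cag] = matrix.depth[present].sum(axis=1) if present else pd.Series(0.0, index=matrix.depth.index)
    abund = pd.DataFrame(cols).div(totals, axis=0)
    abund.index.name = "specimen"
    abund.columns.name = "cag_id"
    return CAGAbundanceMatrix(abund)


def cag_size_spectrum(partition: CAGPartition, bins: list[int] | None = None) -> pd.DataFrame:
    """Genes per CAG-size bin (how many genes live in CAGs of each size range).

    `bins` are left edges of size ranges; default powers of two. The gene
    counts across bins sum to the number of clustered genes.
    """
    sizes = partition.sizes()
    if len(sizes) == 0:
        return pd.DataFrame(columns=["size_range", "n_genes"])
    if bins is None:
        top = int(sizes.max())
        bins = [1]
        while bins[-1] * 2 <= top:
            bins.append(bins[-1] * 2)
    edges = bins + [int(sizes.max()) + 1]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = sizes[(sizes >= lo) & (sizes < hi)]
        label = f"{lo}" if hi == lo + 1 else f"{lo}-{hi - 1}"
        rows.append({"size_range": label, "n_genes": int((in_bin * 1).sum())})
    return pd.DataFrame(rows)
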