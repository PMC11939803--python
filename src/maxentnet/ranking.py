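"""Weighted PageRank, score clustering, triplet co-occurrence, and core genes.

The ranking stage scores every gene of a reconstructed weighted network with
a damped PageRank, clusters the scores with k-means (k = 10 by default), and
then looks for gene triplets that land in the same cluster across many
samples.  Intersecting the genes of the top co-occurring triplets between the
original (G0) and methylation-pruned (G1) networks yields the stable core
gene set; non-core genes touching two or more core genes in the underlying
topology are the bridge genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "PageRankScores",
    "ClusterAssignment",
    "TripletCountTable",
    "CoreGeneResult",
    "weighted_pagerank",
    "kmeans_scores",
    "cluster_count_entropy",
    "cluster_entropy_curve",
    "triplet_cooccurrence",
    "core_set",
    "core_subnetwork_and_bridges",
]


@dataclass
class PageRankScores:
    scores: pd.Series  # gene -> score, strictly positive, sums to 1
    damping: float
    mode: str
    n_iter: int
    residual: float
    converged: bool


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> cluster id in 1..k, ids ascending in mean score
    k: int
    seed: int


@dataclass
class TripletCountTable:
    counts: dict  # sorted 3-tuple of genes -> co-occurrence count (>= 1)
    candidates: tuple[str, ...]


@dataclass
class CoreGeneResult:
    core_genes: tuple[str, ...]
    bridge_genes: tuple[str, ...]
    subnetwork: GeneNetwork


# ---------------------------------------------------------------------------
# PageRank


def weighted_pagerank(
    weights: sp.spmatrix,
    gene_ids,
    damping: float = 0.85,
    mode: str = "row_stochastic",
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> PageRankScores:
    """Damped PageRank on a weighted directed network.

    ``mode="row_stochastic"`` (default) treats ``weights`` as a transition
    matrix and iterates ``PR <- (1-d)/N + d * W^T PR``, which conserves mass
    because the reconstructed weights are row-stochastic.  ``mode="as_printed"``
    follows the in-degree-normalised update
    ``PR(v) <- (1-d)/N + d * sum_{u in N(v)} w_uv PR(u) / C_in(u)`` with
    ``C_in(u)`` the number of edges pointing at u (zero replaced by one);
    scores are renormalised to sum one after every sweep in both modes.
    """
    w = sp.csr_matrix(weights, dtype=float)
    n = w.shape[0]
    if w.shape[0] != w.shape[1] or n != len(gene_ids):
        raise ValueError("weights must be square and match gene_ids")
    if w.nnz and w.data.min() < 0:
        raise ValueError("edge weights must be nonnegative")
    if not (0 < damping < 1):
        raise ValueError("damping must lie in (0, 1)")
    if mode == "row_stochastic":
        wt = sp.csr_matrix(w.T)
        scale = np.ones(n)
    elif mode == "as_printed":
        wt = sp.csr_matrix(w.T)
        c_in = np.asarray((w != 0).sum(axis=0)).ravel().astype(float)
        scale = np.where(c_in == 0, 1.0, c_in)
    else:
        raise ValueError(f"unknown PageRank mode: {mode!r}")
    pr = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    residual = np.inf
    converged = False
    for n_iter in range(1, max_iter + 1):
        new = teleport + damping * (wt @ (pr / scale))
        new /= new.sum()
        residual = float(np.abs(new - pr).sum())
        pr = new
        if residual < tol:
            converged = True
            break
    if not converged:
        logger.warning("PageRank did not converge: L1 residual %.2e", residual)
    return PageRankScores(
        scores=pd.Series(pr, index=list(gene_ids)),
        damping=damping,
        mode=mode,
        n_iter=n_iter,
        residual=residual,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# clustering


def kmeans_scores(
    scores: PageRankScores | pd.Series,
    k: int = 10,
    seed: int = 0,
    log_scale: bool = True,
) -> ClusterAssignment:
    """K-means on the scalar PageRank scores, ids canonicalised by mean.

    Scores follow a heavy-tailed (power-law-like) distribution, so by default
    clustering operates on log10 scores; ``log_scale=False`` uses the raw
    values.  Cluster ids are relabelled 1..k by ascending cluster mean so
    assignments are comparable across samples.  Deterministic given ``seed``.
    """
    series = scores.scores if isinstance(scores, PageRankScores) else scores
    values = series.to_numpy(dtype=float)
    if k > len(np.unique(values)):
        raise ValueError("k exceeds the number of distinct score values")
    feats = np.log10(values) if log_scale else values
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(feats.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return ClusterAssignment(
        labels=pd.Series(relabel[raw], index=series.index), k=k, seed=seed
    )


def cluster_count_entropy(assignment: ClusterAssignment) -> float:
    """Entropy (nats) of the cluster-size distribution."""
    labels = assignment.labels
    if len(labels) == 0:
        raise ValueError("empty cluster assignment")
    frac = labels.value_counts().to_numpy(dtype=float)
    frac /= frac.sum()
    return float(-(frac * np.log(frac)).sum())


def cluster_entropy_curve(
    scores_by_sample: Mapping[str, PageRankScores | pd.Series],
    k_min: int = 5,
    k_max: int = 15,
    seed: int = 0,
    log_scale: bool = True,
) -> pd.Series:
    """Mean cluster-size entropy across samples for each k in [k_min, k_max]."""
    ks = range(k_min, k_max + 1)
    means = []
    for k in ks:
        vals = [
            cluster_count_entropy(kmeans_scores(s, k=k, seed=seed, log_scale=log_scale))
            for s in scores_by_sample.values()
        ]
        means.append(float(np.mean(vals)))
    return pd.Series(means, index=list(ks), name="mean_entropy")


# ---------------------------------------------------------------------------
# triplet co-occurrence and the core set


def triplet_cooccurrence(
    assignments: Mapping[str, ClusterAssignment],
    candidates,
    max_candidates: int = 200,
) -> TripletCountTable:
    """Count, per sorted candidate triple, the samples where it co-clusters.

    For every sample, each 3-subset of candidates lying in one cluster
    increments its count by one; only triples with count >= 1 are stored.
    Candidates absent from a sample's assignment (for example pruned from G1)
    simply do not contribute in that sample.
    """
    candidates = tuple(dict.fromkeys(candidates))
    if len(candidates) > max_candidates:
        raise ValueError(
            f"{len(candidates)} candidates exceed the combinatorial guard of "
            f"{max_candidates}; subset the candidate list"
        )
    counts: dict[tuple[str, str, str], int] = {}
    for assignment in assignments.values():
        labels = assignment.labels
        by_cluster: dict[int, list[str]] = {}
        for g in candidates:
            if g in labels.index and not pd.isna(labels[g]):
                by_cluster.setdefault(int(labels[g]), []).append(g)
        for members in by_cluster.values():
            if len(members) < 3:
                continue
            for triple in combinations(sorted(members), 3):
                counts[triple] = counts.get(triple, 0) + 1
    return TripletCountTable(counts=counts, candidates=candidates)


def _top_triples(table: TripletCountTable, top_n: int) -> list[tuple[str, str, str]]:
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < top_n:
        logger.info(
            "only %d triples available (top_n=%d): using all", len(ranked), top_n
        )
    return [t for t, _ in ranked[:top_n]]


def core_set(
    table_g0: TripletCountTable, table_g1: TripletCountTable, top_n: int = 100
) -> tuple[str, ...]:
    """Intersect the deduplicated gene lists of the top co-occurring triples.

    Triples are ranked by descending count with ties broken lexicographically
    on the sorted triple, so the result is reproducible across runs.  An
    empty intersection is a valid (warned) outcome.
    """
    if not table_g0.counts or not table_g1.counts:
        raise ValueError("both triplet tables must be nonempty")
    genes_g0 = {g for t in _top_triples(table_g0, top_n) for g in t}
    genes_g1 = {g for t in _top_triples(table_g1, top_n) for g in t}
    core = tuple(sorted(genes_g0 & genes_g1))
    if not core:
        logger.warning("core set is empty: G0 and G1 top-triplet genes are disjoint")
    return core


def core_subnetwork_and_bridges(net: GeneNetwork, core) -> CoreGeneResult:
    """Core genes plus first-order neighbors; bridges touch >= 2 core genes.

    Adjacency is taken direction-ignored for both neighborhood expansion and
    the bridge criterion; self-loops are ignored.
    """
    core = tuple(sorted(dict.fromkeys(core)))
    if not core:
        raise ValueError("core gene set is empty")
    missing = [g for g in core if g not in net]
    if missing:
        raise KeyError(f"core genes absent from network: {missing[:5]}")
    und = net.adjacency + net.adjacency.T
    und = sp.csr_matrix(und)
    und.setdiag(0)
    und.eliminate_zeros()
    core_idx = [net.index_of(g) for g in core]
    core_mask = np.zeros(net.n, dtype=bool)
    core_mask[core_idx] = True
    # neighbors of core (in- or out-, direction ignored)
    reach = np.asarray(und[core_idx].sum(axis=0)).ravel() > 0
    member = core_mask | reach
    nodes = [g for g, m in zip(net.gene_ids, member) if m]
    sub = net.subnetwork(nodes)
    # bridge = non-core node adjacent to >= 2 distinct core genes
    core_contacts = np.asarray(
        (und[:, core_idx] != 0).sum(axis=1)
    ).ravel()
    bridges = tuple(
        sorted(
            g
            for i, g in enumerate(net.gene_ids)
            if not core_mask[i] and core_contacts[i] >= 2
        )
    )
    return CoreGeneResult(core_genes=core, bridge_genes=bridges, subnetwork=sub)
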