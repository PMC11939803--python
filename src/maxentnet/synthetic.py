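"""Synthetic networks, expression, and methylation data with planted truth.

The generators emulate the statistical structure the method assumes about
real inputs: a scale-free directed interaction topology, per-sample
nonnegative expression with a planted co-expressed module, and bimodal
methylation beta values peaking near 0.1 and 0.9.  All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from . import maxent
from .network import BetaMatrix, ExpressionDataset, GeneNetwork

__all__ = [
    "SyntheticTruth",
    "SimulatedDataset",
    "generate_network",
    "generate_expression",
    "generate_beta",
    "simulate_dataset",
    "random_connected_network",
    "connector_fixture",
    "degree_powerlaw_slope",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulated dataset."""

    module: tuple[str, ...]
    candidates: tuple[str, ...]
    forced_methylated: dict  # sample id -> tuple of gene ids
    seed: int
    params: dict

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["module"] = list(self.module)
        payload["candidates"] = list(self.candidates)
        payload["forced_methylated"] = {
            k: list(v) for k, v in self.forced_methylated.items()
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class SimulatedDataset:
    network: GeneNetwork  # raw topology, self-loops not yet added
    expression: ExpressionDataset
    beta: BetaMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# topology


def generate_network(
    n: int,
    m_attach: int,
    seed: int,
    orientation: str = "random",
) -> GeneNetwork:
    """Preferential-attachment network with a power-law degree distribution.

    Growth starts from a seed clique of ``m_attach + 1`` nodes (one edge per
    unordered pair); each new node attaches to ``m_attach`` distinct existing
    targets drawn with probability proportional to (total degree + 1), so the
    edge count is ``C(m_attach+1, 2) + m_attach * (n - m_attach - 1)``.

    ``orientation="random"`` (default) orients every edge uniformly at
    random, which keeps directed cycles in the graph so that non-identity
    stationary chains exist on it; ``"forward"`` orients each edge from the
    newer to the older endpoint (yielding an acyclic graph).
    """
    if not (n > m_attach >= 1):
        raise ValueError("need n > m_attach >= 1")
    if orientation not in ("random", "forward"):
        raise ValueError("orientation must be 'random' or 'forward'")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n)]
    degree = np.zeros(n)
    edges: list[tuple[int, int]] = []

    def orient(new: int, old: int) -> tuple[int, int]:
        if orientation == "forward" or rng.random() < 0.5:
            return (new, old)
        return (old, new)

    seed_size = m_attach + 1
    for j in range(seed_size):
        for i in range(j):
            edges.append(orient(j, i))
            degree[i] += 1
            degree[j] += 1
    for t in range(seed_size, n):
        w = degree[:t] + 1.0
        targets = rng.choice(t, size=m_attach, replace=False, p=w / w.sum())
        for tgt in targets:
            edges.append(orient(t, int(tgt)))
            degree[tgt] += 1
            degree[t] += 1
    rows, cols = zip(*edges)
    adj = sp.csr_matrix(
        (np.ones(len(edges), dtype=np.int8), (rows, cols)), shape=(n, n)
    )
    return GeneNetwork(genes, adj)


def degree_powerlaw_slope(net: GeneNetwork, n_bins: int = 12) -> float:
    """Least-squares log-log slope of the binned total-degree tail."""
    deg = net.total_degree().astype(float)
    deg = deg[deg > 0]
    edges = np.logspace(np.log10(deg.min()), np.log10(deg.max() * (1 + 1e-9)), n_bins + 1)
    counts, edges = np.histogram(deg, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / widths
    keep = dens > 0
    slope, _ = np.polyfit(np.log10(centers[keep]), np.log10(dens[keep]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    net: GeneNetwork,
    module,
    q: int,
    effect: float,
    seed: int,
    module_sigma: float = 0.25,
) -> ExpressionDataset:
    """Per-sample expression with a planted co-expressed module.

    Background entries are log-normal(0, 1).  Module genes share a common
    per-sample positive factor ``exp(effect * g_s)`` with ``g_s`` close to 1,
    on top of a mean-compensated log-normal with residual sigma
    ``module_sigma`` (a co-regulated module fluctuates coherently, with less
    independent noise than unrelated genes; the compensation keeps the
    per-gene mean equal to the background mean).  At ``effect = 0`` no module
    treatment is applied at all: module genes are exactly background noise.
    """
    if q < 2:
        raise ValueError("need at least 2 samples")
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    module = tuple(module)
    unknown = [g for g in module if g not in net]
    if unknown:
        raise KeyError(f"module genes absent from network: {unknown[:5]}")
    rng = np.random.default_rng(seed)
    n = net.n
    x = rng.lognormal(mean=0.0, sigma=1.0, size=(n, q))
    if module and effect > 0:
        idx = [net.index_of(g) for g in module]
        g_s = np.exp(0.1 * rng.standard_normal(q))  # shared per-sample wobble
        factor = np.exp(effect * g_s)
        mu = (1.0 - module_sigma**2) / 2.0  # match background mean e^{1/2}
        resid = rng.lognormal(mean=mu, sigma=module_sigma, size=(len(idx), q))
        x[idx, :] = factor[None, :] * resid
    samples = [f"S{k:03d}" for k in range(q)]
    return ExpressionDataset(pd.DataFrame(x, index=list(net.gene_ids), columns=samples))


# ---------------------------------------------------------------------------
# methylation


def generate_beta(
    gene_ids,
    sample_ids,
    weights: tuple[float, float, float] = (0.45, 0.45, 0.10),
    forced: dict | None = None,
    seed: int = 0,
    unmethylated_genes=(),
) -> BetaMatrix:
    """Bimodal beta values: w_low Beta(3,19) + w_high Beta(19,3) + w_mid U(0,1).

    The component modes sit exactly at 0.1 and 0.9.  ``forced`` maps sample
    id -> genes whose entries are drawn from Beta(19,3) truncated to
    [0.6, 1] (always classified fully methylated at the default threshold);
    ``unmethylated_genes`` are always drawn from the low component.
    """
    gene_ids = [str(g) for g in gene_ids]
    sample_ids = [str(s) for s in sample_ids]
    w = np.asarray(weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    forced = forced or {}
    for s, genes in forced.items():
        if s not in sample_ids:
            raise KeyError(f"forced sample {s!r} not in sample_ids")
        bad = [g for g in genes if g not in gene_ids]
        if bad:
            raise KeyError(f"forced genes not in gene_ids: {bad[:5]}")
    rng = np.random.default_rng(seed)
    n, q = len(gene_ids), len(sample_ids)
    comp = rng.choice(3, size=(n, q), p=w)
    beta = np.where(
        comp == 0,
        rng.beta(3, 19, size=(n, q)),
        np.where(comp == 1, rng.beta(19, 3, size=(n, q)), rng.uniform(size=(n, q))),
    )
    gi = {g: i for i, g in enumerate(gene_ids)}
    lo_idx = [gi[g] for g in unmethylated_genes]
    if lo_idx:
        beta[lo_idx, :] = rng.beta(3, 19, size=(len(lo_idx), q))
    cdf_06 = stats.beta.cdf(0.6, 19, 3)
    for s, genes in forced.items():
        j = sample_ids.index(s)
        for g in genes:
            u = rng.uniform(cdf_06, 1.0)
            beta[gi[g], j] = stats.beta.ppf(u, 19, 3)
    return BetaMatrix(pd.DataFrame(beta, index=gene_ids, columns=sample_ids))


# ---------------------------------------------------------------------------
# full datasets


def simulate_dataset(
    n: int = 300,
    q: int = 20,
    module_size: int = 6,
    n_candidates: int = 30,
    effect: float = 4.0,
    m_attach: int = 5,
    methylation_rate: float = 0.05,
    seed: int = 0,
) -> SimulatedDataset:
    """Generate a full dataset with a planted methylation-stable core module.

    The module is planted among mid-degree genes of the network's recurrent
    part (nodes not frozen to the identity by feasibility), mirroring that
    driver modules are embedded in the regulatory cycle structure rather than
    in the tree-like periphery; module beta values come from the unmethylated
    mixture component, matching the observed methylation stability of core
    genes.  Candidates are the module plus random recurrent-part genes; each
    sample additionally forces ``methylation_rate`` of the non-module genes
    to fully methylated betas.
    """
    if not (0 < module_size <= n_candidates <= n):
        raise ValueError("need 0 < module_size <= n_candidates <= n")
    rng = np.random.default_rng(seed)
    net = generate_network(n, m_attach, seed=int(rng.integers(2**31)))
    aug = net.add_self_loops()
    free = ~maxent.frozen_nodes(aug)
    deg = net.total_degree()
    free_idx = np.flatnonzero(free)
    lo, hi = np.percentile(deg[free_idx], [40, 90])
    band = free_idx[(deg[free_idx] >= lo) & (deg[free_idx] <= hi)]
    pool = band if len(band) >= module_size else free_idx
    # a co-regulated module of comparable connectivity: prefer genes sharing
    # the most common degree value in the band, so module scores are co-ranked
    values, counts = np.unique(deg[pool], return_counts=True)
    eligible = values[counts >= module_size]
    if len(eligible):
        d_star = eligible[np.argmax(counts[counts >= module_size])]
        pool = pool[deg[pool] == d_star]
    module_idx = rng.choice(pool, size=module_size, replace=False)
    module = tuple(net.gene_ids[i] for i in sorted(module_idx))
    # wire the module as a directed regulatory loop: a co-regulated module is
    # an interconnected motif, and the cycle keeps it inside the recurrent
    # part of every methylation-pruned network
    cycle = list(sorted(module_idx))
    adj = net.adjacency.tolil(copy=True)
    for a, b in zip(cycle, cycle[1:] + cycle[:1]):
        adj[a, b] = 1
    net = GeneNetwork(net.gene_ids, adj.tocsr())
    rest = np.setdiff1d(free_idx, module_idx)
    extra = rng.choice(rest, size=n_candidates - module_size, replace=False)
    candidates = tuple(sorted(module + tuple(net.gene_ids[i] for i in extra)))

    expr = generate_expression(
        net, module, q=q, effect=effect, seed=int(rng.integers(2**31))
    )
    non_module = [g for g in net.gene_ids if g not in module]
    n_forced = int(round(methylation_rate * len(non_module)))
    forced = {
        s: tuple(sorted(rng.choice(non_module, size=n_forced, replace=False)))
        for s in expr.sample_ids
    }
    beta = generate_beta(
        net.gene_ids,
        expr.sample_ids,
        forced=forced,
        seed=int(rng.integers(2**31)),
        unmethylated_genes=module,
    )
    truth = SyntheticTruth(
        module=module,
        candidates=candidates,
        forced_methylated=forced,
        seed=seed,
        params=dict(
            n=n,
            q=q,
            module_size=module_size,
            n_candidates=n_candidates,
            effect=effect,
            m_attach=m_attach,
            methylation_rate=methylation_rate,
        ),
    )
    return SimulatedDataset(network=net, expression=expr, beta=beta, truth=truth)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict:
    """Write network/expression/beta TSVs, candidate list, and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.network.write_edge_tsv(outdir / "network.tsv")
    ds.expression.write_tsv(outdir / "expression.tsv")
    ds.beta.write_tsv(outdir / "beta.tsv")
    (outdir / "candidates.txt").write_text(
        "".join(f"{g}\n" for g in ds.truth.candidates)
    )
    ds.truth.to_json(outdir / "truth.json")
    return {
        "network": "network.tsv",
        "expression": "expression.tsv",
        "beta": "beta.tsv",
        "candidates": "candidates.txt",
        "truth": "truth.json",
    }


# ---------------------------------------------------------------------------
# small fixtures for oracle and bridge tests


def random_connected_network(n: int, seed: int, extra_edges: int | None = None) -> GeneNetwork:
    """Random strongly connected directed network, self-loops included.

    A random Hamiltonian cycle guarantees strong connectivity (so the
    stationary-flow polytope has a nonempty interior and the fitted chain is
    nondegenerate); ``extra_edges`` additional distinct directed pairs
    (default n) are layered on top.
    """
    rng = np.random.default_rng(seed)
    if extra_edges is None:
        extra_edges = n
    genes = [f"g{i}" for i in range(n)]
    order = rng.permutation(n)
    pairs = set()
    for a, b in zip(order, np.roll(order, -1)):
        pairs.add((int(a), int(b)))
    attempts = 0
    while len(pairs) < n + extra_edges and attempts < 50 * (extra_edges + 1):
        i, j = rng.integers(n, size=2)
        attempts += 1
        if i != j:
            pairs.add((int(i), int(j)))
    edges = [(genes[i], genes[j]) for i, j in sorted(pairs)]
    edges += [(g, g) for g in genes]
    return GeneNetwork.from_edges(edges, gene_ids=genes)


def connector_fixture() -> tuple[GeneNetwork, tuple[str, str], str]:
    """Tiny planted topology whose unique bridge is the designated connector.

    Two core genes sit in separate lobes; the connector is the only node
    adjacent to both.  Returns ``(network, core_genes, connector)``.
    """
    edges = [
        ("c1", "u1"), ("u2", "c1"),          # lobe around c1
        ("c2", "v1"), ("v2", "c2"),          # lobe around c2
        ("c1", "bridge"), ("bridge", "c2"),  # the planted connector
        ("u1", "u2"), ("v1", "v2"),
    ]
    net = GeneNetwork.from_edges(edges)
    return net, ("c1", "c2"), "bridge"
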