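"""Data model and I/O for gene networks, expression matrices, and methylation beta values.

A :class:`GeneNetwork` is a directed graph over gene symbols stored as a sparse
adjacency indicator.  The transition matrices fitted elsewhere in the package
live on the support of this adjacency, augmented with self-loops (every
diagonal entry set to one), which guarantees that the identity chain is always
feasible for any strictly positive stationary distribution.

Expression and beta matrices are thin validated wrappers around pandas
DataFrames (genes in rows, samples in columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "ExpressionDataset",
    "BetaMatrix",
    "NetworkParseError",
    "load_network",
    "write_network",
    "in_strength_distribution",
]


class NetworkParseError(ValueError):
    """Raised when a network file cannot be parsed; carries the line number."""


class GeneNetwork:
    """Directed gene-interaction network.

    Parameters
    ----------
    gene_ids:
        Ordered unique gene symbols (whitespace already trimmed).
    adjacency:
        ``n x n`` sparse 0/1 indicator; ``adjacency[i, j] == 1`` means there is
        a directed edge from gene ``i`` to gene ``j``.
    """

    def __init__(self, gene_ids: Sequence[str], adjacency: sp.spmatrix):
        gene_ids = tuple(str(g) for g in gene_ids)
        if len(gene_ids) == 0:
            raise ValueError("network must contain at least one gene")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("gene_ids must be unique")
        adjacency = sp.csr_matrix(adjacency, dtype=np.int8)
        if adjacency.shape != (len(gene_ids), len(gene_ids)):
            raise ValueError("adjacency shape does not match gene_ids")
        adjacency.eliminate_zeros()
        if adjacency.nnz and adjacency.data.max() > 1:
            adjacency.data[:] = 1
        self.gene_ids = gene_ids
        self.adjacency = adjacency
        self._index = {g: i for i, g in enumerate(gene_ids)}

    # -- basic properties ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        """Number of stored directed edges (including explicit self-loops)."""
        return int(self.adjacency.nnz)

    @property
    def has_self_loops(self) -> bool:
        return bool(np.all(self.adjacency.diagonal() == 1))

    def index_of(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def edges(self) -> list[tuple[str, str]]:
        coo = self.adjacency.tocoo()
        return [(self.gene_ids[i], self.gene_ids[j]) for i, j in zip(coo.row, coo.col)]

    def in_degree(self) -> np.ndarray:
        """Number of edges pointing at each gene (self-loops included)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(int)

    def out_degree(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    def total_degree(self) -> np.ndarray:
        return self.in_degree() + self.out_degree()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        gene_ids: Sequence[str] | None = None,
    ) -> "GeneNetwork":
        """Build a network from (source, target) pairs, deduplicating edges."""
        edges = list(edges)
        if gene_ids is None:
            seen: dict[str, None] = {}
            for s, t in edges:
                seen.setdefault(str(s).strip(), None)
                seen.setdefault(str(t).strip(), None)
            gene_ids = list(seen)
        if not gene_ids:
            raise ValueError("no edges: cannot build an empty network")
        index = {g: i for i, g in enumerate(gene_ids)}
        pairs = set()
        dropped = 0
        for s, t in edges:
            s, t = str(s).strip(), str(t).strip()
            key = (index[s], index[t])
            if key in pairs:
                dropped += 1
            else:
                pairs.add(key)
        if dropped:
            logger.info("dropped %d duplicate edges", dropped)
        if pairs:
            rows, cols = zip(*sorted(pairs))
            adj = sp.csr_matrix(
                (np.ones(len(pairs), dtype=np.int8), (rows, cols)),
                shape=(len(gene_ids), len(gene_ids)),
            )
        else:
            adj = sp.csr_matrix((len(gene_ids), len(gene_ids)), dtype=np.int8)
        return cls(gene_ids, adj)

    def add_self_loops(self) -> "GeneNetwork":
        """Return a copy with every diagonal entry set to one (idempotent)."""
        adj = self.adjacency.tolil(copy=True)
        adj.setdiag(1)
        return GeneNetwork(self.gene_ids, adj.tocsr())

    def subnetwork(self, keep: Sequence[str]) -> "GeneNetwork":
        """Induced subnetwork on ``keep``, preserving this network's gene order."""
        keep_set = set(keep)
        unknown = keep_set - set(self.gene_ids)
        if unknown:
            raise KeyError(f"genes not in network: {sorted(unknown)[:5]}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in keep_set]
        genes = [self.gene_ids[i] for i in idx]
        adj = self.adjacency[idx][:, idx]
        return GeneNetwork(genes, adj)

    # -- export -------------------------------------------------------------

    def to_networkx(self, weights: sp.spmatrix | None = None) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.gene_ids)
        if weights is None:
            g.add_edges_from(self.edges())
        else:
            coo = sp.csr_matrix(weights).tocoo()
            for i, j, w in zip(coo.row, coo.col, coo.data):
                g.add_edge(self.gene_ids[i], self.gene_ids[j], weight=float(w))
        return g

    def write_edge_tsv(self, path: str | Path, weights: sp.spmatrix | None = None) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if weights is None:
                for s, t in self.edges():
                    fh.write(f"{s}\t{t}\n")
            else:
                coo = sp.csr_matrix(weights).tocoo()
                order = np.lexsort((coo.col, coo.row))
                for k in order:
                    i, j, w = coo.row[k], coo.col[k], coo.data[k]
                    fh.write(f"{self.gene_ids[i]}\t{self.gene_ids[j]}\t{w!r}\n")

    def write_graphml(self, path: str | Path, weights: sp.spmatrix | None = None) -> None:
        nx.write_graphml(self.to_networkx(weights), str(path))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneNetwork(n={self.n}, edges={self.n_edges})"


# ---------------------------------------------------------------------------
# parsing


def _parse_edge_tsv(path: Path) -> list[tuple[str, str]]:
    edges = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise NetworkParseError(
                    f"{path}: line {lineno}: expected at least 2 columns, got {len(fields)}"
                )
            edges.append((fields[0].strip(), fields[1].strip()))
    return edges


def _parse_biogrid_tab3(path: Path, symmetrize: bool) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lstrip("#").strip().lower(): c for c in df.columns}
    try:
        col_a = cols["official symbol interactor a"]
        col_b = cols["official symbol interactor b"]
    except KeyError as exc:
        raise NetworkParseError(
            f"{path}: BioGRID TAB3 official-symbol columns not found"
        ) from exc
    edges = []
    for a, b in zip(df[col_a], df[col_b]):
        if pd.isna(a) or pd.isna(b):
            continue
        a, b = str(a).strip(), str(b).strip()
        edges.append((a, b))
        if symmetrize and a != b:
            edges.append((b, a))
    return edges


def load_network(
    path: str | Path,
    fmt: str = "edge_tsv",
    symmetrize: bool = False,
) -> GeneNetwork:
    """Load a directed network from an edge-list TSV or a BioGRID TAB3 file.

    Edge direction for BioGRID rows is interactor A -> interactor B;
    ``symmetrize=True`` additionally adds the reverse edge.  Self-loops are
    NOT added here; call :meth:`GeneNetwork.add_self_loops` before fitting.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "edge_tsv":
        edges = _parse_edge_tsv(path)
        if symmetrize:
            edges = edges + [(t, s) for s, t in edges if s != t]
    elif fmt == "biogrid_tab3":
        edges = _parse_biogrid_tab3(path, symmetrize)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")
    if not edges:
        raise ValueError(f"{path}: no edges")
    return GeneNetwork.from_edges(edges)


def write_network(net: GeneNetwork, path: str | Path) -> None:
    """Write the edge list as a two-column TSV (round-trips with load_network)."""
    net.write_edge_tsv(path)


# ---------------------------------------------------------------------------
# expression / beta containers


@dataclass
class ExpressionDataset:
    """Nonnegative gene x sample expression matrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")
        if (vals < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str).str.strip()
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    def align(self, net: GeneNetwork) -> "ExpressionDataset":
        """Reindex to the network's genes.

        Genes absent from the network are dropped with a warning; network genes
        without an expression row get zero expression (handled downstream by
        the zero-expression policy).
        """
        extra = [g for g in self.values.index if g not in net]
        if extra:
            logger.warning(
                "dropping %d expression genes absent from the network", len(extra)
            )
        aligned = self.values.reindex(net.gene_ids).fillna(0.0)
        return ExpressionDataset(aligned)


@dataclass
class BetaMatrix:
    """Methylation beta values in [0, 1]; NaN marks missing entries."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        present = vals[~np.isnan(vals)]
        if present.size and (present.min() < 0 or present.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BetaMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
        df.index = df.index.astype(str).str.strip()
        if df.index.has_duplicates:
            logger.warning("multiple beta rows per gene: averaging duplicates")
            df = df.groupby(level=0, sort=False).mean()
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")

    def column(self, sample: str) -> pd.Series:
        return self.values[sample]


# ---------------------------------------------------------------------------
# diagnostics


def in_strength_distribution(transition, n_bins: int):
    """Histogram of transition-matrix column sums (continuous in-strengths).

    Bins are logarithmically spaced over the occupied range; counts always
    sum to the number of genes.

    Returns ``(strengths, bin_edges, counts)``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    matrix = getattr(transition, "matrix", transition)
    if matrix is None:
        raise ValueError("transition matrix is not fitted")
    matrix = sp.csr_matrix(matrix)
    strengths = np.asarray(matrix.sum(axis=0)).ravel()
    positive = strengths[strengths > 0]
    if positive.size == 0:
        raise ValueError("transition matrix has no positive column sums")
    lo, hi = positive.min(), strengths.max()
    if lo == hi or n_bins == 1:
        edges = np.array([lo * (1 - 1e-12), hi * (1 + 1e-12)])
    else:
        edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
        edges[0] *= 1 - 1e-12
        edges[-1] *= 1 + 1e-12
    counts, edges = np.histogram(strengths, bins=edges)
    return strengths, edges, counts
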