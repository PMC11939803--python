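"""Maximum-entropy Markov transition matrices on a fixed network support.

Given a directed network ``A`` (with self-loops) and a strictly positive
stationary distribution ``pi`` derived from one sample's expression profile,
the fit selects, among all row-stochastic matrices ``P`` supported on ``A``
with ``pi P = pi``, the one maximising the Markov Chain Entropy

    MCE = - sum_{(i,j) in support} pi_i p_ij log(pi_i p_ij)     (nats).

On the flow scale ``q_ij = pi_i p_ij`` this is the classical maximum-entropy
matrix-scaling problem with prescribed row and column margins both equal to
``pi``: the optimum has the product form ``q = diag(u) A diag(v)`` and is
found by Sinkhorn / iterative proportional fitting.  The alternating updates
are exactly the fixed-point iteration on the Lagrange multipliers of the
constrained program (``alpha_i = u_i / pi_i``, ``beta_j = v_j``).

Boundary optima.  Stationarity confines flow to the strongly connected
components of the support: a source component of the condensation receives no
flow from outside, so it may export none, and removing it makes the next
component a source — hence every edge between distinct components carries
zero flow in *every* feasible matrix.  The fit therefore restricts the
support to within-component edges first (an exact presolve that leaves the
feasible set unchanged).  Within a strongly connected component whose nodes
all carry self-loops an interior feasible flow always exists (route a small
constant flow around a cycle through each edge and absorb the margin
remainder on the self-loops), so after the reduction the scaling iteration
converges linearly instead of stalling at a boundary.  Nodes forming
singleton components keep only their self-loop: ``p_ii = 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, minimize
from scipy.special import entr, xlogy

from .network import GeneNetwork

__all__ = [
    "StationaryDistribution",
    "TransitionMatrix",
    "ScalingFactors",
    "ReconstructionResult",
    "stationary_from_expression",
    "fit_transition_matrix",
    "markov_chain_entropy",
    "flow_entropy",
    "oracle_max_entropy",
    "frozen_nodes",
]


@dataclass
class StationaryDistribution:
    """Probability vector over the network's genes (the chain's invariant law)."""

    pi: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.gene_ids = tuple(self.gene_ids)
        if self.pi.ndim != 1 or len(self.pi) != len(self.gene_ids):
            raise ValueError("pi and gene_ids must have the same length")
        if (self.pi <= 0).any():
            raise ValueError("pi must be strictly positive")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1 within 1e-12")


@dataclass
class TransitionMatrix:
    """Fitted transition matrix with its residual certificates."""

    matrix: sp.csr_matrix
    pi: np.ndarray
    gene_ids: tuple[str, ...]
    support: sp.csr_matrix
    row_residual: float
    stationarity_residual: float
    n_iter: int
    converged: bool

    def flows(self) -> sp.csr_matrix:
        """Edge-flow matrix ``q_ij = pi_i p_ij`` on the support."""
        return sp.csr_matrix(sp.diags(self.pi) @ self.matrix)


@dataclass
class ScalingFactors:
    """Diagonal scaling vectors reproducing P on the (reduced) support."""

    alpha: np.ndarray
    beta: np.ndarray
    converged: bool
    residual: float


@dataclass
class ReconstructionResult:
    transition: TransitionMatrix
    scaling: ScalingFactors
    mce: float


# ---------------------------------------------------------------------------
# stationary distribution


def stationary_from_expression(
    x,
    policy: str = "drop_zero",
    eps: float = 1e-6,
    gene_ids=None,
):
    """L1-normalise an expression vector into a stationary distribution.

    Returns ``(StationaryDistribution, retained_mask)``.  Under
    ``policy="drop_zero"`` genes with zero expression are removed from the
    sample's network before fitting (mask False); under ``"pseudocount"``
    ``eps`` is added to every entry first and all genes are retained.
    """
    if gene_ids is None:
        gene_ids = getattr(x, "index", None)
        if gene_ids is None:
            gene_ids = [str(i) for i in range(len(x))]
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expression vector must be 1-dimensional")
    if (x < 0).any():
        raise ValueError("expression values must be nonnegative")
    if not np.any(x > 0):
        raise ValueError("degenerate sample: all-zero expression vector")
    gene_ids = tuple(str(g) for g in gene_ids)
    if policy == "drop_zero":
        mask = x > 0
    elif policy == "pseudocount":
        if eps <= 0:
            raise ValueError("pseudocount eps must be positive")
        x = x + eps
        mask = np.ones(len(x), dtype=bool)
    else:
        raise ValueError(f"unknown zero-expression policy: {policy!r}")
    kept = x[mask]
    pi = kept / kept.sum()
    kept_genes = tuple(g for g, m in zip(gene_ids, mask) if m)
    return StationaryDistribution(pi, kept_genes), mask


# ---------------------------------------------------------------------------
# feasibility presolve


def strongly_connected_labels(net: GeneNetwork) -> np.ndarray:
    """Strongly-connected-component label of each node."""
    _, labels = sp.csgraph.connected_components(
        net.adjacency, directed=True, connection="strong"
    )
    return labels


def frozen_nodes(net: GeneNetwork) -> np.ndarray:
    """Mask of nodes forced to ``p_ii = 1`` (singleton strong components).

    Feasible stationary flow never crosses between strong components, so a
    node forming its own component keeps only its self-loop.
    """
    if not net.has_self_loops:
        raise ValueError("network must be augmented with self-loops")
    labels = strongly_connected_labels(net)
    _, sizes = np.unique(labels, return_counts=True)
    return sizes[labels] == 1


def _recurrent_support(adj: sp.csr_matrix, labels: np.ndarray) -> sp.csr_matrix:
    """Support restricted to within-component edges (plus all self-loops)."""
    coo = adj.tocoo()
    keep = labels[coo.row] == labels[coo.col]
    return sp.csr_matrix(
        (np.ones(int(keep.sum()), dtype=np.int8), (coo.row[keep], coo.col[keep])),
        shape=adj.shape,
    )


# ---------------------------------------------------------------------------
# the fit


def fit_transition_matrix(
    net: GeneNetwork,
    stationary: StationaryDistribution,
    tol: float = 1e-8,
    max_iter: int = 50_000,
    beta0: np.ndarray | None = None,
) -> ReconstructionResult:
    """Fit the maximum-entropy transition matrix by iterative scaling.

    ``net`` must be augmented with self-loops and its genes must match
    ``stationary.gene_ids`` exactly.  Convergence is declared when the max of
    the L-inf row-sum residual and the L-inf stationarity residual falls
    below ``tol``; hitting ``max_iter`` returns a result with
    ``converged=False`` and a warning (never silently).
    """
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    if tuple(net.gene_ids) != tuple(stationary.gene_ids):
        raise ValueError("network genes and stationary distribution do not align")
    if not net.has_self_loops:
        raise ValueError("network must be augmented with self-loops before fitting")
    n = net.n
    pi = stationary.pi
    labels = strongly_connected_labels(net)
    support = _recurrent_support(net.adjacency, labels)

    a = sp.csr_matrix(support, dtype=float)
    at = sp.csr_matrix(a.T)
    v = np.ones(n) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    if v.shape != (n,) or (v <= 0).any():
        raise ValueError("beta0 must be a strictly positive vector of length n")
    converged = False
    av = a @ v
    for n_iter in range(1, max_iter + 1):
        u = pi / av           # flow scale: q = diag(u) A diag(v)
        atu = at @ u
        v = pi / atu
        av = a @ v
        row_res = np.max(np.abs(u * av / pi - 1.0))
        stat_res = np.max(np.abs(v * atu - pi))
        if max(row_res, stat_res) < tol:
            converged = True
            break

    coo = support.tocoo()
    data = u[coo.row] * v[coo.col] / pi[coo.row]
    matrix = sp.csr_matrix((data, (coo.row, coo.col)), shape=(n, n))

    row_residual = float(np.max(np.abs(np.asarray(matrix.sum(axis=1)).ravel() - 1.0)))
    stationarity_residual = float(np.max(np.abs(pi @ matrix - pi)))
    if not converged:
        warnings.warn(
            f"iterative scaling did not converge in {max_iter} iterations "
            f"(row residual {row_residual:.2e}, stationarity residual "
            f"{stationarity_residual:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = u / pi
    beta = v
    tm = TransitionMatrix(
        matrix=matrix,
        pi=pi,
        gene_ids=net.gene_ids,
        support=support,
        row_residual=row_residual,
        stationarity_residual=stationarity_residual,
        n_iter=n_iter,
        converged=converged,
    )
    scaling = ScalingFactors(
        alpha=alpha,
        beta=beta,
        converged=converged,
        residual=max(row_residual, stationarity_residual),
    )
    return ReconstructionResult(transition=tm, scaling=scaling, mce=markov_chain_entropy(tm))


# ---------------------------------------------------------------------------
# entropies


def markov_chain_entropy(tm: TransitionMatrix) -> float:
    """MCE = -sum over support of q log q with q = pi_i p_ij (0 log 0 := 0)."""
    if len(tm.pi) != tm.matrix.shape[0]:
        raise ValueError("pi and transition matrix dimensions do not match")
    return float(entr(tm.flows().data).sum())


def flow_entropy(tm: TransitionMatrix, direction: str = "out") -> np.ndarray:
    """Per-gene flow entropy (nats).

    ``direction="out"`` (the printed definition) sums ``-q_ij log q_ij`` over
    gene i's outgoing edges; ``"in"`` sums over incoming edges.  Either way
    the values partition the MCE: their total equals
    :func:`markov_chain_entropy` exactly.
    """
    q = tm.flows()
    q.data = entr(q.data)
    axis = 1 if direction == "out" else 0
    if direction not in ("out", "in"):
        raise ValueError("direction must be 'out' or 'in'")
    return np.asarray(q.sum(axis=axis)).ravel()


# ---------------------------------------------------------------------------
# brute-force oracle


def oracle_max_entropy(
    net: GeneNetwork,
    stationary: StationaryDistribution,
    n_max: int = 8,
) -> TransitionMatrix:
    """Solve the maximum-entropy program directly with a dense NLP solver.

    Intended as an independent cross-check on tiny graphs (``n <= 8``): the
    free variables are the flows on the support, the objective is the flow
    entropy, and the row/column margins are linear equality constraints.
    """
    if net.n > n_max:
        raise ValueError(f"oracle refuses n > {n_max} (dense solve only)")
    if not net.has_self_loops:
        raise ValueError("network must be augmented with self-loops")
    if tuple(net.gene_ids) != tuple(stationary.gene_ids):
        raise ValueError("network genes and stationary distribution do not align")
    n = net.n
    pi = stationary.pi
    coo = net.adjacency.tocoo()
    rows, cols = coo.row, coo.col
    k = len(rows)

    # margin constraints: rows sum to pi_i, columns sum to pi_j; the last
    # column constraint is implied by the others (both margin sets total 1)
    # and dropping it keeps the constraint Jacobian full-rank.
    a_eq = np.zeros((2 * n - 1, k))
    for e in range(k):
        a_eq[rows[e], e] = 1.0
        if cols[e] < n - 1:
            a_eq[n + cols[e], e] = 1.0
    b_eq = np.concatenate([pi, pi[:-1]])

    floor = 1e-12

    def negent(q):
        return float(xlogy(q, q).sum())

    def grad(q):
        return np.log(np.maximum(q, floor)) + 1.0

    # feasible start: identity flows blended with a uniform row spread
    q0 = np.zeros(k)
    out_deg = np.asarray(net.adjacency.sum(axis=1)).ravel()
    for e in range(k):
        q0[e] = 0.5 * pi[rows[e]] / out_deg[rows[e]]
        if rows[e] == cols[e]:
            q0[e] += 0.5 * pi[rows[e]]
    res = minimize(
        negent,
        q0,
        jac=grad,
        method="SLSQP",
        bounds=[(floor, 1.0)] * k,
        constraints=[LinearConstraint(a_eq, b_eq, b_eq)],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    q = np.maximum(res.x, 0.0)
    data = q / pi[rows]
    matrix = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    row_residual = float(np.max(np.abs(np.asarray(matrix.sum(axis=1)).ravel() - 1.0)))
    stationarity_residual = float(np.max(np.abs(pi @ matrix - pi)))
    return TransitionMatrix(
        matrix=matrix,
        pi=pi,
        gene_ids=net.gene_ids,
        support=net.adjacency.copy(),
        row_residual=row_residual,
        stationarity_residual=stationarity_residual,
        n_iter=int(res.nit),
        converged=bool(res.success),
    )
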