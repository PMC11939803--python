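"""Beta-value classification, methylation-pruned networks, and the methylation index.

The working model: promoter hypermethylation silences a gene, so for each
sample the genes called *fully methylated* (beta >= 0.6 by default) are
removed from the network, giving the methylation-specific network G1
alongside the original network G0.  Refitting the maximum-entropy chain on G1
and comparing each surviving gene's Markov Flow Entropy against its G0 value
yields the network methylation index

    rho(i) = (MFE1(i) - MFE0(i)) / MFE0(i),

negative when the methylation of other genes inhibits gene i's information
flow, positive when it facilitates it.  Genes pruned from G1 have no rho;
counting those absences per gene across a cohort is the absence census.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import maxent
from .network import GeneNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "FULLY_METHYLATED",
    "PARTIALLY_METHYLATED",
    "UNMETHYLATED",
    "MISSING",
    "FlowEntropyVector",
    "classify_beta",
    "build_g1",
    "markov_flow_entropy",
    "network_methylation_index",
    "absence_census",
]

FULLY_METHYLATED = "fully_methylated"
PARTIALLY_METHYLATED = "partially_methylated"
UNMETHYLATED = "unmethylated"
MISSING = "missing"


def classify_beta(beta, lower: float = 0.2, upper: float = 0.6):
    """Threshold beta values into methylation calls.

    ``beta >= upper`` -> fully methylated; ``beta <= lower`` -> unmethylated;
    strictly between -> partially methylated; NaN -> missing.  Accepts a
    scalar or an array/Series (returned as an object array / Series).
    """
    if not (0 <= lower < upper <= 1):
        raise ValueError("thresholds must satisfy 0 <= lower < upper <= 1")
    arr = np.asarray(beta, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    present = ~np.isnan(arr)
    if present.any() and ((arr[present] < 0).any() or (arr[present] > 1).any()):
        raise ValueError("beta values must lie in [0, 1]")
    out = np.full(arr.shape, MISSING, dtype=object)
    out[present & (arr >= upper)] = FULLY_METHYLATED
    out[present & (arr <= lower)] = UNMETHYLATED
    out[present & (arr > lower) & (arr < upper)] = PARTIALLY_METHYLATED
    if scalar:
        return out[0]
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def build_g1(
    net: GeneNetwork,
    beta_col: pd.Series,
    x: pd.Series,
    lower: float = 0.2,
    upper: float = 0.6,
    policy: str = "drop_zero",
    eps: float = 1e-6,
):
    """Prune fully methylated genes and renormalise the stationary law.

    ``net`` must be the self-loop-augmented G0 topology; ``beta_col`` and
    ``x`` are the sample's beta and expression values indexed by gene symbol.
    Genes with a missing beta are retained (absence of evidence of
    methylation).  Returns ``(g1_network, stationary, retained_gene_ids)``
    where the network is the induced subgraph on the survivors (self-loops
    intact) restricted further by the zero-expression policy.
    """
    if not net.has_self_loops:
        raise ValueError("G0 network must be augmented with self-loops")
    beta_vals = beta_col.reindex(net.gene_ids)
    calls = classify_beta(beta_vals, lower=lower, upper=upper)
    n_missing = int((calls == MISSING).sum())
    if n_missing:
        logger.info("G1: retaining %d genes with missing beta values", n_missing)
    survivors = [g for g, c in zip(net.gene_ids, calls) if c != FULLY_METHYLATED]
    if not survivors:
        raise ValueError("empty G1: every gene is fully methylated")
    x_surv = x.reindex(survivors).fillna(0.0)
    stat, mask = maxent.stationary_from_expression(
        x_surv, policy=policy, eps=eps, gene_ids=survivors
    )
    retained = tuple(g for g, m in zip(survivors, mask) if m)
    g1 = net.subnetwork(retained)
    return g1, stat, retained


@dataclass
class FlowEntropyVector:
    """Per-gene Markov Flow Entropy for one sample and one network label."""

    values: pd.Series  # indexed by the full G0 gene set; NaN where absent
    sample: str
    label: str  # "G0" or "G1"


def markov_flow_entropy(
    tm: maxent.TransitionMatrix,
    sample: str = "",
    label: str = "G0",
    direction: str = "out",
    full_gene_ids=None,
) -> FlowEntropyVector:
    """Per-gene MFE of a fitted chain; sums to the MCE exactly.

    The default follows the printed out-edge form,
    ``MFE(i) = -sum_j pi_i p_ij log(pi_i p_ij)``; ``direction="in"`` gives the
    in-flow variant.  ``full_gene_ids`` reindexes the result to a larger gene
    universe with NaN marking genes absent from this network.
    """
    vals = pd.Series(
        maxent.flow_entropy(tm, direction=direction), index=list(tm.gene_ids)
    )
    if full_gene_ids is not None:
        vals = vals.reindex(list(full_gene_ids))
    return FlowEntropyVector(values=vals, sample=sample, label=label)


def network_methylation_index(
    mfe0: FlowEntropyVector, mfe1: FlowEntropyVector
) -> pd.Series:
    """rho(i) = (MFE1(i) - MFE0(i)) / MFE0(i); NaN where undefined.

    NaN marks genes pruned from G1 (or dropped from G0) and genes with
    MFE0 = 0.  Both vectors must come from the same sample.
    """
    if mfe0.sample != mfe1.sample:
        raise ValueError(
            f"sample mismatch: {mfe0.sample!r} (G0) vs {mfe1.sample!r} (G1)"
        )
    m0 = mfe0.values
    m1 = mfe1.values.reindex(m0.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (m1 - m0) / m0
    rho[(m0 == 0) | m0.isna() | m1.isna()] = np.nan
    return rho


def absence_census(rho_table: pd.DataFrame, genes=None) -> pd.Series:
    """Count samples with missing rho per gene, sorted descending.

    ``rho_table`` is genes x samples with NaN for missing.  ``genes``
    restricts the census to a candidate list; unknown candidates trigger a
    warning and are counted over zero available samples.  Ties are broken by
    symbol order.
    """
    if rho_table.shape[1] < 1:
        raise ValueError("rho table must cover at least one sample")
    if genes is not None:
        unknown = [g for g in genes if g not in rho_table.index]
        if unknown:
            logger.warning("candidate genes absent from rho table: %s", unknown)
        table = rho_table.reindex([g for g in genes])
    else:
        table = rho_table
    counts = table.isna().sum(axis=1).astype(int)
    order = sorted(counts.index, key=lambda g: (-counts[g], g))
    return counts.loc[order]
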