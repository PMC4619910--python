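"""Condition-specific Pearson coexpression networks.

One undirected simple graph is built per condition: nodes are genes, edges
connect gene pairs whose expression profiles correlate positively within
that condition.  With only three samples per condition (df = 1), two-sided
correlation p-values cannot fall below ~0.0127 even at r = 0.9998, so
adjusted-p filtering over all pairs is essentially powerless at genome
scale.  Two retention modes are therefore offered:

* ``r-threshold`` (default, r_min = 0.9998): retain pairs with r >= r_min —
  the threshold at which a 3-per-group design attains 80% power at the
  0.01 level under the Fisher-z approximation (see :mod:`coexmir.stats`).
* ``adjusted-p``: retain positive pairs with adjusted p <= alpha.

Both modes keep positive correlations only, modelling coexpression as a
positive effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from coexmir.expression import ExpressionMatrix

log = logging.getLogger(__name__)

#: Retention threshold reproducing the published minimum retained correlation.
DEFAULT_R_MIN = 0.9998

_ADJUST_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "bh": "fdr_bh",
    "fdr_bh": "fdr_bh",
    "none": None,
}


@dataclass
class CoexpressionNetwork:
    """Undirected simple coexpression graph for one condition.

    Edges carry ``r``, ``p_raw`` and ``p_adj`` attributes; only genes
    incident to at least one retained edge are nodes.
    """

    condition: str
    graph: nx.Graph
    r_min_retained: float | None  # minimum r among retained edges; None if empty

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    density: float
    degenerate: bool = False  # True when density is undefined (N < 2)


def pearson_all_pairs(matrix: ExpressionMatrix, condition: str) -> pd.DataFrame:
    """Pearson r for all gene pairs within one condition.

    Zero-variance genes (correlation undefined) are dropped with a logged
    count.  Returns a frame with columns ``gene_a``, ``gene_b``, ``r`` over
    exactly G*(G-1)/2 pairs of the retained genes, pairs in lexicographic
    order with gene_a < gene_b.
    """
    sub = matrix.condition_values(condition)
    if sub.shape[1] < 3:
        raise ValueError(f"condition {condition!r} has fewer than 3 samples")
    values = sub.to_numpy(float)
    variances = values.var(axis=1)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropping %d zero-variance genes in condition %s", n_dropped, condition)
    genes = np.asarray(sub.index)[keep]
    values = values[keep]
    order = np.argsort(genes)
    genes, values = genes[order], values[order]
    if len(genes) < 2:
        return pd.DataFrame(columns=["gene_a", "gene_b", "r"])
    corr = np.corrcoef(values)
    iu, ju = np.triu_indices(len(genes), k=1)
    return pd.DataFrame(
        {
            "gene_a": genes[iu],
            "gene_b": genes[ju],
            "r": np.clip(corr[iu, ju], -1.0, 1.0),
        }
    )


def correlation_pvalue(r, n: int):
    """Two-sided p for a Pearson correlation from n paired samples.

    Uses the exact-under-normality t transform t = r*sqrt((n-2)/(1-r^2))
    with n-2 degrees of freedom; |r| = 1 maps to p = 0 by convention.
    Accepts scalars or arrays.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    r_arr = np.clip(r_arr, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_arr * np.sqrt((n - 2) / (1.0 - r_arr**2))
    p = np.where(np.abs(r_arr) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    return float(p) if np.isscalar(r) or np.ndim(r) == 0 else p


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment: bonferroni, holm, hochberg or BH.

    All outputs are capped at 1; ties are handled stably by the underlying
    step procedures.  ``method='none'`` returns the input unchanged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    key = method.lower()
    if key not in _ADJUST_METHODS:
        raise ValueError(f"unknown adjustment method {method!r}")
    if _ADJUST_METHODS[key] is None or p.size == 0:
        return p.copy()
    return multipletests(p, method=_ADJUST_METHODS[key])[1]


def build_network(
    pairs: pd.DataFrame,
    condition: str,
    mode: str = "r-threshold",
    alpha: float = 0.05,
    r_min: float = DEFAULT_R_MIN,
    n_samples: int | None = None,
    adjust: str = "bonferroni",
) -> CoexpressionNetwork:
    """Retain edges from an all-pairs correlation table and build the graph.

    ``pairs`` needs columns gene_a, gene_b, r; in ``adjusted-p`` mode it
    also needs ``p_adj`` (computed from ``n_samples`` with ``adjust`` if
    absent).  Only positive correlations are ever retained.  Nodes are the
    genes incident to at least one retained edge.
    """
    if mode not in ("r-threshold", "adjusted-p"):
        raise ValueError(f"unknown mode {mode!r}")
    pairs = pairs.copy()
    if mode == "r-threshold":
        if not -1.0 <= r_min <= 1.0:
            raise ValueError("r_min must lie in [-1, 1]")
        keep = (pairs["r"] > 0) & (pairs["r"] >= r_min)
    else:
        if not 0.0 < alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if "p_adj" not in pairs.columns:
            if n_samples is None:
                raise ValueError("adjusted-p mode needs p_adj column or n_samples")
            pairs["p_raw"] = correlation_pvalue(pairs["r"].to_numpy(), n_samples)
            pairs["p_adj"] = adjust_pvalues(pairs["p_raw"].to_numpy(), adjust)
        keep = (pairs["r"] > 0) & (pairs["p_adj"] <= alpha)

    retained = pairs.loc[keep].sort_values(["gene_a", "gene_b"], kind="stable")
    graph = nx.Graph()
    for row in retained.itertuples(index=False):
        attrs = {"r": float(row.r)}
        if hasattr(row, "p_raw"):
            attrs["p_raw"] = float(row.p_raw)
        if hasattr(row, "p_adj"):
            attrs["p_adj"] = float(row.p_adj)
        graph.add_edge(row.gene_a, row.gene_b, **attrs)
    r_min_retained = float(retained["r"].min()) if len(retained) else None
    if r_min_retained is not None:
        log.info("condition %s: %d edges retained, min r = %.6g",
                 condition, graph.number_of_edges(), r_min_retained)
    return CoexpressionNetwork(condition=condition, graph=graph, r_min_retained=r_min_retained)


def coexpression_network(
    matrix: ExpressionMatrix,
    condition: str,
    mode: str = "r-threshold",
    alpha: float = 0.05,
    r_min: float = DEFAULT_R_MIN,
    adjust: str = "bonferroni",
) -> CoexpressionNetwork:
    """All-pairs correlation + retention in one call."""
    pairs = pearson_all_pairs(matrix, condition)
    n = len(matrix.condition_samples(condition))
    if mode == "adjusted-p":
        pairs["p_raw"] = correlation_pvalue(pairs["r"].to_numpy(), n)
        pairs["p_adj"] = adjust_pvalues(pairs["p_raw"].to_numpy(), adjust)
    return build_network(pairs, condition, mode=mode, alpha=alpha, r_min=r_min)


def network_stats(network: CoexpressionNetwork | nx.Graph) -> NetworkStats:
    """Node count, edge count and edge density E / (N*(N-1)/2).

    Density is reported as 0 with ``degenerate=True`` when fewer than two
    nodes make it undefined.  No rounding is applied here; round only at
    presentation.
    """
    graph = network.graph if isinstance(network, CoexpressionNetwork) else network
    n, e = graph.number_of_nodes(), graph.number_of_edges()
    if n < 2:
        return NetworkStats(n_nodes=n, n_edges=e, density=0.0, degenerate=True)
    return NetworkStats(n_nodes=n, n_edges=e, density=e / (n * (n - 1) / 2))


def edge_density(n_nodes: int, n_edges: int) -> float:
    """Density of a simple undirected graph from printed counts."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return n_edges / (n_nodes * (n_nodes - 1) / 2)


def compare_networks(net_a: CoexpressionNetwork, net_b: CoexpressionNetwork) -> dict:
    """Node/edge overlap between two networks (symmetric).

    Returns shared node and edge sets plus Jaccard indices (1.0 for two
    empty sets by convention).
    """
    def jaccard(x: set, y: set) -> float:
        union = x | y
        return 1.0 if not union else len(x & y) / len(union)

    shared_nodes = net_a.nodes & net_b.nodes
    shared_edges = net_a.edges & net_b.edges
    return {
        "shared_nodes": sorted(shared_nodes),
        "shared_edges": sorted(tuple(sorted(e)) for e in shared_edges),
        "n_shared_nodes": len(shared_nodes),
        "n_shared_edges": len(shared_edges),
        "node_jaccard": jaccard(net_a.nodes, net_b.nodes),
        "edge_jaccard": jaccard(net_a.edges, net_b.edges),
    }
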