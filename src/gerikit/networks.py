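"""Correlation graphs over simultaneously recorded neurons, with degree,
clustering coefficient, Newman modularity and subpopulation normalization.

Edges are defined against a per-pair circular-shift null: traces are
rotated by random offsets (preserving autocorrelation), and a pair is
connected when its Pearson correlation exceeds the chosen quantile
(default 0.99) of its own null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class CorrelationGraph:
    adjacency: np.ndarray  # boolean, symmetric, no self-edges
    edge_weight: np.ndarray  # correlation values
    node_labels: dict = field(default_factory=dict)  # label -> boolean array
    threshold_quantile: Optional[float] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a)):
            raise ValueError("no self-edges")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def correlation_matrix(traces: np.ndarray,
                       mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise Pearson correlation of (walking-masked) traces.

    ``traces`` is (n_cells, n_frames). Constant traces yield NaN rows and
    columns (correlation undefined), recorded as missing.
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 cells of trace data")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("masked duration is zero")
        x = x[:, mask]
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return r


def build_graph(traces: np.ndarray, mask: Optional[np.ndarray] = None,
                quantile: float = 0.99, n_shuffles: int = 100,
                seed: int = 0,
                node_labels: Optional[dict] = None) -> CorrelationGraph:
    """Threshold a correlation matrix against a circular-shift null.

    For each of ``n_shuffles`` rounds every trace is rolled by an
    independent random offset and the full correlation matrix recomputed;
    the edge criterion is r_ij > per-pair ``quantile`` of the null
    correlations. Requires >= 100 shuffles for a stable 99th percentile.
    """
    if n_shuffles < 100:
        raise ValueError("need >= 100 shuffles")
    x = np.asarray(traces, dtype=float)
    if mask is not None:
        x = x[:, np.asarray(mask, dtype=bool)]
    n, t = x.shape
    r_obs = correlation_matrix(x)
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, n, n))
    for k in range(n_shuffles):
        rolled = np.empty_like(x)
        for i in range(n):
            rolled[i] = np.roll(x[i], int(rng.integers(1, t)))
        null[k] = correlation_matrix(rolled)
    thresh = np.nanquantile(null, quantile, axis=0)
    adj = np.zeros((n, n), dtype=bool)
    valid = np.isfinite(r_obs)
    adj[valid] = r_obs[valid] > thresh[valid]
    np.fill_diagonal(adj, False)
    adj &= adj.T  # defensive; criterion is symmetric already
    return CorrelationGraph(adjacency=adj, edge_weight=r_obs,
                            node_labels=dict(node_labels or {}),
                            threshold_quantile=quantile)


def graph_metrics(g: CorrelationGraph) -> dict:
    """Per-node degree and clustering coefficient plus graph-level means.

    Clustering of node i = existing edges among neighbors / possible
    neighbor pairs; 0 when degree < 2.
    """
    a = g.adjacency.astype(int)
    deg = a.sum(axis=1)
    n = g.n_nodes
    clust = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        links = a[np.ix_(nb, nb)].sum() / 2
        clust[i] = links / (nb.size * (nb.size - 1) / 2)
    return {
        "degree": deg,
        "clustering": clust,
        "mean_degree": float(deg.mean()) if n else float("nan"),
        "mean_clustering": float(clust.mean()) if n else float("nan"),
    }


def modularity(g: CorrelationGraph, partition: Sequence) -> float:
    """Newman modularity Q = sum_c (e_cc - a_c^2) for a given partition.

    ``partition`` assigns a community label to every node; a missing label
    (None/NaN) raises. Q is 0 for the single-community partition and lies
    in [-0.5, 1].
    """
    labels = list(partition)
    if len(labels) != g.n_nodes:
        raise ValueError("partition must cover all nodes")
    for lab in labels:
        if lab is None or (isinstance(lab, float) and np.isnan(lab)):
            raise ValueError("node missing a community label")
    a = g.adjacency
    m = a.sum() / 2.0
    if m == 0:
        return 0.0
    labels_arr = np.asarray(labels)
    q = 0.0
    for c in np.unique(labels_arr):
        idx = labels_arr == c
        e_cc = a[np.ix_(idx, idx)].sum() / 2.0 / m
        a_c = a[idx].sum() / (2.0 * m)  # degree fraction of community c
        q += e_cc - a_c ** 2
    return float(q)


def normalize_subpopulation(g: CorrelationGraph, subpop: np.ndarray,
                            n_shuffles: int = 1000, seed: int = 0) -> dict:
    """Subpopulation metrics normalized to the whole population.

    Normalized degree / clustering = subpopulation mean over whole-
    population mean (None when the whole-population mean is zero).
    Normalized modularity = Q of the (subpop, rest) split over the mean |Q|
    of >= 1000 label shuffles, with a two-sided shuffle p-value on Q.
    """
    subpop = np.asarray(subpop, dtype=bool)
    if subpop.size != g.n_nodes:
        raise ValueError("subpop labels must cover all nodes")
    if subpop.sum() == 0:
        raise ValueError("empty subpopulation")
    metrics = graph_metrics(g)
    out = {}
    for key in ("degree", "clustering"):
        whole = metrics[key].mean()
        out[f"normalized_{key}"] = (
            float(metrics[key][subpop].mean() / whole) if whole > 0 else None)
    q_obs = modularity(g, subpop.astype(int))
    rng = np.random.default_rng(seed)
    q_null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        q_null[k] = modularity(g, rng.permutation(subpop).astype(int))
    mean_abs = float(np.abs(q_null).mean())
    out["modularity"] = q_obs
    out["normalized_modularity"] = q_obs / mean_abs if mean_abs > 0 else None
    out["modularity_p"] = float(
        (1 + np.sum(np.abs(q_null) >= abs(q_obs))) / (1 + n_shuffles))
    return out
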