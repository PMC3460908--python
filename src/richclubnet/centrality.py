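"""Node centrality: betweenness, closeness, vulnerability, dynamical
importance, and the consistency-based global centrality score.

Betweenness sums, over all ordered node pairs, the fraction of shortest
paths through a node (Brandes accumulation via networkx).  Closeness is
the average of in-closeness and out-closeness (inverse mean directed
distance); on inputs with unreachable pairs the harmonic-mean variant is
used as a fallback.  Vulnerability of node i is the drop in global
efficiency when i is deleted (the remaining-network efficiency uses the
(N-1)(N-2) denominator, so peripheral nodes can score negative).
Dynamical importance is the relative drop of the dominant adjacency
eigenvalue on node deletion, computed by power iteration.

The global score counts, per node, in how many of the four measures it
reaches the 90th percentile (ties at the threshold included).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from richclubnet.network_core import ConnectionMatrix, shortest_distances
from richclubnet.smallworld import global_efficiency

#: percentile defining "top" nodes for the global score
TOP_PERCENTILE = 90.0


@dataclass(frozen=True)
class CentralityTable:
    betweenness: np.ndarray
    closeness: np.ndarray
    vulnerability: np.ndarray
    dyn_importance: np.ndarray
    global_score: np.ndarray

    def as_frame(self, labels) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "betweenness": self.betweenness,
                "closeness": self.closeness,
                "vulnerability": self.vulnerability,
                "dyn_importance": self.dyn_importance,
                "global_score": self.global_score,
            },
            index=list(labels),
        )


def betweenness_directed(net: ConnectionMatrix) -> np.ndarray:
    """Brandes betweenness on the directed graph (unnormalized sums of
    per-pair shortest-path fractions)."""
    g = net.to_digraph()
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(net.n_nodes)])


def closeness(net: ConnectionMatrix) -> np.ndarray:
    """Average of in- and out-closeness per node.

    On strongly connected inputs this is the inverse mean directed
    distance to (and from) all other nodes; if any pair is unreachable
    the harmonic mean of distances is substituted so the measure stays
    finite.
    """
    d = shortest_distances(net).d
    n = net.n_nodes
    if n < 2:
        return np.zeros(n)
    off = ~np.eye(n, dtype=bool)
    if np.isfinite(d[off]).all():
        out_c = (n - 1) / d.sum(axis=1)
        in_c = (n - 1) / d.sum(axis=0)
    else:
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        out_c = inv.sum(axis=1) / (n - 1)
        in_c = inv.sum(axis=0) / (n - 1)
    return (in_c + out_c) / 2.0


def vulnerability(net: ConnectionMatrix) -> np.ndarray:
    """E_glob(net) minus E_glob(net with node i removed), per node."""
    base = global_efficiency(shortest_distances(net))
    n = net.n_nodes
    out = np.zeros(n)
    all_nodes = np.arange(n)
    for i in range(n):
        rest = net.subnetwork(all_nodes[all_nodes != i])
        out[i] = base - global_efficiency(shortest_distances(rest))
    return out


def _dominant_eigenvalue(a: np.ndarray, tol: float = 1e-10,
                         max_iter: int = 100_000) -> float:
    """Dominant eigenvalue magnitude by power iteration.

    Falls back to a dense eigendecomposition when the iteration cycles
    (complex dominant pair, e.g. a pure directed cycle).
    """
    n = a.shape[0]
    if n == 0 or not a.any():
        return 0.0
    x = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        y = a @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            return 0.0
        x_new = y / norm
        lam_new = float(x_new @ (a @ x_new))
        if abs(lam_new - lam) < tol:
            # accept only a true eigenpair; a Rayleigh plateau on a
            # reducible/periodic matrix is caught by the residual
            residual = np.linalg.norm(a @ x_new - lam_new * x_new)
            if residual <= 1e-8 * max(1.0, abs(lam_new)):
                return abs(lam_new)
            break
        lam, x = lam_new, x_new
    return float(np.max(np.abs(np.linalg.eigvals(a))))


def dynamical_importance(net: ConnectionMatrix) -> np.ndarray:
    """Relative drop of the dominant adjacency eigenvalue per deletion:
    I(i) = (lambda_max - lambda_max^(-i)) / lambda_max."""
    a = net.adjacency.astype(np.float64)
    lam = _dominant_eigenvalue(a)
    if lam == 0:
        raise ValueError("network has no positive dominant eigenvalue")
    n = net.n_nodes
    keep = np.arange(n)
    out = np.zeros(n)
    for i in range(n):
        idx = keep[keep != i]
        lam_i = _dominant_eigenvalue(a[np.ix_(idx, idx)])
        out[i] = (lam - lam_i) / lam
    return out


def global_centrality_score(
    table_or_measures, top_percentile: float = TOP_PERCENTILE
) -> np.ndarray:
    """Count per node of measures where it ranks at/above the percentile."""
    if isinstance(table_or_measures, CentralityTable):
        measures = [
            table_or_measures.betweenness,
            table_or_measures.closeness,
            table_or_measures.vulnerability,
            table_or_measures.dyn_importance,
        ]
    else:
        measures = list(table_or_measures)
    n = len(measures[0])
    score = np.zeros(n, dtype=np.int64)
    for m in measures:
        thr = np.percentile(m, top_percentile)  # midpoint interpolation
        score += (np.asarray(m) >= thr).astype(np.int64)
    return score


def centrality_table(net: ConnectionMatrix) -> CentralityTable:
    """All four measures plus the global score."""
    b = betweenness_directed(net)
    c = closeness(net)
    v = vulnerability(net)
    d = dynamical_importance(net)
    return CentralityTable(
        betweenness=b,
        closeness=c,
        vulnerability=v,
        dyn_importance=d,
        global_score=global_centrality_score([b, c, v, d]),
    )
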