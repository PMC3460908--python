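"""Rich-club detection with permutation significance, edge classification
and k-core decomposition.

The rich-club coefficient at degree k is the connection density of the
subgraph induced by nodes with total degree > k,

    Phi(k) = E_{>k} / ( N_{>k} (N_{>k} - 1) ),

computed over ordered (directed) pairs.  Because the randomized null
model conserves every node's degrees, the >k node set is identical in
every null member, and the null distribution of Phi(k) reduces to the
distribution of edge counts inside that fixed set.  The sweep runs from
the lowest degree to the second-highest degree; each k gets a one-sided
permutation p-value (add-one corrected), Benjamini-Hochberg FDR is
applied across the sweep, and the surviving k values are collapsed into
a nested hierarchy of unique node sets (level 1 = innermost = highest
defining k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from richclubnet.network_core import ConnectionMatrix, degrees
from richclubnet.null_models import NullEnsemble

#: FDR level used for the sweep
DEFAULT_Q = 0.05


@dataclass(frozen=True)
class RichClubResult:
    k_values: np.ndarray
    phi: np.ndarray
    phi_random_mean: np.ndarray
    phi_norm: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    fdr_significant: np.ndarray
    levels: list[frozenset[int]]  # level 1 first (innermost)
    level_k: list[int]  # innermost defining k per level
    n_null: int

    def level_labels(self, net: ConnectionMatrix) -> list[list[str]]:
        return [
            sorted(net.labels[i] for i in lev) for lev in self.levels
        ]


@dataclass(frozen=True)
class EdgeClassification:
    """Exhaustive 3-way partition of directed edges given an RC node set."""

    rc_nodes: frozenset[int]
    class_of: dict[tuple[int, int], str] = field(repr=False)

    def edges_in(self, cls: str) -> list[tuple[int, int]]:
        return [e for e, c in self.class_of.items() if c == cls]

    def counts(self) -> dict[str, int]:
        out = {"rich_club": 0, "feeder": 0, "local": 0}
        for c in self.class_of.values():
            out[c] += 1
        return out


@dataclass(frozen=True)
class CoreDecomposition:
    core_level: np.ndarray  # max k at which each node survives k-core pruning
    subshell_rank: np.ndarray  # removal order at the disintegration degree
    disintegration_k: int  # first k with an empty k-core
    peak_core_size: int  # size of the core at disintegration_k - 1


def phi(net: ConnectionMatrix, k: int) -> float:
    """Density of the directed subgraph on nodes with total degree > k."""
    ktot = degrees(net).k
    nodes = np.flatnonzero(ktot > k)
    if nodes.size < 2:
        raise ValueError(f"fewer than 2 nodes with degree > {k}")
    sub = net.adjacency[np.ix_(nodes, nodes)]
    return float(sub.sum() / (nodes.size * (nodes.size - 1)))


def _phi_sweep_counts(adjacency: np.ndarray, ktot: np.ndarray,
                      k_values: np.ndarray) -> np.ndarray:
    """Edge counts E_{>k} for all k at once.

    An edge (i, j) survives at threshold k iff min(k_i, k_j) > k, so the
    per-k counts follow from a histogram of edge min-degrees.
    """
    src, dst = np.nonzero(adjacency)
    edge_min = np.minimum(ktot[src], ktot[dst])
    kmax = int(ktot.max()) if ktot.size else 0
    hist = np.bincount(edge_min, minlength=kmax + 2)
    # suffix sum: edges with edge_min > k
    suffix = np.cumsum(hist[::-1])[::-1]
    counts = np.zeros(k_values.size)
    for idx, k in enumerate(k_values):
        counts[idx] = suffix[k + 1] if k + 1 <= kmax else 0
    return counts


def rich_club_curve(
    net: ConnectionMatrix,
    ensemble: NullEnsemble,
    q: float = DEFAULT_Q,
) -> RichClubResult:
    """Full rich-club sweep with permutation significance and FDR.

    ``ensemble`` must be a randomized (degree-preserving) population; the
    one-sided p-value at each k is the add-one-corrected fraction of null
    coefficients at least as large as the empirical one.
    """
    if ensemble.model != "randomized":
        raise ValueError("rich-club nulls must use the randomized model")
    n_null = len(ensemble)
    if n_null < 1000:
        warnings.warn(
            f"only {n_null} null networks; p-value resolution is "
            f"{1.0 / (n_null + 1):.3g}"
        )
    ktot = degrees(net).k
    uniq = np.unique(ktot)
    k_min = int(uniq.min()) if uniq.size else 0
    k_secondmax = int(np.sort(ktot)[-2]) if ktot.size >= 2 else 0
    k_candidates = np.arange(max(k_min, 1), k_secondmax + 1)
    # keep only k with >= 2 qualifying nodes
    sizes = np.array([(ktot > k).sum() for k in k_candidates])
    k_values = k_candidates[sizes >= 2]
    sizes = sizes[sizes >= 2]
    possible = sizes * (sizes - 1)

    emp_counts = _phi_sweep_counts(net.adjacency, ktot, k_values)
    phi_emp = emp_counts / possible

    null_counts = np.empty((n_null, k_values.size))
    for i, member in enumerate(ensemble):
        null_counts[i] = _phi_sweep_counts(member.adjacency, ktot, k_values)
    phi_null = null_counts / possible
    phi_rand_mean = phi_null.mean(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_norm = np.where(phi_rand_mean > 0, phi_emp / phi_rand_mean, np.nan)
    p_raw = (1.0 + (phi_null >= phi_emp[None, :]).sum(axis=0)) / (1.0 + n_null)
    significant, p_adj = fdr_correct(p_raw, q)

    levels, level_k = _nested_levels(ktot, k_values[significant])
    return RichClubResult(
        k_values=k_values,
        phi=phi_emp,
        phi_random_mean=phi_rand_mean,
        phi_norm=phi_norm,
        p_raw=p_raw,
        p_adjusted=p_adj,
        fdr_significant=significant,
        levels=levels,
        level_k=level_k,
        n_null=n_null,
    )


def _nested_levels(
    ktot: np.ndarray, significant_k: np.ndarray
) -> tuple[list[frozenset[int]], list[int]]:
    """Collapse significant k values into unique nested node sets.

    Levels are ordered innermost (highest defining k, smallest set)
    first; each level is labeled by the innermost (largest) k producing
    its node set.
    """
    levels: list[frozenset[int]] = []
    level_k: list[int] = []
    for k in sorted(significant_k, reverse=True):
        nodes = frozenset(np.flatnonzero(ktot > k).tolist())
        if levels and nodes == levels[-1]:
            continue
        levels.append(nodes)
        level_k.append(int(k))
    return levels, level_k


def fdr_correct(p_values, q: float = DEFAULT_Q):
    """Benjamini-Hochberg step-up: (survivor flags, adjusted p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def classify_edges(
    net: ConnectionMatrix, rc_nodes
) -> EdgeClassification:
    """Partition edges into rich-club / feeder / local given RC nodes."""
    rc = frozenset(int(i) for i in rc_nodes)
    class_of: dict[tuple[int, int], str] = {}
    for s, t in net.edge_array():
        in_s, in_t = s in rc, t in rc
        if in_s and in_t:
            cls = "rich_club"
        elif in_s or in_t:
            cls = "feeder"
        else:
            cls = "local"
        class_of[(int(s), int(t))] = cls
    return EdgeClassification(rc_nodes=rc, class_of=class_of)


def kcore_decompose(net: ConnectionMatrix) -> CoreDecomposition:
    """Total-degree k-core decomposition with subshell ranks.

    For increasing k, nodes with total degree < k within the surviving
    subgraph are removed iteratively.  ``core_level[i]`` is the largest k
    whose core contains i.  At the first k where the core is empty (the
    disintegration degree), ``subshell_rank`` records the order in which
    nodes detached (1 = first removed; ties within one pruning pass share
    a rank).
    """
    n = net.n_nodes
    a = net.adjacency.astype(np.int64)
    core_level = np.zeros(n, dtype=np.int64)
    subshell_rank = np.zeros(n, dtype=np.int64)
    peak_size = n
    k = 1
    while True:
        alive = np.ones(n, dtype=bool)
        # k-core: iteratively remove nodes with total degree < k
        rank = 0
        order_this_k = np.zeros(n, dtype=np.int64)
        while True:
            deg = (a * alive[None, :]).sum(axis=1) + \
                  (a * alive[:, None]).sum(axis=0)
            low = alive & (deg < k)
            if not low.any():
                break
            rank += 1
            order_this_k[low] = rank
            alive[low] = False
        if alive.any():
            core_level[alive] = k
            peak_size = int(alive.sum())
            k += 1
        else:
            subshell_rank = order_this_k
            return CoreDecomposition(
                core_level=core_level,
                subshell_rank=subshell_rank,
                disintegration_k=k,
                peak_core_size=peak_size,
            )
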