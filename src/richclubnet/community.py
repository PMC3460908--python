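"""Directed modularity optimization and module-based node roles.

Directed modularity of a partition {c_i} is

    Q = (1/m) sum_ij [ a_ij - k_i^out k_j^in / m ] delta(c_i, c_j)

with m the edge count.  Since the Kronecker delta is symmetric, Q can be
optimized through the symmetrized modularity matrix
S = (B + B^T)/2, B_ij = a_ij - k_i^out k_j^in/m: recursive spectral
bisection on the leading eigenvector of the (row-sum corrected) restricted
matrix S^(g), each split polished by Kernighan-Lin-style single-node
moves, followed by a final refinement pass moving nodes between modules.

Node roles given a partition: the participation coefficient
P_i = 1 - sum_s (kappa_is / k_i)^2 (kappa_is = number of i's edges, in
plus out, attached to module s) and the within-module degree z-score;
connector hubs combine z > 2 with P > 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from richclubnet.network_core import ConnectionMatrix

#: connector-hub thresholds
Z_THRESHOLD = 2.0
P_THRESHOLD = 0.5


@dataclass(frozen=True)
class ModularPartition:
    assignment: np.ndarray  # node -> module id (0-based, contiguous)
    Q: float
    within_density: float
    between_density: float
    intra_edge_fraction: float

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    def members(self, module: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module)


@dataclass(frozen=True)
class NodeRole:
    participation: np.ndarray
    z_within: np.ndarray
    is_connector_hub: np.ndarray


def modularity_value(net: ConnectionMatrix, assignment: np.ndarray) -> float:
    """Directed modularity Q of an arbitrary assignment."""
    a = net.adjacency.astype(np.float64)
    m = a.sum()
    if m == 0:
        return 0.0
    k_out = a.sum(axis=1)
    k_in = a.sum(axis=0)
    b = a - np.outer(k_out, k_in) / m
    same = assignment[:, None] == assignment[None, :]
    return float((b * same).sum() / m)


def _leading_eigvec(s: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(s)
    return float(vals[-1]), vecs[:, -1]


def _kl_refine(s_g: np.ndarray, sign: np.ndarray, max_sweeps: int = 10) -> np.ndarray:
    """Greedy single-node flips maximizing s^T S^(g) s."""
    sign = sign.copy()
    for _ in range(max_sweeps):
        # gain of flipping node i: -4 s_i * (S row_i . s) + 4 S_ii
        row = s_g @ sign
        gains = -4.0 * sign * row + 4.0 * np.diagonal(s_g)
        order = np.argsort(gains)[::-1]
        improved = False
        for i in order:
            if gains[i] <= 1e-12:
                break
            sign[i] = -sign[i]
            improved = True
            row = s_g @ sign
            gains = -4.0 * sign * row + 4.0 * np.diagonal(s_g)
        if not improved:
            break
    return sign


def optimize_modularity_directed(
    net: ConnectionMatrix, seed: int = 0
) -> ModularPartition:
    """Partition maximizing directed modularity by spectral bisection.

    Deterministic given ``seed`` (the seed only breaks exact eigenvector
    degeneracies and the order of the final refinement pass).
    """
    a = net.adjacency.astype(np.float64)
    n = net.n_nodes
    m = a.sum()
    rng = np.random.default_rng(seed)
    if m == 0 or n == 0:
        return _finalize(net, np.zeros(n, dtype=np.int64))
    k_out = a.sum(axis=1)
    k_in = a.sum(axis=0)
    b = a - np.outer(k_out, k_in) / m
    s_full = (b + b.T) / 2.0

    assignment = np.zeros(n, dtype=np.int64)
    stack = [np.arange(n)]
    next_id = 1
    while stack:
        g = stack.pop()
        if g.size < 2:
            continue
        s_g = s_full[np.ix_(g, g)].copy()
        s_g[np.diag_indices_from(s_g)] -= s_g.sum(axis=1)
        val, vec = _leading_eigvec(s_g)
        if val <= 1e-10:
            continue  # indivisible
        sign = np.where(vec >= 0, 1.0, -1.0)
        if np.abs(vec).max() < 1e-12:
            sign = rng.choice([-1.0, 1.0], size=g.size)
        # ties in eigenvector sign: zeros join the larger side
        zero = np.abs(vec) < 1e-12
        if zero.any():
            bigger = 1.0 if (sign > 0).sum() >= (sign < 0).sum() else -1.0
            sign[zero] = bigger
        sign = _kl_refine(s_g, sign)
        delta_q = float(sign @ s_g @ sign) / (2.0 * m)
        if delta_q <= 1e-10 or np.all(sign == sign[0]):
            continue
        left = g[sign > 0]
        right = g[sign < 0]
        assignment[right] = next_id
        next_id += 1
        stack.append(left)
        stack.append(right)

    assignment = _refine_assignment(net, assignment, rng)
    return _finalize(net, assignment)


def _refine_assignment(
    net: ConnectionMatrix, assignment: np.ndarray, rng: np.random.Generator,
    max_sweeps: int = 20,
) -> np.ndarray:
    """Final pass: move single nodes to any module while Q improves."""
    assignment = _relabel(assignment)
    a = net.adjacency.astype(np.float64)
    m = a.sum()
    if m == 0:
        return assignment
    k_out = a.sum(axis=1)
    k_in = a.sum(axis=0)
    n = net.n_nodes
    for _ in range(max_sweeps):
        moved = False
        n_mod = assignment.max() + 1
        member = np.eye(n_mod)[assignment]  # n x n_mod indicator
        # directed attachment of node i to module s, counting both
        # directions, minus the degree-expected term
        attach = (a @ member) + (a.T @ member)
        expect = (np.outer(k_out, member.T @ k_in)
                  + np.outer(k_in, member.T @ k_out)) / m
        gain_mat = attach - expect
        for i in rng.permutation(n):
            cur = assignment[i]
            own = gain_mat[i].copy()
            # leaving module cur removes i's own contribution incl. the
            # self term a_ii (=0) and expected self-pair
            own[cur] -= (a[i, i] * 2 - 2 * k_out[i] * k_in[i] / m)
            best = int(np.argmax(own))
            if own[best] > own[cur] + 1e-12:
                # apply move and update incremental structures
                assignment[i] = best
                member[i, cur] = 0.0
                member[i, best] = 1.0
                delta = np.zeros(n_mod)
                delta[cur], delta[best] = -1.0, 1.0
                attach[:, cur] -= a[:, i] + a[i, :]
                attach[:, best] += a[:, i] + a[i, :]
                expect[:, cur] -= (k_out * k_in[i] + k_in * k_out[i]) / m
                expect[:, best] += (k_out * k_in[i] + k_in * k_out[i]) / m
                gain_mat = attach - expect
                moved = True
        if not moved:
            break
    return _relabel(assignment)


def _relabel(assignment: np.ndarray) -> np.ndarray:
    _, inv = np.unique(assignment, return_inverse=True)
    return inv.astype(np.int64)


def _finalize(net: ConnectionMatrix, assignment: np.ndarray) -> ModularPartition:
    within, between, intra = partition_densities(net, assignment)
    return ModularPartition(
        assignment=_relabel(assignment),
        Q=modularity_value(net, assignment),
        within_density=within,
        between_density=between,
        intra_edge_fraction=intra,
    )


def partition_densities(
    net: ConnectionMatrix, assignment: np.ndarray
) -> tuple[float, float, float]:
    """(within_density, between_density, intra_edge_fraction)."""
    a = net.adjacency
    assignment = np.asarray(assignment)
    same = assignment[:, None] == assignment[None, :]
    np.fill_diagonal(same, False)
    within_possible = int(same.sum())
    n = net.n_nodes
    between_possible = n * (n - 1) - within_possible
    within_edges = int(a[same].sum())
    m = net.n_edges
    between_edges = m - within_edges
    within = within_edges / within_possible if within_possible else 0.0
    between = between_edges / between_possible if between_possible else 0.0
    intra = within_edges / m if m else 0.0
    return within, between, intra


def node_roles(
    net: ConnectionMatrix,
    partition: ModularPartition | np.ndarray,
    z_threshold: float = Z_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> NodeRole:
    """Participation coefficient, within-module z-score, connector flags.

    Both measures use total (in+out) degree.  Nodes in singleton modules
    get z = 0 (with a warning).
    """
    assignment = (
        partition.assignment
        if isinstance(partition, ModularPartition)
        else np.asarray(partition)
    )
    a = net.adjacency.astype(np.float64)
    n = net.n_nodes
    n_mod = int(assignment.max()) + 1
    member = np.eye(n_mod)[assignment]
    kappa = (a + a.T) @ member  # node x module total-degree attachment
    k = kappa.sum(axis=1)
    participation = np.zeros(n)
    ok = k > 0
    participation[ok] = 1.0 - ((kappa[ok] / k[ok, None]) ** 2).sum(axis=1)

    z = np.zeros(n)
    for s in range(n_mod):
        idx = np.flatnonzero(assignment == s)
        if idx.size == 1:
            warnings.warn(f"module {s} is a singleton; z set to 0")
            continue
        within_k = kappa[idx, s]
        sd = within_k.std()
        if sd > 0:
            z[idx] = (within_k - within_k.mean()) / sd
    hub = (z > z_threshold) & (participation > p_threshold)
    return NodeRole(participation=participation, z_within=z,
                    is_connector_hub=hub)
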