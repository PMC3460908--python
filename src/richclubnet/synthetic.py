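"""Synthetic directed networks with planted structure for validation.

The generator emulates the statistical profile of a mammalian
cortico-cortical projection matrix: a sparse directed graph (density
~0.07) with ~50% reciprocity, a broad exponential-like total-degree
distribution, ~5 planted modules (stochastic block structure), and a
planted rich club — a small set of high-degree nodes, spread across all
modules, wired among themselves far more densely than their degrees
alone predict.  3D centroid coordinates place modules in distinct
spatial clusters so that planted rich-club edges (which cross modules)
span longer Euclidean distances than local edges.

Edges are sampled per dyad: a dyad connects with a propensity set by the
block densities and per-node exponential weights, and a connected dyad
is reciprocal with probability rho = r / (2 - r), which yields an
expected edge-wise reciprocity of r.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from richclubnet.network_core import ConnectionMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults emulate the macaque-scale regime."""

    n_nodes: int = 242
    n_modules: int = 5
    within_density: float = 0.191
    between_density: float = 0.037
    rc_size: int = 15
    rc_density: float = 0.65
    reciprocity_target: float = 0.507
    degree_tail: float = 1.0  # exponential rate of per-node weights
    coord_box: float = 60.0  # mm extent of the coordinate space
    seed: int = 0

    def __post_init__(self):
        if not (self.rc_density >= self.within_density
                > self.between_density):
            raise ValueError(
                "need rc_density >= within_density > between_density"
            )
        if self.rc_size > self.n_nodes:
            raise ValueError("rc_size exceeds n_nodes")

    @property
    def rc_per_module(self) -> list[int]:
        """RC nodes allocated per module (as even as possible)."""
        base, extra = divmod(self.rc_size, self.n_modules)
        return [base + (1 if m < extra else 0)
                for m in range(self.n_modules)]


@dataclass(frozen=True)
class PlantedTruth:
    module_of: np.ndarray  # node -> module id
    rc_nodes: frozenset[int]
    coords: pd.DataFrame = field(repr=False)  # label-indexed x, y, z


def generate(spec: SyntheticSpec) -> tuple[ConnectionMatrix, PlantedTruth]:
    """Sample one network with planted modules, rich club and coordinates."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    # module assignment: contiguous, near-equal blocks
    sizes = np.full(spec.n_modules, n // spec.n_modules)
    sizes[: n % spec.n_modules] += 1
    module_of = np.repeat(np.arange(spec.n_modules), sizes)

    # rich-club members spread across modules
    rc: list[int] = []
    for m, quota in enumerate(spec.rc_per_module):
        members = np.flatnonzero(module_of == m)
        rc.extend(members[:quota])
    rc_nodes = np.array(sorted(rc))
    rc_mask = np.zeros(n, dtype=bool)
    rc_mask[rc_nodes] = True

    # A third of the club ("connectors", spread across modules) will
    # concentrate the club's internal wiring; the remaining "satellite"
    # members carry the highest background degrees.  This mimics the
    # core-periphery arrangement of empirical hub sets and keeps any
    # high-degree subset of the club from being enriched on its own.
    m = rc_nodes.size
    n_conn = max(1, int(round(m / 3))) if m >= 3 else 0
    connectors = rc_nodes[:: max(1, m // n_conn)][:n_conn] if n_conn else \
        rc_nodes[:0]
    conn_mask = np.zeros(n, dtype=bool)
    conn_mask[connectors] = True

    # exponential per-node weights give the broad degree tail; the
    # floor keeps every node away from isolation (pruned empirical
    # matrices have no near-isolated regions)
    weights = 0.3 + rng.exponential(1.0 / spec.degree_tail, size=n)
    weights /= weights.mean()

    # dyad-level sampling outside the club
    rho = spec.reciprocity_target / (2.0 - spec.reciprocity_target)
    same = module_of[:, None] == module_of[None, :]
    base = np.where(same, spec.within_density, spec.between_density)
    # with rc_density == within_density the club wiring is disabled:
    # club members keep their high degrees but no excess interconnection
    # is planted (null case for false-positive testing)
    plant_club = spec.rc_density > spec.within_density
    rc_pair = np.outer(rc_mask, rc_mask)
    if plant_club:
        base = np.where(rc_pair, 0.0, base)  # club wired separately below
    # dyad connection propensity q with E[directed density] = base:
    # a connected dyad carries 1 + rho expected directed edges
    sqrt_w = np.sqrt(weights)
    pair_w = np.outer(sqrt_w, sqrt_w) / sqrt_w.mean() ** 2
    q = np.clip(2.0 * base * pair_w / (1.0 + rho), 0.0, 1.0)
    if q.max() >= 1.0 and (q >= 1.0).mean() > 0.05:
        raise ValueError("infeasible density combination (propensities >= 1)")

    # Calibrate club-to-background propensities so expected TOTAL
    # degrees form three separated bands: background tail < connectors
    # < satellites.  Targets are multiples of the mean background
    # degree; each member's expected internal (club) degree is
    # subtracted so the bands hold across network scales.  The club
    # thereby holds the highest total degrees, ordered satellites
    # first, connectors at the club's lower edge.
    exp_deg = (1.0 + rho) * q.sum(axis=1)
    dbar = exp_deg[~rc_mask].mean()
    n_sat = m - n_conn
    e_target = int(round(spec.rc_density * m * (m - 1))) if plant_club else 0
    extra_int = max(0, e_target - n_conn * (n_conn - 1)
                    - 2 * n_conn * n_sat)
    internal = np.zeros(n)
    if plant_club:
        internal[conn_mask] = 2 * (m - 1)
        internal[rc_mask & ~conn_mask] = (
            2 * n_conn + (2 * extra_int / n_sat if n_sat else 0.0)
        )
    total_ratio = np.zeros(n)
    total_ratio[rc_mask & ~conn_mask] = rng.uniform(
        3.1, 3.35, size=int((rc_mask & ~conn_mask).sum())
    )
    total_ratio[rc_mask & conn_mask] = rng.uniform(
        2.5, 2.65, size=int(conn_mask.sum())
    )
    target_total = q.sum()  # dyad propensity mass before calibration
    for i in rc_nodes:
        cur = (1.0 + rho) * q[i, ~rc_mask].sum()
        bg_target = max(0.3 * dbar, total_ratio[i] * dbar - internal[i])
        if cur > 0:
            q[i, ~rc_mask] *= bg_target / cur
            q[~rc_mask, i] = q[i, ~rc_mask]
    q = np.clip(q, 0.0, 1.0)
    # restore the overall expected density by trimming the background
    # block (club rows untouched)
    bg_block = np.outer(~rc_mask, ~rc_mask)
    excess = q.sum() - target_total
    bg_mass = q[bg_block].sum()
    if bg_mass > 0:
        q[bg_block] *= max(0.0, 1.0 - excess / bg_mass)

    iu, ju = np.triu_indices(n, k=1)
    connected = rng.random(iu.size) < q[iu, ju]
    recip = rng.random(iu.size) < rho
    direction = rng.random(iu.size) < 0.5
    a = np.zeros((n, n), dtype=np.uint8)
    both = connected & recip
    one = connected & ~recip
    a[iu[both], ju[both]] = 1
    a[ju[both], iu[both]] = 1
    fwd = one & direction
    bwd = one & ~direction
    a[iu[fwd], ju[fwd]] = 1
    a[ju[bwd], iu[bwd]] = 1

    # Club subgraph: core-periphery wiring at the target density.  The
    # connector members are reciprocally tied to every club member;
    # satellite members are only sparsely interlinked directly.  The
    # club's excess density is therefore a property of the whole set —
    # no high-degree subset of satellites is itself enriched — so the
    # planted set is the innermost detectable rich-club level.
    if plant_club and m >= 2:
        e_target = int(round(spec.rc_density * m * (m - 1)))
        sat = np.array([i for i in rc_nodes if not conn_mask[i]])
        for ci in connectors:
            for j in rc_nodes:
                if j != ci:
                    a[ci, j] = 1
                    a[j, ci] = 1
        filled = int(a[np.ix_(rc_nodes, rc_nodes)].sum())
        extra = e_target - filled
        if extra > 0 and sat.size >= 2:
            # direct satellite-satellite links, reciprocal with the same
            # dyad-level probability as the background
            free = [(s, t) for ix, s in enumerate(sat)
                    for t in sat[ix + 1:]]
            order = rng.permutation(len(free))
            added = 0
            force_full = e_target >= m * (m - 1)
            for idx in order:
                if added >= extra:
                    break
                s, t = free[idx]
                if (force_full or rng.random() < rho) and extra - added >= 2:
                    a[s, t] = 1
                    a[t, s] = 1
                    added += 2
                else:
                    if rng.random() < 0.5:
                        s, t = t, s
                    a[s, t] = 1
                    added += 1

    labels = tuple(f"R{i:03d}" for i in range(n))
    net = ConnectionMatrix(a, labels)

    # coordinates: module clusters on a ring in 3D, nodes scattered
    centers = np.column_stack(
        [
            spec.coord_box / 2 * np.cos(
                2 * np.pi * np.arange(spec.n_modules) / spec.n_modules
            ),
            spec.coord_box / 2 * np.sin(
                2 * np.pi * np.arange(spec.n_modules) / spec.n_modules
            ),
            np.zeros(spec.n_modules),
        ]
    )
    xyz = centers[module_of] + rng.normal(
        0.0, spec.coord_box / 10.0, size=(n, 3)
    )
    coords = pd.DataFrame(xyz, columns=["x", "y", "z"], index=list(labels))
    truth = PlantedTruth(
        module_of=module_of,
        rc_nodes=frozenset(int(i) for i in rc_nodes),
        coords=coords,
    )
    return net, truth


# ---------------------------------------------------------------------------
# Hand-analyzable fixtures
# ---------------------------------------------------------------------------


def fixture_library() -> dict[str, ConnectionMatrix]:
    """Small named graphs with exactly known metric values.

    - ``cycle_3``: directed 3-cycle; clustering 0.5 per node,
      reciprocity 0.
    - ``cycle_4``: directed 4-cycle; characteristic path length 2.0.
    - ``chain_4``: directed 4-chain A->B->C->D; d(A, D) = 3.
    - ``reciprocal_star_5``: center reciprocally tied to 5 mutually
      unconnected leaves; center clustering 0, motif-9 apex ratio 1.
    - ``two_clique_bridge``: two reciprocal 4-cliques joined by one
      reciprocal bridge; optimal 2-module partition = the cliques.
    - ``grid_2x2``: directed 2x2 grid with two equal-length routes
      across the diagonal (sigma = 2).
    - ``complete_5``: complete digraph on 5 nodes.
    """
    out: dict[str, ConnectionMatrix] = {}

    def from_edges(n, edges, name_prefix="N"):
        a = np.zeros((n, n), dtype=np.uint8)
        for s, t in edges:
            a[s, t] = 1
        labels = tuple(f"{name_prefix}{i}" for i in range(n))
        return ConnectionMatrix(a, labels)

    out["cycle_3"] = from_edges(3, [(0, 1), (1, 2), (2, 0)])
    out["cycle_4"] = from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    out["chain_4"] = from_edges(4, [(0, 1), (1, 2), (2, 3)])
    star = [(0, i) for i in range(1, 6)] + [(i, 0) for i in range(1, 6)]
    out["reciprocal_star_5"] = from_edges(6, star)
    cliq = []
    for block in (range(0, 4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    cliq.append((i, j))
    cliq += [(0, 4), (4, 0)]
    out["two_clique_bridge"] = from_edges(8, cliq)
    out["grid_2x2"] = from_edges(4, [(0, 1), (0, 2), (1, 3), (2, 3)])
    out["complete_5"] = from_edges(
        5, [(i, j) for i in range(5) for j in range(5) if i != j]
    )
    return out


def plant_flow_bias(
    net: ConnectionMatrix,
    rc_nodes,
    node: int,
    mode: str = "sink",
    seed: int = 0,
) -> ConnectionMatrix:
    """Impose a one-way feeder bias on one rich-club member.

    ``mode="sink"`` removes the node's outgoing feeder edges and points
    the freed out-stubs at club members instead, so every shortest path
    that enters the node can only continue inside the club: the node
    absorbs paths (in-out ratio -> +1) far beyond what its degrees
    explain, since degree-preserving rewiring scatters those out-stubs
    back across the network.  ``mode="source"`` is the mirror image
    (ratio -> -1).  Out-stubs that cannot be re-hosted inside the club
    are dropped.
    """
    if mode not in ("sink", "source"):
        raise ValueError(f"unknown bias mode {mode!r}")
    rng = np.random.default_rng(seed)
    rc = set(int(i) for i in rc_nodes)
    if node not in rc:
        raise ValueError("bias target must be a rich-club member")
    a = net.adjacency.copy()
    others = [i for i in sorted(rc) if i != node]
    rng.shuffle(others)
    if mode == "sink":
        feeder_out = [j for j in np.flatnonzero(a[node])
                      if j not in rc]
        free = [v for v in others if not a[node, v]]
        for j in feeder_out:
            a[node, j] = 0
            if free:
                a[node, free.pop()] = 1
    else:
        feeder_in = [j for j in np.flatnonzero(a[:, node])
                     if j not in rc]
        free = [v for v in others if not a[v, node]]
        for j in feeder_in:
            a[j, node] = 0
            if free:
                a[free.pop(), node] = 1
    return net.with_adjacency(a)
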