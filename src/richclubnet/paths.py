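"""Exhaustive shortest-path analytics.

All statistics are computed over the complete multiset of minimally
short directed paths (every distinct shortest path between every
ordered node pair counts once).  Counting uses dynamic programming on
the per-source shortest-path DAG — sigma(s, v) forward path counts and
h(v) backward suffix counts — so totals, per-edge usage and positional
statistics are exact without enumerating individual paths.

Rich-club participation restricts attention to paths whose endpoints
both lie outside the rich club; "touching" counts RC nodes as
intermediates, "traveling" counts RC->RC edges.  Both fractions are
computed by complement: paths that avoid the rich club are counted on
the RC-free (or RC-edge-free) subgraph and kept only where the
subgraph distance still equals the full-graph distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix

from richclubnet._kernels import flow_events, path_census
from richclubnet.network_core import ConnectionMatrix, degrees
from richclubnet.null_models import NullEnsemble
from richclubnet.richclub import EdgeClassification


# ---------------------------------------------------------------------------
# Core counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathStats:
    """Shortest-path counts between admissible ordered pairs."""

    sigma: np.ndarray  # (N, N) number of shortest s->t paths counted
    dist: np.ndarray  # (N, N) hop distance, -1 unreachable/not computed
    edge_usage: np.ndarray  # per edge (edge_array order)
    node_usage: np.ndarray  # per node, as intermediate
    total_paths: float
    edges: np.ndarray = field(repr=False)  # (E, 2) edge array

    def edge_usage_frame(self, net: ConnectionMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [net.labels[s] for s, _ in self.edges],
                "target": [net.labels[t] for _, t in self.edges],
                "usage": self.edge_usage,
            }
        )


def _csr_arrays(net: ConnectionMatrix):
    csr = csr_matrix(net.adjacency)
    return csr.indptr.astype(np.int64), csr.indices.astype(np.int64)


def count_shortest_paths(
    net: ConnectionMatrix,
    sources: np.ndarray | None = None,
    allow: np.ndarray | None = None,
    targets_mask: np.ndarray | None = None,
) -> PathStats:
    """Count all shortest paths (optionally between restricted endpoints
    or avoiding disallowed intermediates) and their edge/node usage."""
    n = net.n_nodes
    indptr, indices = _csr_arrays(net)
    edges = net.edge_array()
    if sources is None:
        sources = np.arange(n)
    if allow is None:
        allow = np.ones(n, dtype=np.uint8)
    if targets_mask is None:
        targets_mask = np.ones(n, dtype=np.uint8)
    sigma = np.zeros((n, n))
    dist = np.full((n, n), -1, dtype=np.int64)
    edge_usage = np.zeros(edges.shape[0])
    node_usage = np.zeros(n)
    total = path_census(
        indptr, indices, n,
        np.asarray(sources, dtype=np.int64),
        np.ascontiguousarray(allow, dtype=np.uint8),
        np.ascontiguousarray(targets_mask, dtype=np.uint8),
        np.ascontiguousarray(edges[:, 0]),
        np.ascontiguousarray(edges[:, 1]),
        edge_usage, node_usage, sigma, dist,
    )
    return PathStats(
        sigma=sigma,
        dist=dist,
        edge_usage=edge_usage,
        node_usage=node_usage,
        total_paths=float(total),
        edges=edges,
    )


# ---------------------------------------------------------------------------
# Rich-club participation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RCPathParticipation:
    frac_touch_node: float
    frac_travel_edge: float
    total_paths: float  # shortest paths between non-RC ordered pairs
    touch_paths: float
    travel_paths: float


def _restricted_counts(net, rc_mask, remove_nodes: bool):
    """sigma restricted to paths avoiding RC nodes (or RC->RC edges),
    valid only where the restricted distance matches the full one."""
    n = net.n_nodes
    non_rc = ~rc_mask
    if remove_nodes:
        allow = non_rc.astype(np.uint8)
        sub = net
    else:
        a = net.adjacency.copy()
        a[np.ix_(rc_mask.nonzero()[0], rc_mask.nonzero()[0])] = 0
        sub = net.with_adjacency(a)
        allow = np.ones(n, dtype=np.uint8)
    return count_shortest_paths(
        sub,
        sources=np.flatnonzero(non_rc),
        allow=allow,
        targets_mask=non_rc.astype(np.uint8),
    )


def rc_participation(net: ConnectionMatrix, rc_nodes) -> RCPathParticipation:
    """Fractions of non-RC-endpoint shortest paths touching an RC node
    (as intermediate) or traveling an RC->RC edge."""
    n = net.n_nodes
    rc_mask = np.zeros(n, dtype=bool)
    rc_mask[list(rc_nodes)] = True
    non_rc = np.flatnonzero(~rc_mask)
    full = count_shortest_paths(
        net, sources=non_rc, targets_mask=(~rc_mask).astype(np.uint8)
    )
    if not rc_mask.any() or full.total_paths == 0:
        return RCPathParticipation(0.0, 0.0, full.total_paths, 0.0, 0.0)

    pair_ok = np.outer(~rc_mask, ~rc_mask)

    def avoiding_total(restricted: PathStats) -> float:
        same_len = (restricted.dist == full.dist) & (full.dist > 0) & pair_ok
        return float(restricted.sigma[same_len].sum())

    avoid_nodes = avoiding_total(_restricted_counts(net, rc_mask, True))
    avoid_edges = avoiding_total(_restricted_counts(net, rc_mask, False))
    touch = full.total_paths - avoid_nodes
    travel = full.total_paths - avoid_edges
    return RCPathParticipation(
        frac_touch_node=touch / full.total_paths,
        frac_travel_edge=travel / full.total_paths,
        total_paths=full.total_paths,
        touch_paths=touch,
        travel_paths=travel,
    )


# ---------------------------------------------------------------------------
# Positional degree profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeAlongPath:
    """Positional statistics for paths of each length L.

    ``node_position_counts[L]`` is an (L+1, N) array: entry (p, v) is
    the number of length-L shortest paths (non-RC endpoints) with node v
    at position p.  ``median_degree[L]`` is the weighted median total
    degree per position; ``touch_prob[L][p]`` the probability that the
    node at position p is an RC member; ``travel_prob[L][p]`` the
    probability that step p -> p+1 runs along an RC->RC edge.
    """

    lengths: tuple[int, ...]
    node_position_counts: dict[int, np.ndarray]
    median_degree: dict[int, np.ndarray]
    touch_prob: dict[int, np.ndarray]
    travel_prob: dict[int, np.ndarray]
    n_paths: dict[int, float]


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    if cum[-1] == 0:
        return float("nan")
    return float(v[np.searchsorted(cum, cum[-1] / 2.0)])


def degree_profile_along_paths(
    net: ConnectionMatrix,
    rc_nodes,
    lengths: tuple[int, ...] | None = None,
) -> DegreeAlongPath:
    """Degree structure along all shortest paths between non-RC endpoints."""
    n = net.n_nodes
    rc_mask = np.zeros(n, dtype=bool)
    rc_mask[list(rc_nodes)] = True
    ktot = degrees(net).k.astype(np.float64)
    full = count_shortest_paths(net)
    d = full.dist
    sigma = full.sigma
    diameter = int(d.max())
    if lengths is None:
        lengths = tuple(range(2, diameter + 1))
    # S_p[s, v] = sigma(s, v) where d(s, v) == p
    s_mats = {p: np.where(d == p, sigma, 0.0) for p in range(diameter + 1)}
    a = net.adjacency.astype(np.float64)
    rc_edge = a * np.outer(rc_mask, rc_mask)
    endpoint = (~rc_mask).astype(np.float64)
    pair_ok = np.outer(endpoint, endpoint)

    counts, medians, touch, travel, n_paths = {}, {}, {}, {}, {}
    for ell in lengths:
        d_l = np.where(d == ell, 1.0, 0.0) * pair_ok
        total = float((d_l * sigma).sum())
        n_paths[ell] = total
        pos = np.zeros((ell + 1, n))
        for p in range(ell + 1):
            pos[p] = np.diagonal(
                s_mats[p].T @ d_l @ s_mats[ell - p].T
            )
        counts[ell] = pos
        medians[ell] = np.array(
            [_weighted_median(ktot, pos[p]) for p in range(ell + 1)]
        )
        if total > 0:
            touch[ell] = pos[:, rc_mask].sum(axis=1) / total
            tr = np.zeros(ell)
            for p in range(ell):
                step = s_mats[p].T @ d_l @ s_mats[ell - p - 1].T
                tr[p] = float((step * rc_edge).sum()) / total
            travel[ell] = tr
        else:
            touch[ell] = np.zeros(ell + 1)
            travel[ell] = np.zeros(ell)
    return DegreeAlongPath(
        lengths=tuple(lengths),
        node_position_counts=counts,
        median_degree=medians,
        touch_prob=touch,
        travel_prob=travel,
        n_paths=n_paths,
    )


# ---------------------------------------------------------------------------
# Flow asymmetry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowAsymmetry:
    rc_nodes: np.ndarray  # node indices, sorted
    in_paths: np.ndarray
    out_paths: np.ndarray
    ratio: np.ndarray  # (in - out) / (in + out); NaN when in + out == 0
    null_mean: np.ndarray
    null_sd: np.ndarray
    p_value: np.ndarray  # two-sided empirical, uncorrected
    n_null: int

    def as_frame(self, net: ConnectionMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "in_paths": self.in_paths,
                "out_paths": self.out_paths,
                "ratio": self.ratio,
                "null_mean_ratio": self.null_mean,
                "null_sd_ratio": self.null_sd,
                "p_value": self.p_value,
            },
            index=[net.labels[i] for i in self.rc_nodes],
        )


def _flow_counts(net: ConnectionMatrix, rc_mask: np.ndarray):
    n = net.n_nodes
    indptr, indices = _csr_arrays(net)
    edges = net.edge_array()
    in_events = np.zeros(n)
    out_events = np.zeros(n)
    flow_events(
        indptr, indices, n,
        np.flatnonzero(~rc_mask).astype(np.int64),
        rc_mask.astype(np.uint8),
        np.ascontiguousarray(edges[:, 0]),
        np.ascontiguousarray(edges[:, 1]),
        in_events, out_events,
    )
    return in_events, out_events


def _ratios(in_ev, out_ev, rc_idx):
    tot = in_ev[rc_idx] + out_ev[rc_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tot > 0, (in_ev[rc_idx] - out_ev[rc_idx]) / tot,
                        np.nan)


def flow_asymmetry(
    net: ConnectionMatrix,
    rc_nodes,
    ensemble: NullEnsemble,
) -> FlowAsymmetry:
    """In/out path counts through each RC node and their asymmetry.

    Entry (exit) events count every step of a shortest path between
    non-RC endpoints crossing from outside (inside) the RC to inside
    (outside); significance is an empirical two-sided p-value of the
    in-out ratio against the degree-preserving randomized ensemble.
    """
    if ensemble.model != "randomized":
        raise ValueError("flow-asymmetry nulls must use the randomized model")
    n = net.n_nodes
    rc_mask = np.zeros(n, dtype=bool)
    rc_idx = np.unique(np.asarray(list(rc_nodes), dtype=np.int64))
    rc_mask[rc_idx] = True
    in_ev, out_ev = _flow_counts(net, rc_mask)
    obs_ratio = _ratios(in_ev, out_ev, rc_idx)

    null_ratios = np.empty((len(ensemble), rc_idx.size))
    for i, member in enumerate(ensemble):
        nin, nout = _flow_counts(member, rc_mask)
        null_ratios[i] = _ratios(nin, nout, rc_idx)
    n_null = len(ensemble)
    with np.errstate(invalid="ignore"):
        ge = np.nansum(null_ratios >= obs_ratio[None, :], axis=0)
        le = np.nansum(null_ratios <= obs_ratio[None, :], axis=0)
    p = np.minimum(1.0, 2.0 * (1.0 + np.minimum(ge, le)) / (1.0 + n_null))
    p[np.isnan(obs_ratio)] = np.nan
    return FlowAsymmetry(
        rc_nodes=rc_idx,
        in_paths=in_ev[rc_idx],
        out_paths=out_ev[rc_idx],
        ratio=obs_ratio,
        null_mean=np.nanmean(null_ratios, axis=0),
        null_sd=np.nanstd(null_ratios, axis=0),
        p_value=p,
        n_null=n_null,
    )


# ---------------------------------------------------------------------------
# Communication cost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CommunicationCost:
    per_edge: pd.DataFrame  # source, target, class, usage, length, cost
    class_density_share: dict[str, float]
    class_cost_share: dict[str, float]
    cost_over_density: dict[str, float]
    tests: pd.DataFrame  # one-sided rank-sum comparisons
    n_covered_nodes: int


def _rank_sum_one_sided(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p for x stochastically greater than y
    (exact permutation-based method for small samples)."""
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    method = "exact" if min(len(x), len(y)) < 20 else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def communication_cost(
    net: ConnectionMatrix,
    coords: pd.DataFrame,
    edge_classes: EdgeClassification,
    path_stats: PathStats | None = None,
) -> CommunicationCost:
    """Per-edge Euclidean length, cost (usage x length) and class shares.

    ``coords`` is indexed by region label with columns x, y, z and may
    cover only a subset of regions; the analysis is restricted to edges
    whose both endpoints are covered.  Shares are reported per edge
    class for density (edge counts) and cost, plus the cost/density
    ratio; rank-sum tests compare rich-club and feeder edges against
    local edges on length and cost.
    """
    covered = [lab for lab in net.labels if lab in coords.index]
    if len(covered) < 2:
        raise ValueError("fewer than 2 regions have coordinates")
    xyz = {lab: coords.loc[lab, ["x", "y", "z"]].to_numpy(dtype=float)
           for lab in covered}
    if path_stats is None:
        path_stats = count_shortest_paths(net)
    rows = []
    for e, (s, t) in enumerate(path_stats.edges):
        ls, lt = net.labels[s], net.labels[t]
        if ls not in xyz or lt not in xyz:
            continue
        length = float(np.linalg.norm(xyz[ls] - xyz[lt]))
        usage = float(path_stats.edge_usage[e])
        cls = edge_classes.class_of[(int(s), int(t))]
        rows.append((ls, lt, cls, usage, length, usage * length))
    per_edge = pd.DataFrame(
        rows, columns=["source", "target", "class", "usage", "length", "cost"]
    )
    n_edges = len(per_edge)
    total_cost = per_edge.cost.sum()
    density_share, cost_share, ratio = {}, {}, {}
    for cls in ("rich_club", "feeder", "local"):
        sub = per_edge[per_edge["class"] == cls]
        density_share[cls] = len(sub) / n_edges if n_edges else 0.0
        cost_share[cls] = sub.cost.sum() / total_cost if total_cost else 0.0
        ratio[cls] = (cost_share[cls] / density_share[cls]
                      if density_share[cls] > 0 else float("nan"))
    tests = []
    local = per_edge[per_edge["class"] == "local"]
    for cls in ("rich_club", "feeder"):
        sub = per_edge[per_edge["class"] == cls]
        for measure in ("length", "cost"):
            tests.append(
                {
                    "comparison": f"{cls} > local",
                    "measure": measure,
                    "p_value": _rank_sum_one_sided(
                        sub[measure].to_numpy(), local[measure].to_numpy()
                    ),
                }
            )
    return CommunicationCost(
        per_edge=per_edge,
        class_density_share=density_share,
        class_cost_share=cost_share,
        cost_over_density=ratio,
        tests=pd.DataFrame(tests),
        n_covered_nodes=len(covered),
    )


# ---------------------------------------------------------------------------
# Cross-module paths
# ---------------------------------------------------------------------------


def cross_module_paths(
    net: ConnectionMatrix,
    assignment: np.ndarray,
    rc_nodes,
) -> pd.DataFrame:
    """RC involvement of shortest paths whose endpoints lie in different
    modules.

    A path "involves" the rich club when any of its nodes (endpoints
    included) is an RC member.  Returns one row per ordered module pair
    plus an "overall" row, with total paths and the involved fraction.
    """
    assignment = np.asarray(assignment)
    n = net.n_nodes
    rc_mask = np.zeros(n, dtype=bool)
    rc_mask[list(rc_nodes)] = True
    full = count_shortest_paths(net)
    avoid = count_shortest_paths(
        net,
        sources=np.flatnonzero(~rc_mask),
        allow=(~rc_mask).astype(np.uint8),
        targets_mask=(~rc_mask).astype(np.uint8),
    )
    same_len = (avoid.dist == full.dist) & (full.dist > 0)
    avoid_sigma = np.where(same_len, avoid.sigma, 0.0)
    cross = assignment[:, None] != assignment[None, :]
    rows = []
    modules = np.unique(assignment)
    tot_all = inv_all = 0.0
    for m1 in modules:
        for m2 in modules:
            if m1 == m2:
                continue
            mask = cross & np.outer(assignment == m1, assignment == m2)
            total = float(full.sigma[mask & (full.dist > 0)].sum())
            avoiding = float(avoid_sigma[mask].sum())
            involved = total - avoiding
            tot_all += total
            inv_all += involved
            rows.append(
                {
                    "module_from": int(m1),
                    "module_to": int(m2),
                    "total_paths": total,
                    "involved_fraction": involved / total if total else 0.0,
                }
            )
    rows.append(
        {
            "module_from": -1,
            "module_to": -1,
            "total_paths": tot_all,
            "involved_fraction": inv_all / tot_all if tot_all else 0.0,
        }
    )
    return pd.DataFrame(rows)
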