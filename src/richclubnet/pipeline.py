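"""End-to-end analysis: every stage on one network, shared null ensembles,
structured report.

Stage order: global metrics -> modularity -> centrality -> rich club ->
k-core -> motifs -> paths -> communication cost -> flow directionality.
Randomized and latticized ensembles are each built once at the largest
size any stage requests and sliced per stage, so all stages see
consistent null populations and the whole run is deterministic given the
master seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from richclubnet import centrality as centrality_mod
from richclubnet import community, motifs, paths, richclub, smallworld
from richclubnet.network_core import (
    ConnectionMatrix,
    degrees,
    prune_to_connected,
    reciprocity,
    shortest_distances,
)
from richclubnet.null_models import NullEnsemble, build_ensemble


@dataclass
class RunConfig:
    """Ensemble sizes, seeds and thresholds for a full run.

    Defaults use reduced ensemble sizes that keep a macaque-scale run in
    the minutes range; ``n_richclub=10000`` and ``n_flow=200`` reproduce
    the full-scale regime.
    """

    seed: int = 0
    n_richclub: int = 1000  # randomized nulls for the rich-club sweep
    n_smallworld: int = 100  # randomized + latticized for gamma/lambda/omega
    n_motifs: int = 100  # randomized + latticized for motif z-scores
    n_flow: int = 200  # randomized nulls for flow asymmetry
    swaps_per_edge: int = 10
    lattice_swaps_per_edge: int = 100
    fdr_q: float = 0.05
    z_threshold: float = 2.0
    p_threshold: float = 0.5
    top_percentile: float = 90.0
    star_restarts: int = 20
    prune_iterative: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class AnalysisReport:
    config: RunConfig
    net: ConnectionMatrix
    removed_in_pruning: list[str]
    reciprocity: float
    diameter: int
    small_world: smallworld.SmallWorldReport
    partition: community.ModularPartition
    roles: community.NodeRole
    centrality: centrality_mod.CentralityTable
    rich_club: richclub.RichClubResult
    core: richclub.CoreDecomposition
    census: motifs.MotifCensus
    motif_z: pd.DataFrame
    star_size: np.ndarray
    path_stats: paths.PathStats
    rc_participation: dict[int, paths.RCPathParticipation]
    degree_profile: paths.DegreeAlongPath | None
    flow: paths.FlowAsymmetry | None
    cost: paths.CommunicationCost | None
    cross_module: pd.DataFrame | None
    timings: dict[str, float] = field(default_factory=dict)

    # convenience accessors -------------------------------------------------
    @property
    def rc1(self) -> frozenset[int]:
        """Innermost (tightest) significant rich-club node set."""
        return self.rich_club.levels[0] if self.rich_club.levels else frozenset()

    @property
    def rc2(self) -> frozenset[int]:
        """Rich-club level with the lowest FDR-adjusted p-value."""
        res = self.rich_club
        sig = np.flatnonzero(res.fdr_significant)
        if sig.size == 0:
            return frozenset()
        best_k = int(res.k_values[sig[np.argmin(res.p_adjusted[sig])]])
        ktot = degrees(self.net).k
        return frozenset(np.flatnonzero(ktot > best_k).tolist())


def run_full_analysis(
    net: ConnectionMatrix,
    config: RunConfig | None = None,
    coords: pd.DataFrame | None = None,
    with_profiles: bool = True,
) -> AnalysisReport:
    """Run every analysis stage on a network.

    ``coords`` (label-indexed x/y/z centroid table) enables the
    communication-cost stage.  Set ``with_profiles=False`` to skip the
    positional degree-profile and flow-asymmetry stages (the most
    expensive ones at large ensemble sizes).
    """
    cfg = config or RunConfig()
    timings: dict[str, float] = {}

    def tic(name):
        timings[name] = time.perf_counter()

    def toc(name):
        timings[name] = time.perf_counter() - timings[name]

    tic("prune")
    net, removed = prune_to_connected(net, iterative=cfg.prune_iterative)
    toc("prune")

    tic("ensembles")
    n_rand = max(cfg.n_richclub, cfg.n_smallworld, cfg.n_motifs, cfg.n_flow)
    n_latt = max(cfg.n_smallworld, cfg.n_motifs)
    rand_all = build_ensemble(
        net, "randomized", n_rand, cfg.swaps_per_edge, seed=cfg.seed
    )
    latt_all = build_ensemble(
        net, "latticized", n_latt, cfg.lattice_swaps_per_edge,
        seed=cfg.seed + 1
    )

    def slice_ens(ens: NullEnsemble, size: int) -> NullEnsemble:
        return NullEnsemble(
            ens.members[:size], ens.model, ens.seed, ens.swaps_per_edge
        )

    toc("ensembles")

    tic("global_metrics")
    recip = reciprocity(net)
    dist = shortest_distances(net)
    sw = smallworld.small_world_indices(
        net,
        slice_ens(rand_all, cfg.n_smallworld),
        slice_ens(latt_all, cfg.n_smallworld),
    )
    toc("global_metrics")

    tic("modularity")
    partition = community.optimize_modularity_directed(net, seed=cfg.seed)
    roles = community.node_roles(
        net, partition, cfg.z_threshold, cfg.p_threshold
    )
    toc("modularity")

    tic("centrality")
    cent = centrality_mod.centrality_table(net)
    toc("centrality")

    tic("rich_club")
    rc_result = richclub.rich_club_curve(
        net, slice_ens(rand_all, cfg.n_richclub), q=cfg.fdr_q
    )
    core = richclub.kcore_decompose(net)
    toc("rich_club")

    tic("motifs")
    census = motifs.triad_census(net)
    motif_z = motifs.motif_zscores(
        net,
        slice_ens(rand_all, cfg.n_motifs),
        slice_ens(latt_all, cfg.n_motifs),
    )
    stars = motifs.star_sizes(
        net, n_restarts=cfg.star_restarts, seed=cfg.seed
    )
    toc("motifs")

    tic("paths")
    path_stats = paths.count_shortest_paths(net)
    report = AnalysisReport(
        config=cfg,
        net=net,
        removed_in_pruning=removed,
        reciprocity=recip,
        diameter=dist.diameter,
        small_world=sw,
        partition=partition,
        roles=roles,
        centrality=cent,
        rich_club=rc_result,
        core=core,
        census=census,
        motif_z=motif_z,
        star_size=stars,
        path_stats=path_stats,
        rc_participation={},
        degree_profile=None,
        flow=None,
        cost=None,
        cross_module=None,
        timings=timings,
    )
    rc1, rc2 = report.rc1, report.rc2
    participation = {}
    if rc1:
        participation[1] = paths.rc_participation(net, rc1)
        if rc2 != rc1:
            participation[2] = paths.rc_participation(net, rc2)
    report.rc_participation = participation
    cross = (
        paths.cross_module_paths(net, partition.assignment, rc1)
        if rc1 else None
    )
    report.cross_module = cross
    toc("paths")

    if with_profiles and rc2:
        tic("profiles")
        report.degree_profile = paths.degree_profile_along_paths(net, rc2)
        toc("profiles")
        tic("flow")
        report.flow = paths.flow_asymmetry(
            net, rc2, slice_ens(rand_all, cfg.n_flow)
        )
        toc("flow")

    if coords is not None and rc1:
        tic("cost")
        classes = richclub.classify_edges(net, rc1)
        report.cost = paths.communication_cost(
            net, coords, classes, path_stats
        )
        toc("cost")
    return report


def write_report(report: AnalysisReport, out_dir: str | Path) -> Path:
    """Write the report as a JSON summary plus tidy CSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = report.net
    labels = list(net.labels)

    deg = degrees(net)
    deg.as_frame(labels).to_csv(out / "degrees.csv")
    report.centrality.as_frame(labels).to_csv(out / "centrality.csv")
    pd.DataFrame(
        {
            "module": report.partition.assignment,
            "participation": report.roles.participation,
            "z_within": report.roles.z_within,
            "connector_hub": report.roles.is_connector_hub,
        },
        index=labels,
    ).to_csv(out / "modules.csv")
    rc = report.rich_club
    pd.DataFrame(
        {
            "k": rc.k_values,
            "phi": rc.phi,
            "phi_random_mean": rc.phi_random_mean,
            "phi_norm": rc.phi_norm,
            "p_raw": rc.p_raw,
            "p_adjusted": rc.p_adjusted,
            "significant": rc.fdr_significant,
        }
    ).to_csv(out / "rich_club_curve.csv", index=False)
    report.motif_z.to_csv(out / "motif_zscores.csv")
    report.path_stats.edge_usage_frame(net).to_csv(
        out / "edge_usage.csv", index=False
    )
    if report.flow is not None:
        report.flow.as_frame(net).to_csv(out / "flow_asymmetry.csv")
    if report.cost is not None:
        report.cost.per_edge.to_csv(out / "edge_cost.csv", index=False)
    if report.cross_module is not None:
        report.cross_module.to_csv(out / "cross_module_paths.csv", index=False)

    summary = {
        "config": report.config.as_dict(),
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "density": net.density,
        "removed_in_pruning": report.removed_in_pruning,
        "reciprocity": report.reciprocity,
        "diameter": report.diameter,
        "small_world": report.small_world.as_dict(),
        "modularity": {
            "Q": report.partition.Q,
            "n_modules": report.partition.n_modules,
            "within_density": report.partition.within_density,
            "between_density": report.partition.between_density,
            "intra_edge_fraction": report.partition.intra_edge_fraction,
        },
        "connector_hubs": [
            labels[i] for i in np.flatnonzero(report.roles.is_connector_hub)
        ],
        "top_centrality_regions": [
            labels[i]
            for i in np.flatnonzero(report.centrality.global_score == 4)
        ],
        "rich_club": {
            "n_levels": len(rc.levels),
            "level_sizes": [len(s) for s in rc.levels],
            "level_k": rc.level_k,
            "levels": rc.level_labels(net),
        },
        "k_core": {
            "disintegration_k": report.core.disintegration_k,
            "peak_core_size": report.core.peak_core_size,
        },
        "motif_counts": {
            int(i): int(c)
            for i, c in enumerate(report.census.class_count)
            if i > 0
        },
        "total_shortest_paths": report.path_stats.total_paths,
        "rc_participation": {
            lvl: {
                "touch": p.frac_touch_node,
                "travel": p.frac_travel_edge,
                "total_paths": p.total_paths,
            }
            for lvl, p in report.rc_participation.items()
        },
        "timings_s": report.timings,
    }
    if report.cost is not None:
        summary["communication_cost"] = {
            "density_share": report.cost.class_density_share,
            "cost_share": report.cost.class_cost_share,
            "cost_over_density": report.cost.cost_over_density,
        }
    path = out / "report.json"
    path.write_text(json.dumps(summary, indent=2, default=float))
    return path
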