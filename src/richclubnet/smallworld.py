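"""Directed clustering, path length, efficiency and small-world indices.

Clustering uses the Fagiolo directed coefficient: with A the binary
adjacency, the number of directed triangles around node i is
t_i = 1/2 [(A + A^T)^3]_ii and the coefficient is

    C_i = t_i / (k_i (k_i - 1) - 2 k_i^<->)

where k_i is the total (in+out) degree and k_i^<-> the number of
reciprocal neighbors; the denominator discounts "false" triangles formed
by reciprocal edges alone.  Nodes with fewer than two neighbors get 0.

The characteristic path length L is the mean of finite off-diagonal
entries of the hop-distance matrix; global efficiency is the mean of
1/d over ordered pairs; local efficiency of node i is the global
efficiency of the subgraph induced on its in/out-neighborhood.

Normalized indices calibrate against degree-matched null populations:
gamma = C/<C_rand>, lambda = L/<L_rand>, sigma = gamma/lambda, and
omega = <L_rand>/L - C/<C_latt> (clustering referenced to the lattice
null, path length to the random null; omega near 0 marks a small world).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from richclubnet.network_core import (
    ConnectionMatrix,
    DistanceMatrix,
    shortest_distances,
)
from richclubnet.null_models import NullEnsemble


@dataclass(frozen=True)
class SmallWorldReport:
    C: float
    L: float
    E_glob: float
    E_loc: float
    gamma: float
    lam: float
    sigma: float
    omega: float
    n_random: int
    n_lattice: int

    def as_dict(self) -> dict:
        return {
            "C": self.C,
            "L": self.L,
            "E_glob": self.E_glob,
            "E_loc": self.E_loc,
            "gamma": self.gamma,
            "lambda": self.lam,
            "sigma": self.sigma,
            "omega": self.omega,
            "n_random": self.n_random,
            "n_lattice": self.n_lattice,
        }


def clustering_directed(net: ConnectionMatrix) -> np.ndarray:
    """Fagiolo directed clustering coefficient per node."""
    a = net.adjacency.astype(np.float64)
    sym = a + a.T
    t = np.diagonal(sym @ sym @ sym) / 2.0
    k = a.sum(axis=0) + a.sum(axis=1)
    k_recip = np.diagonal(a @ a)  # reciprocal-neighbor count
    denom = k * (k - 1) - 2 * k_recip
    c = np.zeros(net.n_nodes)
    ok = denom > 0
    c[ok] = t[ok] / denom[ok]
    return c


def characteristic_path_length(dist: DistanceMatrix) -> float:
    """Mean finite off-diagonal hop distance (self-pairs excluded)."""
    d = dist.d
    n = d.shape[0]
    mask = np.isfinite(d) & ~np.eye(n, dtype=bool)
    if not mask.any():
        return float("inf")
    return float(d[mask].mean())


def global_efficiency(dist: DistanceMatrix) -> float:
    """Mean of 1/d over ordered node pairs (unreachable pairs give 0)."""
    d = dist.d
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(net: ConnectionMatrix) -> np.ndarray:
    """Per-node efficiency of the subgraph on its in/out-neighborhood."""
    a = net.adjacency
    neigh = (a + a.T) > 0
    out = np.zeros(net.n_nodes)
    for i in range(net.n_nodes):
        nb = np.flatnonzero(neigh[i])
        if nb.size < 2:
            continue
        sub = net.subnetwork(nb)
        out[i] = global_efficiency(shortest_distances(sub))
    return out


def _ensemble_cl(ensemble: NullEnsemble) -> tuple[float, float]:
    cs, ls = [], []
    for member in ensemble:
        cs.append(float(clustering_directed(member).mean()))
        ls.append(characteristic_path_length(shortest_distances(member)))
    return float(np.mean(cs)), float(np.mean(ls))


def small_world_indices(
    net: ConnectionMatrix,
    rand_ensemble: NullEnsemble,
    latt_ensemble: NullEnsemble,
) -> SmallWorldReport:
    """Small-world report with gamma, lambda, sigma and omega."""
    if rand_ensemble.model != "randomized":
        raise ValueError("rand_ensemble must use the randomized null model")
    if latt_ensemble.model != "latticized":
        raise ValueError("latt_ensemble must use the latticized null model")
    c = float(clustering_directed(net).mean())
    dist = shortest_distances(net)
    length = characteristic_path_length(dist)
    c_rand, l_rand = _ensemble_cl(rand_ensemble)
    c_latt, _ = _ensemble_cl(latt_ensemble)
    gamma = c / c_rand
    lam = length / l_rand
    return SmallWorldReport(
        C=c,
        L=length,
        E_glob=global_efficiency(dist),
        E_loc=float(local_efficiency(net).mean()),
        gamma=gamma,
        lam=lam,
        sigma=gamma / lam,
        omega=l_rand / length - c / c_latt,
        n_random=len(rand_ensemble),
        n_lattice=len(latt_ensemble),
    )
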