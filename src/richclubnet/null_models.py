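"""Degree-preserving null models: edge randomization and latticization.

Both nulls rewire the empirical network by Markov-chain double-edge
swaps, (a->b, c->d) => (a->d, c->b), rejecting swaps that would create
self-loops or duplicate edges.  Size, density and the exact in- and
out-degree sequences are conserved by construction.

*Randomization* accepts every legal swap and destroys all global
structure beyond the degree sequence.  *Latticization* additionally
requires that the rewired edges do not move further from the matrix
diagonal under a node ordering drawn at random per instantiation,
concentrating edges among "neighboring" nodes as in a ring lattice
(a cost-efficient wiring null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from richclubnet._kernels import rewire_kernel
from richclubnet.network_core import ConnectionMatrix

#: default swap attempts per edge for randomization (Markov-chain mixing)
DEFAULT_SWAPS_PER_EDGE = 10
#: default for latticization, whose accept-only-if-closer rule is a greedy
#: descent and needs far more attempts to approach the converged lattice
LATTICE_SWAPS_PER_EDGE = 100


def _rewire(
    net: ConnectionMatrix,
    swaps_per_edge: int,
    rng: np.random.Generator,
    lattice: bool,
    strict: bool = False,
) -> tuple[ConnectionMatrix, int]:
    edges = net.edge_array()
    m = edges.shape[0]
    if m < 2:
        warnings.warn("network has <2 edges; returning an unchanged copy")
        return net.with_adjacency(net.adjacency.copy()), 0
    adj = net.adjacency.copy()
    src = np.ascontiguousarray(edges[:, 0])
    dst = np.ascontiguousarray(edges[:, 1])
    n_attempts = int(swaps_per_edge) * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    if lattice:
        order = rng.permutation(net.n_nodes).astype(np.int64)
    else:
        order = np.zeros(net.n_nodes, dtype=np.int64)
    accepted = rewire_kernel(adj, src, dst, pick, order, lattice, strict)
    if accepted == 0:
        warnings.warn(
            "degree sequence admits no rewiring; returning an unchanged copy"
        )
    return net.with_adjacency(adj), int(accepted)


def randomize(
    net: ConnectionMatrix,
    swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
) -> ConnectionMatrix:
    """One randomized network sharing the empirical degree sequences."""
    rng = np.random.default_rng(seed)
    out, _ = _rewire(net, swaps_per_edge, rng, lattice=False)
    return out


def latticize(
    net: ConnectionMatrix,
    swaps_per_edge: int = LATTICE_SWAPS_PER_EDGE,
    seed: int | np.random.Generator = 0,
    strict: bool = False,
) -> ConnectionMatrix:
    """One latticized network (edges concentrated near the diagonal).

    ``strict=True`` requires each rewired edge individually not to move
    away from the diagonal; the default accepts any swap whose combined
    diagonal distance does not increase.
    """
    rng = np.random.default_rng(seed)
    out, _ = _rewire(net, swaps_per_edge, rng, lattice=True, strict=strict)
    return out


def member_seed(master_seed: int, index: int) -> int:
    """Derive a per-member sub-seed (splitmix64-style) below 2**31."""
    mask = 0xFFFFFFFFFFFFFFFF
    z = (int(master_seed) + (index + 1) * 0x9E3779B97F4A7C15) & mask
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
    z ^= z >> 31
    return z % (2**31 - 1)


@dataclass
class NullEnsemble:
    """A seeded population of degree-matched null networks."""

    members: list[ConnectionMatrix]
    model: str  # "randomized" | "latticized"
    seed: int
    swaps_per_edge: int

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def metadata(self) -> dict:
        return {
            "model": self.model,
            "size": len(self.members),
            "seed": self.seed,
            "swaps_per_edge": self.swaps_per_edge,
        }


def build_ensemble(
    net: ConnectionMatrix,
    model: str,
    size: int,
    swaps_per_edge: int | None = None,
    seed: int = 0,
) -> NullEnsemble:
    """Build a reproducible null population.

    Member *i* is generated from the sub-seed ``member_seed(seed, i)``,
    so ensembles are deterministic given ``seed`` and trivially
    parallelizable or resumable.
    """
    if size < 1:
        raise ValueError("ensemble size must be >= 1")
    if model not in ("randomized", "latticized"):
        raise ValueError(f"unknown null model {model!r}")
    if swaps_per_edge is None:
        swaps_per_edge = (DEFAULT_SWAPS_PER_EDGE if model == "randomized"
                          else LATTICE_SWAPS_PER_EDGE)
    make = randomize if model == "randomized" else latticize
    members = [
        make(net, swaps_per_edge=swaps_per_edge, seed=member_seed(seed, i))
        for i in range(size)
    ]
    return NullEnsemble(members, model, seed, swaps_per_edge)
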