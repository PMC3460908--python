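"""Directed triad (3-node motif) census, null-model z-scores, apex
statistics and star-motif search.

Thirteen connected directed 3-node graphs exist up to isomorphism.  The
canonical numbering used here orders the isomorphism classes by edge
count (counting each direction separately) and, within an edge count, by
the lexicographically sorted per-node (out-degree, in-degree) signature.
Under this ordering the three *apex* classes — a central node adjacent
to two mutually unconnected nodes — are classes 4 and 6 (apex tied to
one leaf reciprocally and to the other by a single edge, outgoing for 4
and incoming for 6) and class 9 (apex tied to both leaves reciprocally);
class 13 is the fully reciprocal triangle.  Counting is induced-subgraph
counting: every connected node triple contributes to exactly one class.

``motif_library()`` returns the full auditable id -> pattern table.
"""

from __future__ import annotations

from dataclasses import dataclass
import networkx as nx
import numpy as np
import pandas as pd

from richclubnet.network_core import ConnectionMatrix
from richclubnet.null_models import NullEnsemble

#: the three apex motif classes
APEX_CLASSES = (4, 6, 9)

# ---------------------------------------------------------------------------
# Canonical class library, derived once at import
# ---------------------------------------------------------------------------
# A triad over nodes (0, 1, 2) is encoded by 6 bits, one per ordered pair
# in the fixed order (0,1),(0,2),(1,0),(1,2),(2,0),(2,1).

_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def _code_to_adj(code: int) -> np.ndarray:
    a = np.zeros((3, 3), dtype=np.int64)
    for bit, (i, j) in enumerate(_PAIRS):
        if code >> bit & 1:
            a[i, j] = 1
    return a


def _signature(a: np.ndarray) -> tuple:
    deg = sorted((int(a[i].sum()), int(a[:, i].sum())) for i in range(3))
    return (int(a.sum()),) + tuple(x for pair in deg for x in pair)


def _build_library():
    sig_of_code: dict[int, tuple] = {}
    for code in range(64):
        a = _code_to_adj(code)
        und = a + a.T
        if all(und[i].sum() > 0 for i in range(3)):  # weakly connected
            sig_of_code[code] = _signature(a)
    classes = sorted(set(sig_of_code.values()))
    class_of_sig = {sig: i + 1 for i, sig in enumerate(classes)}
    class_of_code = np.zeros(64, dtype=np.int64)  # 0 = disconnected
    apex_of_code = np.full(64, -1, dtype=np.int64)
    for code, sig in sig_of_code.items():
        cls = class_of_sig[sig]
        class_of_code[code] = cls
        if cls in APEX_CLASSES:
            a = _code_to_adj(code)
            und = a + a.T
            # apex = the single node adjacent to both others
            for i in range(3):
                others = [j for j in range(3) if j != i]
                if (und[i, others[0]] and und[i, others[1]]
                        and not und[others[0], others[1]]):
                    apex_of_code[code] = i
                    break
    return class_of_code, apex_of_code, len(classes)


_CLASS_OF_CODE, _APEX_OF_CODE, N_CLASSES = _build_library()
assert N_CLASSES == 13


def _triad_code(a: np.ndarray, u: int, v: int, w: int) -> int:
    nodes = (u, v, w)
    code = 0
    for bit, (i, j) in enumerate(_PAIRS):
        if a[nodes[i], nodes[j]]:
            code |= 1 << bit
    return code


def motif_library() -> pd.DataFrame:
    """Auditable table: class id, edge pattern, census name, apex flag.

    The ``census_name`` column gives the standard triad-census label
    (021D ... 300) so the numbering can be checked against any motif
    reference.
    """
    rows = []
    for name in ("021D", "021U", "021C", "111D", "111U", "030T", "030C",
                 "201", "120D", "120U", "120C", "210", "300"):
        g = nx.triad_graph(name)
        mapping = {n: i for i, n in enumerate(sorted(g.nodes()))}
        a = np.zeros((3, 3), dtype=np.int64)
        for s, t in g.edges():
            a[mapping[s], mapping[t]] = 1
        code = _triad_code(a, 0, 1, 2)
        cls = int(_CLASS_OF_CODE[code])
        edges = sorted(
            f"{'abc'[mapping[s]]}->{'abc'[mapping[t]]}" for s, t in g.edges()
        )
        rows.append(
            {
                "class_id": cls,
                "census_name": name,
                "n_edges": int(a.sum()),
                "edges": ";".join(edges),
                "is_apex_class": cls in APEX_CLASSES,
            }
        )
    return pd.DataFrame(rows).sort_values("class_id").reset_index(drop=True)


_NAME_TO_CLASS = None


def _census_name_to_class() -> dict[str, int]:
    global _NAME_TO_CLASS
    if _NAME_TO_CLASS is None:
        lib = motif_library()
        _NAME_TO_CLASS = dict(zip(lib.census_name, lib.class_id))
    return _NAME_TO_CLASS


# ---------------------------------------------------------------------------
# Census
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifCensus:
    class_count: np.ndarray  # index 0 unused; [1..13]
    node_participation: np.ndarray  # (n_nodes, 14)
    node_apex_count: np.ndarray  # (n_nodes, 14); nonzero only for 4, 6, 9

    def apex_ratio(self, node: int, classes=APEX_CLASSES) -> float:
        """Fraction of the node's apex-motif instances (over the given
        classes) in which it occupies the apex; 0 if it participates in
        none."""
        classes = list(np.atleast_1d(classes))
        part = self.node_participation[node, classes].sum()
        if part == 0:
            return 0.0
        return float(self.node_apex_count[node, classes].sum() / part)


@dataclass(frozen=True)
class StarMotif:
    center: int
    leaves: frozenset[int]

    @property
    def size(self) -> int:
        return len(self.leaves)


def triad_census(net: ConnectionMatrix) -> MotifCensus:
    """Exact induced census with per-node participation and apex tallies.

    Enumeration visits every weakly connected node triple exactly once
    (from its first linked dyad), so runtime scales with the number of
    connected triples rather than all n-choose-3 triples.
    """
    from scipy.sparse import csr_matrix

    from richclubnet._kernels import triad_census_kernel

    a = net.adjacency
    n = net.n_nodes
    und = csr_matrix(((a + a.T) > 0).astype(np.uint8))
    class_count = np.zeros(N_CLASSES + 1, dtype=np.int64)
    participation = np.zeros((n, N_CLASSES + 1), dtype=np.int64)
    apex_count = np.zeros((n, N_CLASSES + 1), dtype=np.int64)
    triad_census_kernel(
        a, und.indptr.astype(np.int64), und.indices.astype(np.int64),
        _CLASS_OF_CODE, _APEX_OF_CODE,
        class_count, participation, apex_count,
    )
    return MotifCensus(class_count, participation, apex_count)


def class_counts_fast(net: ConnectionMatrix) -> np.ndarray:
    """Connected-triad class counts only."""
    return triad_census(net).class_count


def class_counts_networkx(net: ConnectionMatrix) -> np.ndarray:
    """Class counts via the networkx triadic census (independent route,
    used for cross-checking)."""
    census = nx.triadic_census(net.to_digraph())
    counts = np.zeros(N_CLASSES + 1, dtype=np.int64)
    for name, cls in _census_name_to_class().items():
        counts[cls] = census[name]
    return counts


def motif_zscores(
    net: ConnectionMatrix,
    rand_ensemble: NullEnsemble,
    latt_ensemble: NullEnsemble,
) -> pd.DataFrame:
    """Per-class z-scores against both null populations.

    Classes whose null spread is zero get NaN z (flagged by the
    ``degenerate_*`` columns); ``over_represented`` marks classes with
    z > 2 against *both* nulls.
    """
    real = class_counts_fast(net)[1:]

    def null_stats(ensemble):
        counts = np.array(
            [class_counts_fast(member)[1:] for member in ensemble]
        )
        return counts.mean(axis=0), counts.std(axis=0)

    mean_r, sd_r = null_stats(rand_ensemble)
    mean_l, sd_l = null_stats(latt_ensemble)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_r = np.where(sd_r > 0, (real - mean_r) / sd_r, np.nan)
        z_l = np.where(sd_l > 0, (real - mean_l) / sd_l, np.nan)
    return pd.DataFrame(
        {
            "class_id": np.arange(1, N_CLASSES + 1),
            "count": real,
            "mean_random": mean_r,
            "z_vs_random": z_r,
            "degenerate_random": sd_r == 0,
            "mean_lattice": mean_l,
            "z_vs_lattice": z_l,
            "degenerate_lattice": sd_l == 0,
            "over_represented": (z_r > 2) & (z_l > 2),
        }
    ).set_index("class_id")


def apex_ratio(census: MotifCensus, node: int, classes=APEX_CLASSES) -> float:
    """Apex ratio of a node over the given apex classes."""
    return census.apex_ratio(node, classes)


def largest_star(
    net: ConnectionMatrix,
    center: int,
    n_restarts: int = 20,
    seed: int = 0,
) -> StarMotif:
    """Heuristically largest star motif centered on a node.

    A star is the center plus leaves that are each reciprocally connected
    to the center and mutually unconnected (in either direction).  The
    leaves form an independent set among the center's reciprocal
    neighbors; the greedy heuristic adds candidates in ascending-degree
    order, with seeded random-order restarts, keeping the best result.
    """
    a = net.adjacency
    recip = np.flatnonzero(a[center] & a[:, center])
    if recip.size == 0:
        return StarMotif(center=center, leaves=frozenset())
    und = (a + a.T) > 0
    deg = und.sum(axis=1)
    rng = np.random.default_rng(seed)

    def greedy(order):
        leaves: list[int] = []
        for cand in order:
            if all(not und[cand, leaf] for leaf in leaves):
                leaves.append(cand)
        return leaves

    best = greedy(recip[np.argsort(deg[recip], kind="stable")])
    for _ in range(n_restarts):
        trial = greedy(rng.permutation(recip))
        if len(trial) > len(best):
            best = trial
    return StarMotif(center=center, leaves=frozenset(int(x) for x in best))


def star_sizes(net: ConnectionMatrix, n_restarts: int = 20,
               seed: int = 0) -> np.ndarray:
    """Largest-star size for every node."""
    return np.array([
        largest_star(net, i, n_restarts=n_restarts, seed=seed + i).size
        for i in range(net.n_nodes)
    ])


def brute_force_census(net: ConnectionMatrix) -> np.ndarray:
    """Independent oracle: classify all node triples by testing the 64
    patterns directly (cubic; small graphs only)."""
    a = net.adjacency
    n = net.n_nodes
    counts = np.zeros(N_CLASSES + 1, dtype=np.int64)
    for u in range(n):
        for v in range(u + 1, n):
            for w in range(v + 1, n):
                code = _triad_code(a, u, v, w)
                counts[_CLASS_OF_CODE[code]] += 1
    counts[0] = 0
    return counts


def exhaustive_star_size(net: ConnectionMatrix, center: int) -> int:
    """Exact maximum star size by exhaustive independent-set search
    (exponential; small graphs only)."""
    a = net.adjacency
    recip = [int(x) for x in np.flatnonzero(a[center] & a[:, center])]
    und = (a + a.T) > 0

    def grow(chosen, rest):
        if not rest:
            return len(chosen)
        best = len(chosen)
        for i, cand in enumerate(rest):
            if all(not und[cand, c] for c in chosen):
                best = max(best, grow(chosen + [cand], rest[i + 1:]))
        return best

    return grow([], recip)
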