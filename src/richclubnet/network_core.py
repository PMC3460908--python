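"""Graph data model, file I/O and degree/distance primitives.

The single in-memory container is :class:`ConnectionMatrix`, a binary
directed adjacency matrix with region labels.  Orientation is
rows = source, columns = target: ``a[i, j] == 1`` means region *i* sends a
projection to region *j*.  Self-connections are forbidden and entries must
be 0/1.  All public functions accept and return this container; node
indexing is 0-based internally while every exported table is keyed by
region label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


class NetworkError(ValueError):
    """Raised for structurally invalid or degenerate networks."""


@dataclass(frozen=True, eq=False)
class ConnectionMatrix:
    """Binary directed adjacency matrix with region labels.

    Parameters
    ----------
    adjacency
        ``(N, N)`` array of 0/1 indicators; ``adjacency[i, j] == 1`` iff
        there is a directed projection i -> j.  No self-loops.
    labels
        ``N`` unique region-name strings, order defining matrix order.
    module_of
        Optional mapping label -> community id.
    """

    adjacency: np.ndarray
    labels: tuple[str, ...]
    module_of: dict[str, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise NetworkError(f"adjacency must be square, got shape {a.shape}")
        if not np.isin(a, (0, 1)).all():
            raise NetworkError("adjacency entries must be binary (0/1)")
        if np.diagonal(a).any():
            raise NetworkError("self-loop present: diagonal entries must be 0")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != a.shape[0]:
            raise NetworkError(
                f"{len(labels)} labels for {a.shape[0]} matrix rows"
            )
        if len(set(labels)) != len(labels):
            raise NetworkError("region labels must be unique")
        object.__setattr__(self, "adjacency", a.astype(np.uint8))
        object.__setattr__(self, "labels", labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectionMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(
            self.adjacency, other.adjacency
        )

    def __hash__(self) -> int:
        return hash((self.labels, self.adjacency.tobytes()))

    # -- basic descriptors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1))

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def edge_array(self) -> np.ndarray:
        """``(E, 2)`` int array of (source, target) node indices."""
        src, dst = np.nonzero(self.adjacency)
        return np.column_stack([src, dst]).astype(np.int64)

    def subnetwork(self, nodes: Sequence[int]) -> "ConnectionMatrix":
        """Induced subgraph on the given node indices (order preserved)."""
        idx = np.asarray(list(nodes), dtype=np.int64)
        sub = self.adjacency[np.ix_(idx, idx)]
        labels = tuple(self.labels[i] for i in idx)
        mod = None
        if self.module_of is not None:
            mod = {l: self.module_of[l] for l in labels if l in self.module_of}
        return ConnectionMatrix(sub, labels, mod)

    def with_adjacency(self, adjacency: np.ndarray) -> "ConnectionMatrix":
        """Same labels/modules, different adjacency (used by null models)."""
        return ConnectionMatrix(adjacency, self.labels, self.module_of)

    def to_digraph(self):
        """networkx.DiGraph view (integer nodes, ``label`` attribute)."""
        import networkx as nx

        g = nx.from_numpy_array(
            self.adjacency.astype(int), create_using=nx.DiGraph
        )
        nx.set_node_attributes(
            g, {i: lab for i, lab in enumerate(self.labels)}, "label"
        )
        return g


@dataclass(frozen=True)
class DegreeProfile:
    """Per-node in-, out- and total degree (k = k_in + k_out)."""

    k_in: np.ndarray
    k_out: np.ndarray

    @property
    def k(self) -> np.ndarray:
        return self.k_in + self.k_out

    def as_frame(self, labels: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {"k_in": self.k_in, "k_out": self.k_out, "k": self.k},
            index=list(labels),
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Directed hop distances; unreachable pairs are ``inf``."""

    d: np.ndarray

    @property
    def diameter(self) -> int:
        finite = self.d[np.isfinite(self.d)]
        off = finite[finite > 0]
        return int(off.max()) if off.size else 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _read_labels(labels_path: str | Path) -> tuple[str, ...]:
    lines = Path(labels_path).read_text().splitlines()
    return tuple(s.strip() for s in lines if s.strip())


def load_network(
    adjacency_path: str | Path,
    labels_path: str | Path,
    transpose: bool = False,
) -> ConnectionMatrix:
    """Load a network from an adjacency (or edge-list) file plus a label file.

    The adjacency file is either a whitespace/comma-delimited dense N x N
    0/1 table, or an edge list with two (or more) columns of region labels
    per line (source, target).  The labels file has one region name per
    line; its order defines matrix order.

    Parameters
    ----------
    transpose
        Set when the input file stores columns = source (the package
        convention is rows = source).
    """
    labels = _read_labels(labels_path)
    n = len(labels)
    first = ""
    with open(adjacency_path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    tokens = first.replace(",", " ").split()
    numeric = all(t.lstrip("+-").replace(".", "", 1).isdigit() for t in tokens)
    if numeric and len(tokens) == n:
        a = np.loadtxt(adjacency_path, delimiter="," if "," in first else None)
    else:
        index = {lab: i for i, lab in enumerate(labels)}
        a = np.zeros((n, n), dtype=np.uint8)
        with open(adjacency_path) as fh:
            for line in fh:
                parts = line.replace(",", " ").split()
                if not parts:
                    continue
                s, t = parts[0], parts[1]
                if s not in index or t not in index:
                    raise NetworkError(f"edge-list label not in labels file: {s}->{t}")
                a[index[s], index[t]] = 1
    if a.shape != (n, n):
        raise NetworkError(
            f"adjacency shape {a.shape} does not match {n} labels"
        )
    if transpose:
        a = a.T
    return ConnectionMatrix(a, labels)


def save_network(net: ConnectionMatrix, adjacency_path: str | Path,
                 labels_path: str | Path) -> None:
    np.savetxt(adjacency_path, net.adjacency, fmt="%d")
    Path(labels_path).write_text("\n".join(net.labels) + "\n")


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def degrees(net: ConnectionMatrix) -> DegreeProfile:
    """In-, out- and total degree of every node."""
    a = net.adjacency
    return DegreeProfile(
        k_in=a.sum(axis=0).astype(np.int64),
        k_out=a.sum(axis=1).astype(np.int64),
    )


def reciprocity(net: ConnectionMatrix) -> float:
    """Fraction of directed edges whose opposite edge also exists.

    Equals 2 * (#reciprocal dyads) / |E|: an edge counts as reciprocal when
    it lies in a mutually connected pair.
    """
    a = net.adjacency
    m = int(a.sum())
    if m == 0:
        raise NetworkError("reciprocity undefined on an empty graph")
    paired = int((a & a.T).sum())  # counts both edges of each mutual dyad
    return paired / m


def shortest_distances(net: ConnectionMatrix) -> DistanceMatrix:
    """Directed hop (BFS) distances between all ordered node pairs."""
    if net.n_nodes == 0:
        raise NetworkError("empty network")
    sp = shortest_path(
        csr_matrix(net.adjacency), method="D", unweighted=True, directed=True
    )
    return DistanceMatrix(sp)


def prune_to_connected(
    net: ConnectionMatrix, iterative: bool = True
) -> tuple[ConnectionMatrix, list[str]]:
    """Remove nodes lacking at least one incoming and one outgoing edge.

    With ``iterative=True`` (default) removal is repeated until every
    surviving node keeps both an afferent and an efferent within the
    surviving subnetwork; with ``iterative=False`` a single pass is made
    against the original degrees.

    Returns the surviving subnetwork and the removal log (labels in order
    of removal).  Raises :class:`NetworkError` if nothing survives.
    """
    keep = np.arange(net.n_nodes)
    a = net.adjacency
    removed: list[str] = []
    while True:
        k_in = a.sum(axis=0)
        k_out = a.sum(axis=1)
        bad = (k_in == 0) | (k_out == 0)
        if not bad.any():
            break
        removed.extend(net.labels[i] for i in keep[bad])
        keep = keep[~bad]
        a = net.adjacency[np.ix_(keep, keep)]
        if keep.size == 0:
            raise NetworkError("pruning removed every node")
        if not iterative:
            # one pass: re-check only to report, not to remove further
            break
    return net.subnetwork(keep), removed
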