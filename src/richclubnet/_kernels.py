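"""Numba-compiled inner loops: edge rewiring and shortest-path counting.

All kernels are deterministic functions of their array arguments; any
randomness is drawn outside and passed in, so seeding lives entirely in
the calling code.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rewire_kernel(adj, src, dst, pick, order, lattice, strict):
    """In-place degree-preserving double-edge swaps.

    For each proposed pair of edge indices ``pick[t] = (e1, e2)`` with
    edges (a, b) and (c, d), attempt the swap (a, b), (c, d) ->
    (a, d), (c, b).  The swap is rejected when it would create a
    self-loop, a duplicate edge, or touch fewer than 4 distinct nodes.

    With ``lattice`` set, a swap is additionally accepted only if it does
    not increase the combined distance of the two edges from the matrix
    diagonal under the node ordering ``order`` (with ``strict`` set, each
    rewired edge must individually move strictly closer or stay).

    Returns the number of accepted swaps.
    """
    n_attempts = pick.shape[0]
    accepted = 0
    for t in range(n_attempts):
        e1 = pick[t, 0]
        e2 = pick[t, 1]
        if e1 == e2:
            continue
        a = src[e1]
        b = dst[e1]
        c = src[e2]
        d = dst[e2]
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        if lattice:
            before1 = abs(order[a] - order[b])
            before2 = abs(order[c] - order[d])
            after1 = abs(order[a] - order[d])
            after2 = abs(order[c] - order[b])
            if strict:
                if after1 > before1 or after2 > before2:
                    continue
            else:
                if after1 + after2 > before1 + before2:
                    continue
        adj[a, b] = 0
        adj[c, d] = 0
        adj[a, d] = 1
        adj[c, b] = 1
        dst[e1] = d
        dst[e2] = b
        accepted += 1
    return accepted


@njit(cache=True)
def _bfs_dag_counts(indptr, indices, n, s, dist, sigma,
                    h, bfs_order, allow, target_ok):
    """Single-source BFS with path counting on the shortest-path DAG.

    Fills ``dist`` (hop distance from s), ``sigma`` (number of shortest
    paths from s), and ``h`` (number of shortest-path *suffixes* starting
    at each node: h(v) = [v is an admissible target] + sum of h over DAG
    successors of v).  ``allow[v] == 0`` removes v as an intermediate
    (and as anything but the source).  Returns the number of reached
    nodes (length of ``bfs_order``).
    """
    for v in range(n):
        dist[v] = -1
        sigma[v] = 0.0
        h[v] = 0.0
    dist[s] = 0
    sigma[s] = 1.0
    bfs_order[0] = s
    head = 0
    tail = 1
    while head < tail:
        u = bfs_order[head]
        head += 1
        du = dist[u]
        su = sigma[u]
        for p in range(indptr[u], indptr[u + 1]):
            v = indices[p]
            if allow[v] == 0:
                continue
            if dist[v] == -1:
                dist[v] = du + 1
                bfs_order[tail] = v
                tail += 1
            if dist[v] == du + 1:
                sigma[v] += su
    # reverse BFS order for suffix counts
    for i in range(tail - 1, -1, -1):
        v = bfs_order[i]
        hv = 1.0 if (target_ok[v] == 1 and v != s) else 0.0
        dv = dist[v]
        for p in range(indptr[v], indptr[v + 1]):
            w = indices[p]
            if allow[w] == 0:
                continue
            if dist[w] == dv + 1:
                hv += h[w]
        h[v] = hv
    return tail


@njit(cache=True)
def path_census(indptr, indices, n, sources, allow, target_ok, edge_src,
                edge_dst, edge_usage, node_usage, sigma_out, dist_out):
    """All-sources shortest-path counts, per-edge and per-node usage.

    ``sources`` lists the source nodes to process.  For each admissible
    ordered pair (s, t) every distinct shortest path counts once.

    Outputs (accumulated in place):
      edge_usage[e]  -- number of counted paths traversing edge e
      node_usage[v]  -- number of counted paths with v as intermediate
      sigma_out[s, t] -- number of shortest s->t paths (0 if not counted)
      dist_out[s, t]  -- hop distance (-1 when unreachable)

    Returns total number of counted paths.
    """
    dist = np.empty(n, dtype=np.int64)
    sigma = np.empty(n, dtype=np.float64)
    h = np.empty(n, dtype=np.float64)
    bfs_order = np.empty(n, dtype=np.int64)
    total = 0.0
    n_edges = edge_src.shape[0]
    for si in range(sources.shape[0]):
        s = sources[si]
        reached = _bfs_dag_counts(indptr, indices, n, s, dist,
                                  sigma, h, bfs_order, allow, target_ok)
        for i in range(reached):
            v = bfs_order[i]
            sigma_out[s, v] = sigma[v]
            dist_out[s, v] = dist[v]
            if v == s:
                continue
            if target_ok[v] == 1:
                total += sigma[v]
                # paths through v as intermediate: suffixes minus the one
                # ending at v itself
                node_usage[v] += sigma[v] * (h[v] - 1.0)
            else:
                node_usage[v] += sigma[v] * h[v]
        for e in range(n_edges):
            u = edge_src[e]
            v = edge_dst[e]
            if allow[u] == 0 or allow[v] == 0:
                continue
            if dist[u] >= 0 and dist[v] == dist[u] + 1:
                edge_usage[e] += sigma[u] * h[v]
    return total


@njit(cache=True)
def flow_events(indptr, indices, n, sources, is_rc, edge_src, edge_dst,
                in_events, out_events):
    """Entry/exit path counts through each rich-club node.

    Over all shortest paths between non-RC ordered pairs, count for each
    RC node r the number of path steps u->r with u outside the RC
    (entries) and r->w with w outside the RC (exits).  Every boundary
    crossing along a path counts.
    """
    dist = np.empty(n, dtype=np.int64)
    sigma = np.empty(n, dtype=np.float64)
    h = np.empty(n, dtype=np.float64)
    bfs_order = np.empty(n, dtype=np.int64)
    allow = np.ones(n, dtype=np.uint8)
    target_ok = np.empty(n, dtype=np.uint8)
    for v in range(n):
        target_ok[v] = 0 if is_rc[v] == 1 else 1
    n_edges = edge_src.shape[0]
    for si in range(sources.shape[0]):
        s = sources[si]
        _bfs_dag_counts(indptr, indices, n, s, dist, sigma, h,
                        bfs_order, allow, target_ok)
        for e in range(n_edges):
            u = edge_src[e]
            v = edge_dst[e]
            if dist[u] >= 0 and dist[v] == dist[u] + 1:
                usage = sigma[u] * h[v]
                if usage > 0.0:
                    if is_rc[v] == 1 and is_rc[u] == 0:
                        in_events[v] += usage
                    if is_rc[u] == 1 and is_rc[v] == 0:
                        out_events[u] += usage


@njit(cache=True)
def triad_census_kernel(adj, indptr, indices, class_of_code, apex_of_code,
                        class_count, participation, apex_count):
    """Exact connected-triad census with per-node tallies.

    ``indptr/indices`` describe the *undirected* neighbor lists (sorted).
    Each connected triple {a < b < c} is visited exactly once: from its
    first linked pair in the order (a,b), (a,c), (b,c).
    """
    n = adj.shape[0]
    for x in range(n):
        for p in range(indptr[x], indptr[x + 1]):
            y = indices[p]
            if y <= x:
                continue
            # merge neighbors of x and y
            i = indptr[x]
            j = indptr[y]
            ex = indptr[x + 1]
            ey = indptr[y + 1]
            while i < ex or j < ey:
                if i < ex and (j >= ey or indices[i] <= indices[j]):
                    w = indices[i]
                    if j < ey and indices[j] == w:
                        j += 1
                    i += 1
                else:
                    w = indices[j]
                    j += 1
                if w == x or w == y:
                    continue
                if w > y:
                    pass  # (x, y) is the first linked pair
                elif w > x:
                    if adj[x, w] or adj[w, x]:
                        continue  # triple counted from pair (x, w)
                else:
                    continue  # w < x: counted from an earlier pair
                # code bits: pairs (0,1),(0,2),(1,0),(1,2),(2,0),(2,1)
                # on nodes (x, y, w)
                code = 0
                if adj[x, y]:
                    code |= 1
                if adj[x, w]:
                    code |= 2
                if adj[y, x]:
                    code |= 4
                if adj[y, w]:
                    code |= 8
                if adj[w, x]:
                    code |= 16
                if adj[w, y]:
                    code |= 32
                cls = class_of_code[code]
                class_count[cls] += 1
                participation[x, cls] += 1
                participation[y, cls] += 1
                participation[w, cls] += 1
                apex = apex_of_code[code]
                if apex == 0:
                    apex_count[x, cls] += 1
                elif apex == 1:
                    apex_count[y, cls] += 1
                elif apex == 2:
                    apex_count[w, cls] += 1
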