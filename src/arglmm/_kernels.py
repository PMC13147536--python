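"""Numba kernels: one genome sweep over edge insertions/removals.

Both kernels stream the local trees left-to-right in the standard
tree-sequence order (removals then insertions at each breakpoint) and
touch, per event, only the path from the event's child to its root.
Per-node state:

``parent``  current tree parent (-1 if detached),
``w``       sum of input weights over samples below the node (matvec only),
``pi``      cumulative per-sample contribution generated at-or-absorbed-by
            the node ("rain"),
``off``     value of the parent's ``pi`` when the node last synchronized,
``x``       genome position at which the node's parent branch was last
            settled.

When anything below a node is about to change, the pending fragment of
its parent branch — a sub-edge ``[x, pos)`` with constant descendant set
— is finalized into ``pi``, and pending rain is absorbed top-down along
the event path via ``pi[child] += pi[parent] - off[child]``.  Nodes off
the path absorb lazily at their own next event, which keeps every event
O(depth * k) and the whole sweep O(N + E log N) per column.
"""

import numba
import numpy as np

__all__ = ["matvec_sweep", "simulate_sweep"]


@numba.njit(cache=True)
def _settle_path(pos, u0, parent, times, w, pi, off, x, stack, update_w):
    """Finalize branch areas and absorb rain along the path u0 -> root.

    Returns the path depth.  ``update_w`` distinguishes the matvec sweep
    (True) from the effect-simulation sweep, which carries no weights.
    """
    depth = 0
    u = u0
    while u != -1:
        stack[depth] = u
        depth += 1
        u = parent[u]
    # accrue pending sub-edge areas (weights still pre-event)
    for i in range(depth):
        u = stack[i]
        q = parent[u]
        if q != -1:
            c = (pos - x[u]) * (times[q] - times[u])
            if update_w:
                for j in range(w.shape[1]):
                    pi[u, j] += c * w[u, j]
            x[u] = pos
    # absorb rain top-down along the path
    for i in range(depth - 2, -1, -1):
        cu = stack[i]
        pu = stack[i + 1]
        for j in range(pi.shape[1]):
            pi[cu, j] += pi[pu, j] - off[cu, j]
            off[cu, j] = pi[pu, j]
    return depth


@numba.njit(cache=True)
def matvec_sweep(
    num_nodes,
    times,
    edges_left,
    edges_right,
    edges_parent,
    edges_child,
    insertion_order,
    removal_order,
    sequence_length,
    W,
    time_desc_order,
):
    """Exact branch-GRM product at sample-node level: returns B_hap @ W.

    ``W`` is (num_nodes, k) with input weights on sample nodes (zero
    elsewhere); the result lives on sample nodes as well.
    """
    k = W.shape[1]
    parent = np.full(num_nodes, -1, dtype=np.int64)
    w = W.copy()
    pi = np.zeros((num_nodes, k))
    off = np.zeros((num_nodes, k))
    x = np.zeros(num_nodes)
    stack = np.empty(num_nodes, dtype=np.int64)

    n_edges = edges_left.shape[0]
    a = 0  # removal pointer
    b = 0  # insertion pointer
    pos = 0.0
    while b < n_edges or a < n_edges:
        while a < n_edges and edges_right[removal_order[a]] == pos:
            e = removal_order[a]
            p = edges_parent[e]
            c = edges_child[e]
            depth = _settle_path(pos, c, parent, times, w, pi, off, x, stack, True)
            parent[c] = -1
            for i in range(1, depth):
                u = stack[i]
                for j in range(k):
                    w[u, j] -= w[c, j]
            a += 1
        while b < n_edges and edges_left[insertion_order[b]] == pos:
            e = insertion_order[b]
            p = edges_parent[e]
            c = edges_child[e]
            _settle_path(pos, p, parent, times, w, pi, off, x, stack, True)
            parent[c] = p
            for j in range(k):
                off[c, j] = pi[p, j]
            x[c] = pos
            u = p
            while u != -1:
                for j in range(k):
                    w[u, j] += w[c, j]
                u = parent[u]
            b += 1
        # advance to the next breakpoint
        nxt = sequence_length
        if a < n_edges and edges_right[removal_order[a]] < nxt:
            nxt = edges_right[removal_order[a]]
        if b < n_edges and edges_left[insertion_order[b]] < nxt:
            nxt = edges_left[insertion_order[b]]
        if nxt == pos:
            break
        pos = nxt
    # finalize at the right-hand end of the genome
    for u in range(num_nodes):
        q = parent[u]
        if q != -1:
            c = (sequence_length - x[u]) * (times[q] - times[u])
            for j in range(k):
                pi[u, j] += c * w[u, j]
    for i in range(num_nodes):
        u = time_desc_order[i]
        q = parent[u]
        if q != -1:
            for j in range(k):
                pi[u, j] += pi[q, j] - off[u, j]
    return pi


@numba.njit(cache=True)
def simulate_sweep(
    num_nodes,
    times,
    edges_left,
    edges_right,
    edges_parent,
    edges_child,
    insertion_order,
    removal_order,
    sequence_length,
    tau2,
    k,
    seed,
    time_desc_order,
):
    """Additive genetic values on the ARG ("Algorithm T" shape).

    Draws an independent Gaussian effect with variance ``tau2 * area``
    for every settled sub-edge fragment and pushes effects down to the
    samples with the same rain machinery as the matvec sweep; the
    returned (num_nodes, k) array holds k independent replicates of
    genetic values on sample nodes, with covariance ``tau2 * B_hap``.
    """
    np.random.seed(seed)
    parent = np.full(num_nodes, -1, dtype=np.int64)
    pi = np.zeros((num_nodes, k))
    off = np.zeros((num_nodes, k))
    x = np.zeros(num_nodes)
    stack = np.empty(num_nodes, dtype=np.int64)

    n_edges = edges_left.shape[0]
    a = 0
    b = 0
    pos = 0.0
    while b < n_edges or a < n_edges:
        while a < n_edges and edges_right[removal_order[a]] == pos:
            e = removal_order[a]
            c = edges_child[e]
            _draw_path(pos, c, parent, times, pi, off, x, stack, tau2, k)
            parent[c] = -1
            a += 1
        while b < n_edges and edges_left[insertion_order[b]] == pos:
            e = insertion_order[b]
            p = edges_parent[e]
            c = edges_child[e]
            _draw_path(pos, p, parent, times, pi, off, x, stack, tau2, k)
            parent[c] = p
            for j in range(k):
                off[c, j] = pi[p, j]
            x[c] = pos
            b += 1
        nxt = sequence_length
        if a < n_edges and edges_right[removal_order[a]] < nxt:
            nxt = edges_right[removal_order[a]]
        if b < n_edges and edges_left[insertion_order[b]] < nxt:
            nxt = edges_left[insertion_order[b]]
        if nxt == pos:
            break
        pos = nxt
    for u in range(num_nodes):
        q = parent[u]
        if q != -1:
            v = tau2 * (sequence_length - x[u]) * (times[q] - times[u])
            if v > 0:
                s = np.sqrt(v)
                for j in range(k):
                    pi[u, j] += s * np.random.normal()
    for i in range(num_nodes):
        u = time_desc_order[i]
        q = parent[u]
        if q != -1:
            for j in range(k):
                pi[u, j] += pi[q, j] - off[u, j]
    return pi


@numba.njit(cache=True)
def _draw_path(pos, u0, parent, times, pi, off, x, stack, tau2, k):
    depth = 0
    u = u0
    while u != -1:
        stack[depth] = u
        depth += 1
        u = parent[u]
    for i in range(depth):
        u = stack[i]
        q = parent[u]
        if q != -1:
            v = tau2 * (pos - x[u]) * (times[q] - times[u])
            if v > 0:
                s = np.sqrt(v)
                for j in range(k):
                    pi[u, j] += s * np.random.normal()
            x[u] = pos
    for i in range(depth - 2, -1, -1):
        cu = stack[i]
        pu = stack[i + 1]
        for j in range(k):
            pi[cu, j] += pi[pu, j] - off[cu, j]
            off[cu, j] = pi[pu, j]
    return depth
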