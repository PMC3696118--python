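"""Connectivity-preserving double-edge-swap kernel (numba).

Degree-preserving topology randomization: repeatedly pick two edges
(a, b), (c, d) and rewire them to (a, d), (c, b), rejecting any swap that
would create a self-loop or duplicate edge.  Connectivity is enforced with
an adaptive check window: swaps are applied in batches, a BFS verifies the
graph is still connected at the end of each batch, and a failing batch is
rolled back entirely (window shrinks to 1, so hard cases degrade to a BFS
per swap).  The committed graph therefore always has the input's exact
degree sequence and is simple and connected.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_WINDOW = 64


@njit(cache=True)
def _connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    visited = np.zeros(n, dtype=np.uint8)
    queue = np.empty(n, dtype=np.int64)
    queue[0] = 0
    visited[0] = 1
    head = 0
    tail = 1
    while head < tail:
        u = queue[head]
        head += 1
        for v in range(n):
            if adj[u, v] == 1 and visited[v] == 0:
                visited[v] = 1
                queue[tail] = v
                tail += 1
    return tail == n


@njit(cache=True)
def _revert(adj: np.ndarray, edges: np.ndarray, log: np.ndarray, k: int) -> None:
    # roll back the last k logged swaps, newest first
    for t in range(k - 1, -1, -1):
        e1 = log[t, 0]
        e2 = log[t, 1]
        a = log[t, 2]
        b = log[t, 3]
        c = log[t, 4]
        d = log[t, 5]
        adj[a, d] = 0
        adj[d, a] = 0
        adj[c, b] = 0
        adj[b, c] = 0
        adj[a, b] = 1
        adj[b, a] = 1
        adj[c, d] = 1
        adj[d, c] = 1
        edges[e1, 0] = a
        edges[e1, 1] = b
        edges[e2, 0] = c
        edges[e2, 1] = d


@njit(cache=True)
def rewire_connected(
    adj: np.ndarray,
    edges: np.ndarray,
    n_target_swaps: int,
    max_attempts: int,
    seed: int,
    check_connectivity: bool = True,
) -> int:
    """Rewire in place; returns the number of committed swaps.

    ``adj`` is a symmetric uint8 adjacency matrix, ``edges`` an (E, 2) int64
    array of its edges; both are mutated to the rewired state.  With
    ``check_connectivity=False`` swaps are only constrained to keep the
    graph simple (used for inputs that are already fragmented).
    """
    np.random.seed(seed)
    E = edges.shape[0]
    committed = 0
    attempts = 0
    window = 1
    in_window = 0
    log = np.empty((_MAX_WINDOW, 6), dtype=np.int64)
    while committed + in_window < n_target_swaps and attempts < max_attempts:
        attempts += 1
        e1 = np.random.randint(E)
        e2 = np.random.randint(E)
        if e1 == e2:
            continue
        a = edges[e1, 0]
        b = edges[e1, 1]
        c = edges[e2, 0]
        d = edges[e2, 1]
        if np.random.randint(2) == 1:
            tmp = c
            c = d
            d = tmp
        # proposed new edges: (a, d) and (c, b)
        if a == d or c == b or a == c or b == d:
            continue
        if adj[a, d] == 1 or adj[c, b] == 1:
            continue
        adj[a, b] = 0
        adj[b, a] = 0
        adj[c, d] = 0
        adj[d, c] = 0
        adj[a, d] = 1
        adj[d, a] = 1
        adj[c, b] = 1
        adj[b, c] = 1
        log[in_window, 0] = e1
        log[in_window, 1] = e2
        log[in_window, 2] = a
        log[in_window, 3] = b
        log[in_window, 4] = c
        log[in_window, 5] = d
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        in_window += 1
        if in_window >= window or committed + in_window >= n_target_swaps:
            if not check_connectivity or _connected(adj):
                committed += in_window
                window = min(window * 2, _MAX_WINDOW)
            else:
                _revert(adj, edges, log, in_window)
                window = 1
            in_window = 0
    if in_window > 0:  # attempt cap hit mid-window
        if not check_connectivity or _connected(adj):
            committed += in_window
        else:
            _revert(adj, edges, log, in_window)
    return committed
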