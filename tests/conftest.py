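"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: clustering
is counted by enumerating neighbour pairs, path lengths come from a plain
BFS, so they can arbitrate the vectorized implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swnull

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# --------------------------------------------------------------------------
# oracles


def brute_clustering(adj: np.ndarray) -> float:
    """Mean local clustering by explicit neighbour-pair enumeration."""
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        vals.append(links / (k * (k - 1) / 2))
    return float(np.mean(vals))


def brute_path_length(adj: np.ndarray) -> tuple[float, int]:
    """Mean shortest-path length over connected pairs via BFS; also the
    number of disconnected (excluded) pairs."""
    n = adj.shape[0]
    total = 0
    count = 0
    excluded = 0
    for s in range(n):
        dist = [-1] * n
        dist[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for v in range(n):
                if adj[u, v] and dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
        for t in range(s + 1, n):
            if dist[t] > 0:
                total += dist[t]
                count += 1
            elif dist[t] < 0:
                excluded += 1
    return total / count, excluded


def random_connected_adjacency(rng: np.random.Generator, n: int,
                               extra_edge_p: float = 0.15) -> np.ndarray:
    """Random connected simple graph: random spanning tree + extra edges."""
    adj = np.zeros((n, n), dtype=np.uint8)
    perm = rng.permutation(n)
    for k in range(1, n):
        a = perm[k]
        b = perm[rng.integers(0, k)]
        adj[a, b] = adj[b, a] = 1
    iu, ju = np.triu_indices(n, k=1)
    add = rng.random(iu.size) < extra_edge_p
    adj[iu[add], ju[add]] = 1
    adj[ju[add], iu[add]] = 1
    return adj


def make_network(adj: np.ndarray) -> swnull.BinaryNetwork:
    n = adj.shape[0]
    n_pairs = n * (n - 1) // 2
    return swnull.BinaryNetwork(
        adjacency=adj, density=adj.sum() / 2 / n_pairs,
        threshold_kind="density", threshold_value=np.nan,
    )


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_config() -> swnull.SimulationConfig:
    return swnull.SimulationConfig()


@pytest.fixture(scope="session")
def small_config() -> swnull.SimulationConfig:
    """Reduced-size configuration for fast resampling tests."""
    return swnull.SimulationConfig(
        n_subjects_per_group=(15, 15), n_regions=40, n_blocks=4, seed=7,
    )
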