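"""Binary graph metrics: clustering, path length, small-world parameters.

Clustering coefficient C (segregation) and characteristic path length L
(integration) are the two ingredients of the small-world index
SW = (C/C_null) / (L/L_null), where C_null and L_null are ensemble means
over null networks.  A network is called small-world when C/C_null > 1
while L/L_null stays near 1.

Null networks from covariance- or data-randomizing models can fragment, so
L is defined here over connected node pairs only (infinite distances are
excluded and counted); this keeps ensemble means finite at the cost of a
slight downward bias for fragmented graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

if TYPE_CHECKING:  # pragma: no cover
    from .nullmodels import NullEnsemble

__all__ = [
    "SmallWorldParams",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_world_params",
    "degree_skewness",
]


def _adj(G) -> np.ndarray:
    A = getattr(G, "adjacency", G)
    return np.asarray(A)


@dataclass(frozen=True)
class SmallWorldParams:
    """Raw and normalized small-world parameters at one density.

    gamma = C / C_null, lam = L / L_null, sigma_sw = gamma / lam.
    """

    C: float
    L: float
    gamma: float
    lam: float
    sigma_sw: float
    model: str
    density: float


def clustering_coefficient(G) -> float:
    """Mean local clustering coefficient of a simple binary graph.

    Per node: existing edges among its neighbours divided by the number of
    possible ones, deg(deg-1)/2.  Nodes of degree < 2 contribute 0.
    """
    A = _adj(G).astype(np.float64)
    if A.size == 0 or A.sum() == 0:
        raise ValueError("clustering coefficient undefined for an empty graph")
    k = A.sum(axis=0)
    # diag(A^3)/2 counts triangles through each node
    triangles = np.einsum("ij,ji->i", A @ A, A) / 2.0
    denom = k * (k - 1) / 2.0
    local = np.zeros_like(k)
    mask = k >= 2
    local[mask] = triangles[mask] / denom[mask]
    return float(local.mean())


def characteristic_path_length(G, return_excluded: bool = False):
    """Mean shortest-path length over connected node pairs.

    Disconnected (infinite-distance) pairs are excluded from the mean and
    their count is available via ``return_excluded=True``.
    """
    A = _adj(G)
    n = A.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    if A.sum() == 0:
        raise ValueError("path length undefined for a graph with no edges")
    D = shortest_path(csr_matrix(A), method="D", unweighted=True, directed=False)
    iu, ju = np.triu_indices(n, k=1)
    d = D[iu, ju]
    finite = np.isfinite(d)
    n_excluded = int((~finite).sum())
    L = float(d[finite].mean())
    if return_excluded:
        return L, n_excluded
    return L


def small_world_params(G, ensemble: "NullEnsemble") -> SmallWorldParams:
    """Normalize C and L of ``G`` by a null ensemble's means.

    gamma = C/C_null_mean, lam = L/L_null_mean, sigma_sw = gamma/lam.
    """
    C = clustering_coefficient(G)
    L = characteristic_path_length(G)
    if ensemble.C_null_mean == 0 or ensemble.L_null_mean == 0:
        raise ValueError("null ensemble has zero mean C or L; cannot normalize")
    gamma = C / ensemble.C_null_mean
    lam = L / ensemble.L_null_mean
    return SmallWorldParams(
        C=C,
        L=L,
        gamma=gamma,
        lam=lam,
        sigma_sw=gamma / lam,
        model=ensemble.model,
        density=float(getattr(G, "density", np.nan)),
    )


def degree_skewness(G) -> float:
    """Fisher-Pearson moment skewness g1 of the degree sequence.

    Positive g1 means a right tail of high-degree nodes.  Regular graphs
    (zero degree variance) return 0 with a warning, since skewness is then
    undefined.
    """
    k = _adj(G).sum(axis=0).astype(np.float64)
    if k.size < 3:
        raise ValueError("degree skewness needs at least 3 nodes")
    dev = k - k.mean()
    m2 = np.mean(dev**2)
    if m2 == 0:
        warnings.warn("regular graph: degree skewness undefined, returning 0",
                      stacklevel=2)
        return 0.0
    m3 = np.mean(dev**3)
    return float(m3 / m2**1.5)
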