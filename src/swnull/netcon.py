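"""Association matrices, density/correlation thresholding, and D_min.

An association matrix is the region x region Pearson correlation of the
corrected regional volumes across subjects.  Binary networks are obtained
either by keeping the E strongest (most positive) correlations needed to
reach a target edge density, or by an absolute correlation cutoff.  Groups
are compared at fixed densities so that differences in correlation scale do
not translate into different edge counts.

Edges are ranked by signed correlation (largest positive first) with a
deterministic tie-break, which makes edge sets nested across densities:
the network at a lower density is always a subgraph of the network at a
higher density from the same matrix.  D_min is the smallest grid density at
which every group's network is connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AssociationMatrix",
    "DensityGrid",
    "BinaryNetwork",
    "association_matrix",
    "threshold_by_density",
    "threshold_by_correlation",
    "minimum_connected_density",
    "edge_order",
    "adjacency_over_grid",
]

_SYM_TOL = 1e-12
_PSD_TOL = -1e-8


@dataclass
class AssociationMatrix:
    """Region x region Pearson correlation matrix and its covariance twin.

    ``r`` is symmetric with unit diagonal; ``cov`` is the corresponding
    covariance matrix (needed by the HQS null model, which matches moments
    of the covariance rather than the correlation).
    """

    r: np.ndarray
    cov: np.ndarray
    n_subjects: int
    region_names: list[str]

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.r.shape != self.cov.shape or self.r.ndim != 2:
            raise ValueError("r and cov must be square matrices of equal shape")
        if not np.allclose(self.r, self.r.T, atol=_SYM_TOL):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        min_eig = float(np.linalg.eigvalsh(self.cov)[0])
        if min_eig < _PSD_TOL * max(1.0, float(np.abs(self.cov).max())):
            raise ValueError(
                f"covariance matrix is not PSD (smallest eigenvalue {min_eig:.3e})"
            )

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]


def _default_windows() -> list[tuple[float, float]]:
    return [(0.22, 0.30), (0.30, 0.38), (0.38, 0.46), (0.46, 0.50)]


@dataclass(frozen=True)
class DensityGrid:
    """Evenly spaced density grid with analysis sub-windows.

    Defaults cover [0.22, 0.50] in steps of 0.02 — from the typical minimum
    connected density of group covariance networks up to the density above
    which thresholded correlation networks become near-random — with four
    windows separating strong-correlation from weak-correlation regimes.
    """

    start: float = 0.22
    step: float = 0.02
    stop: float = 0.50
    windows: list[tuple[float, float]] = field(default_factory=_default_windows)

    def __post_init__(self) -> None:
        if not (0.0 < self.start <= self.stop <= 1.0):
            raise ValueError("need 0 < start <= stop <= 1")
        if self.step <= 0:
            raise ValueError("step must be positive")
        eps = 1e-9
        for lo, hi in self.windows:
            if lo < self.start - eps or hi > self.stop + eps or lo > hi:
                raise ValueError(f"window ({lo}, {hi}) not inside [{self.start}, {self.stop}]")

    @property
    def densities(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return np.round(self.start + self.step * np.arange(n), 10)

    def window_mask(self, window: tuple[float, float] | None) -> np.ndarray:
        d = self.densities
        if window is None:
            return np.ones_like(d, dtype=bool)
        lo, hi = window
        return (d >= lo - 1e-9) & (d <= hi + 1e-9)


@dataclass
class BinaryNetwork:
    """Thresholded simple undirected graph with provenance.

    ``adjacency`` is a symmetric 0/1 matrix with zero diagonal.  ``density``
    records the achieved edge fraction, which can differ from a requested
    density by at most one edge of quantization.
    """

    adjacency: np.ndarray
    density: float
    threshold_kind: str  # "density" | "correlation"
    threshold_value: float
    provenance: str = "empirical"  # empirical | TOP | HQS | COR
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = A.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)

    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        n_comp, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n_comp == 1

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju] == 1
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def association_matrix(data) -> AssociationMatrix:
    """Pearson correlation (and covariance) of regions across subjects.

    ``data`` is anything with ``values`` (subject x region), ``region_names``
    — a :class:`MorphometryDataset` or :class:`CorrectedRGV` — or a bare
    2-D array.
    """
    values = np.asarray(getattr(data, "values", data), dtype=float)
    region_names = list(
        getattr(data, "region_names", [f"R{i + 1:03d}" for i in range(values.shape[1])])
    )
    if values.ndim != 2 or values.shape[0] < 3:
        raise ValueError("need a subject x region matrix with at least 3 subjects")
    sd = values.std(axis=0)
    if np.any(sd == 0):
        bad = [region_names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {bad}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    cov = np.cov(values, rowvar=False)
    return AssociationMatrix(
        r=r, cov=cov, n_subjects=values.shape[0], region_names=region_names
    )


def edge_order(r: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by descending correlation.

    Ties are broken deterministically by node-index pair (lexicographic), so
    thresholding is reproducible and edge sets are nested across densities.
    Returns ``(i, j, r_sorted)``.
    """
    r = np.asarray(r, dtype=float)
    iu, ju = np.triu_indices(r.shape[0], k=1)
    vals = r[iu, ju]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order], vals[order]


def _edge_count(d: float, n_pairs: int) -> int:
    # round-half-away-from-zero on the requested edge count
    return int(np.floor(d * n_pairs + 0.5))


def _mat(A) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(A, AssociationMatrix):
        return A.r, A.region_names
    return np.asarray(A, dtype=float), None


def threshold_by_density(A, d: float, provenance: str = "empirical") -> BinaryNetwork:
    """Binary network keeping the E = round(d * n(n-1)/2) strongest edges.

    Edges are ranked by signed correlation (most positive first); negative
    correlations can only enter at densities high enough to exhaust the
    positive tail.
    """
    r, region_names = _mat(A)
    if not (0.0 < d <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = r.shape[0]
    n_pairs = n * (n - 1) // 2
    E = _edge_count(d, n_pairs)
    if E == 0:
        raise ValueError(f"density {d} yields zero edges for n={n}")
    i, j, _ = edge_order(r)
    adj = np.zeros((n, n), dtype=np.uint8)
    adj[i[:E], j[:E]] = 1
    adj |= adj.T
    return BinaryNetwork(
        adjacency=adj,
        density=E / n_pairs,
        threshold_kind="density",
        threshold_value=float(d),
        provenance=provenance,
        region_names=region_names,
    )


def threshold_by_correlation(A, r0: float, provenance: str = "empirical") -> BinaryNetwork:
    """Binary network with an edge wherever r[i, j] > r0."""
    r, region_names = _mat(A)
    if not (-1.0 < r0 < 1.0):
        raise ValueError("correlation threshold must lie in (-1, 1)")
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    adj = np.zeros((n, n), dtype=np.uint8)
    keep = r[iu, ju] > r0
    adj[iu[keep], ju[keep]] = 1
    adj |= adj.T
    n_pairs = n * (n - 1) // 2
    E = int(adj.sum()) // 2
    if E == 0:
        warnings.warn(
            f"correlation threshold {r0} leaves an empty graph", stacklevel=2
        )
    return BinaryNetwork(
        adjacency=adj,
        density=E / n_pairs,
        threshold_kind="correlation",
        threshold_value=float(r0),
        provenance=provenance,
        region_names=region_names,
    )


def adjacency_over_grid(r: np.ndarray, densities: np.ndarray):
    """Yield ``(density, adjacency)`` cumulatively along a density grid.

    Exploits nestedness: each step only adds the edges between consecutive
    edge-count cutoffs.  The yielded array is reused — callers must copy if
    they need to keep it.
    """
    r = np.asarray(r, dtype=float)
    n = r.shape[0]
    n_pairs = n * (n - 1) // 2
    i, j, _ = edge_order(r)
    adj = np.zeros((n, n), dtype=np.uint8)
    prev = 0
    for d in densities:
        E = _edge_count(float(d), n_pairs)
        if E > prev:
            adj[i[prev:E], j[prev:E]] = 1
            adj[j[prev:E], i[prev:E]] = 1
            prev = E
        yield float(d), adj


def minimum_connected_density(matrices, grid: DensityGrid) -> float:
    """Smallest grid density at which every matrix's network is connected.

    This is D_min, the lower bound of the analysis range: below it at least
    one group's network fragments and size-dependent metrics stop being
    comparable.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one association matrix")
    rs = [_mat(A)[0] for A in matrices]
    densities = grid.densities
    n_components = np.zeros(len(rs), dtype=int)
    gens = [adjacency_over_grid(r, densities) for r in rs]
    for k, d in enumerate(densities):
        all_connected = True
        for idx, g in enumerate(gens):
            _, adj = next(g)
            n_comp, _ = connected_components(csr_matrix(adj), directed=False)
            n_components[idx] = n_comp
            if n_comp > 1:
                all_connected = False
        if all_connected:
            return float(d)
    worst = int(np.argmax(n_components))
    raise ValueError(
        "no grid density connects all networks; most fragmented matrix is "
        f"index {worst} with {n_components[worst]} components at density "
        f"{densities[-1]}"
    )
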