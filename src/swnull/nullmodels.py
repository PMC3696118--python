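"""Null-network families for benchmarking correlation networks.

Three nulls, differing in what structure they destroy and what they keep:

* **TOP** — topology randomization: connected, simple, degree-preserving
  double-edge-swap rewiring of the thresholded network.  Destroys all
  correlation-induced structure, including the transitive clustering that
  any correlation network carries, and therefore yields the most liberal
  normalized clustering.
* **HQS** — a random covariance matrix moment-matched to the observed one
  (Hirschberger-Qi-Steuer construction), converted to a correlation matrix
  and thresholded at the matched density.  Keeps correlation transitivity,
  so its clustering is inherently elevated and the normalized clustering of
  the empirical network comes out more conservative.
* **COR** — each subject's regional values are independently permuted, the
  Pearson matrix recomputed, and thresholded at the matched density.
  Destroys the region-level covariance structure while preserving each
  subject's value multiset.

TOP outputs are connected by construction; HQS and COR networks may
fragment, which the ensemble machinery flags and can optionally discard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._rewire import rewire_connected
from .metrics import characteristic_path_length, clustering_coefficient
from .netcon import AssociationMatrix, BinaryNetwork, threshold_by_density
from .preprocess import CorrectedRGV

__all__ = [
    "HQSMoments",
    "NullEnsemble",
    "hqs_moments",
    "top_null",
    "hqs_null_covariance",
    "hqs_null_network",
    "cor_null",
    "cor_null_correlation",
    "null_ensemble",
]


@dataclass(frozen=True)
class HQSMoments:
    """Constants of the HQS random-covariance construction.

    From the observed covariance: ``dbar`` mean diagonal entry, ``e`` mean
    off-diagonal entry, ``v`` (population) variance of off-diagonal entries.
    A draw is C = B Bᵀ with B an n x m_f matrix of i.i.d. Normal(mu, sigma²)
    entries, where

        m_f    = max(2, round((dbar² - e²) / v))
        mu     = sqrt(e / m_f)
        sigma² = sqrt(mu⁴ + v / m_f) - mu²

    which matches E[C_ij] = e, Var[C_ij] = v (i != j) and E[C_ii] ≈ dbar.
    """

    dbar: float
    e: float
    v: float
    m_f: int
    mu: float
    sigma: float


def hqs_moments(cov: np.ndarray) -> HQSMoments:
    """Derive the HQS construction constants from a covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    off = cov[iu, ju]
    dbar = float(np.mean(np.diag(cov)))
    e = float(np.mean(off))
    v = float(np.var(off))
    if e <= 0:
        raise ValueError("HQS undefined for non-positive mean covariance")
    if v <= 1e-12 * max(dbar, e) ** 2:  # exact-constant off-diagonal, up to float noise
        raise ValueError("HQS undefined for zero off-diagonal covariance variance")
    m_f = max(2, int(np.floor((dbar**2 - e**2) / v + 0.5)))
    mu = np.sqrt(e / m_f)
    sigma2 = np.sqrt(mu**4 + v / m_f) - mu**2
    return HQSMoments(dbar=dbar, e=e, v=v, m_f=m_f, mu=float(mu),
                      sigma=float(np.sqrt(max(sigma2, 0.0))))


@dataclass
class NullEnsemble:
    """A set of null networks with ensemble-mean C and L.

    ``C_null_mean`` / ``L_null_mean`` are the arithmetic means used to
    normalize the empirical metrics; ``n_fragmented`` counts disconnected
    members (always 0 for TOP).
    """

    model: str
    members: list[BinaryNetwork]
    C_null_values: np.ndarray
    L_null_values: np.ndarray
    n_fragmented: int
    seed: int
    fragment_policy: str = "keep"
    density: float | None = None

    @property
    def m(self) -> int:
        return len(self.members)

    @property
    def C_null_mean(self) -> float:
        return float(np.mean(self.C_null_values))

    @property
    def L_null_mean(self) -> float:
        return float(np.mean(self.L_null_values))


def top_null(
    G: BinaryNetwork, seed: int, swaps_per_edge: int = 10,
    allow_fragmented: bool = False,
) -> BinaryNetwork:
    """Connected degree-preserving rewiring of a binary network.

    Attempts ``swaps_per_edge * E`` accepted double-edge swaps; swaps that
    would break simplicity are rejected and swaps that would disconnect the
    graph are reverted.  A graph with no rewirable edge pair (e.g. a
    complete graph) is returned unchanged with a warning.

    A fragmented input (which bootstrap networks at the minimum density can
    be) cannot be rewired under a connectivity constraint; by default this
    raises, but ``allow_fragmented=True`` falls back to plain
    degree-preserving swaps with a warning, leaving the component structure
    unconstrained.
    """
    connected = G.is_connected()
    if not connected and not allow_fragmented:
        raise ValueError("TOP rewiring requires a connected input network")
    if not connected:
        warnings.warn(
            "input network is fragmented; rewiring without the "
            "connectivity constraint", stacklevel=2)
    n = G.n_nodes
    E = G.n_edges
    if E == n * (n - 1) // 2:
        warnings.warn("complete graph has no rewirable edge pair; returned unchanged",
                      stacklevel=2)
        return BinaryNetwork(
            adjacency=G.adjacency.copy(),
            density=G.density,
            threshold_kind=G.threshold_kind,
            threshold_value=G.threshold_value,
            provenance="TOP",
            region_names=G.region_names,
        )
    adj = np.ascontiguousarray(G.adjacency.copy())
    edges = np.array(G.edge_list(), dtype=np.int64)
    target = swaps_per_edge * E
    max_attempts = max(100 * target, 1000)
    accepted = rewire_connected(adj, edges, target, max_attempts,
                                int(seed) % (2**31 - 1),
                                check_connectivity=connected)
    if accepted < target:
        warnings.warn(
            f"rewiring achieved {accepted}/{target} swaps before the attempt cap",
            stacklevel=2,
        )
    return BinaryNetwork(
        adjacency=adj,
        density=G.density,
        threshold_kind=G.threshold_kind,
        threshold_value=G.threshold_value,
        provenance="TOP",
        region_names=G.region_names,
    )


def hqs_null_covariance(A: AssociationMatrix | np.ndarray, seed) -> np.ndarray:
    """One random covariance draw moment-matched to the observed covariance.

    ``seed`` may be an int or a ``numpy.random.Generator``.  The draw is a
    Gram matrix, hence PSD by construction.
    """
    cov = A.cov if isinstance(A, AssociationMatrix) else np.asarray(A, dtype=float)
    mom = hqs_moments(cov)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = rng.normal(mom.mu, mom.sigma, size=(cov.shape[0], mom.m_f))
    return B @ B.T


def _cov_to_corr(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    r = C / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def hqs_null_network(
    A: AssociationMatrix, d: float, seed, region_names=None
) -> BinaryNetwork:
    """HQS covariance draw -> correlation matrix -> density-matched network.

    Connectedness is not guaranteed; callers should check ``is_connected``.
    """
    C = hqs_null_covariance(A, seed)
    net = threshold_by_density(_cov_to_corr(C), d, provenance="HQS")
    net.region_names = region_names or (
        A.region_names if isinstance(A, AssociationMatrix) else None
    )
    return net


def cor_null_correlation(
    data: CorrectedRGV | np.ndarray, seed, return_permuted: bool = False
):
    """Correlation matrix of subject-wise permuted data.

    Each subject's row of regional values is independently permuted (the
    multiset per subject is preserved), then the region x region Pearson
    matrix is recomputed across subjects.  With ``return_permuted=True`` the
    permuted data matrix is returned alongside.
    """
    values = np.asarray(getattr(data, "values", data), dtype=float)
    if values.shape[0] < 3:
        raise ValueError("COR null needs at least 3 subjects")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    permuted = np.empty_like(values)
    for s in range(values.shape[0]):
        permuted[s] = values[s, rng.permutation(values.shape[1])]
    r = np.corrcoef(permuted, rowvar=False)
    np.fill_diagonal(r, 1.0)
    if return_permuted:
        return r, permuted
    return r


def cor_null(data: CorrectedRGV | np.ndarray, d: float, seed) -> BinaryNetwork:
    """Density-matched network from the correlation of permuted data."""
    r = cor_null_correlation(data, seed)
    net = threshold_by_density(r, d, provenance="COR")
    net.region_names = list(getattr(data, "region_names", [])) or None
    return net


_MAX_REDRAW_FACTOR = 20


def null_ensemble(
    target,
    model: str,
    m: int = 20,
    seed: int = 0,
    fragment_policy: str = "keep",
    density: float | None = None,
    swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Generate an ensemble of m null networks and its mean C and L.

    Parameters
    ----------
    target :
        ``BinaryNetwork`` for model "TOP"; ``AssociationMatrix`` (plus
        ``density``) for "HQS"; ``CorrectedRGV`` or subject x region array
        (plus ``density``) for "COR".
    model : {"TOP", "HQS", "COR"}
    m : int
        Ensemble size (default 20).
    fragment_policy : {"keep", "discard", "error"}
        How to treat disconnected members: keep them (L over connected
        pairs only), redraw with a bounded retry budget, or raise.
    """
    if m < 1:
        raise ValueError("ensemble size m must be >= 1")
    if fragment_policy not in ("keep", "discard", "error"):
        raise ValueError(f"unknown fragment_policy {fragment_policy!r}")
    model = model.upper()
    if model == "TOP":
        if not isinstance(target, BinaryNetwork):
            raise TypeError("TOP ensemble needs a BinaryNetwork target")
        density = target.density
    elif model in ("HQS", "COR"):
        if density is None:
            raise ValueError(f"{model} ensemble needs an explicit density")
    else:
        raise ValueError(f"unknown null model {model!r}")

    child_seeds = np.random.SeedSequence(seed).generate_state(
        _MAX_REDRAW_FACTOR * m
    ) % (2**31 - 1)

    def _draw(k: int) -> BinaryNetwork:
        s = int(child_seeds[k])
        if model == "TOP":
            return top_null(target, seed=s, swaps_per_edge=swaps_per_edge,
                            allow_fragmented=True)
        if model == "HQS":
            return hqs_null_network(target, density, seed=s)
        return cor_null(target, density, seed=s)

    members: list[BinaryNetwork] = []
    n_fragmented = 0
    k = 0
    while len(members) < m:
        if k >= _MAX_REDRAW_FACTOR * m:
            raise RuntimeError(
                f"{model} ensemble: retry budget exhausted under "
                f"fragment_policy='discard' (fragmentation rate "
                f"{n_fragmented / k:.2f})"
            )
        net = _draw(k)
        k += 1
        connected = net.is_connected()
        if not connected:
            if fragment_policy == "error":
                raise RuntimeError(f"{model} null network is fragmented")
            if fragment_policy == "discard":
                n_fragmented += 1
                continue
            n_fragmented += 1
        members.append(net)

    C_vals = np.array([clustering_coefficient(g) for g in members])
    L_vals = np.array([characteristic_path_length(g) for g in members])
    return NullEnsemble(
        model=model,
        members=members,
        C_null_values=C_vals,
        L_null_values=L_vals,
        n_fragmented=n_fragmented,
        seed=int(seed),
        fragment_policy=fragment_policy,
        density=float(density) if density is not None else None,
    )
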