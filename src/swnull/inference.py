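"""Curve statistics and resampling inference.

Every network metric, evaluated over the density grid, becomes a curve
y = f(density).  Two curves are compared by the functional-data-analysis
(FDA) area statistic

    A = sum_i |y2(x_i) - y1(x_i)|

optionally restricted to a density window.  The signed sum is reported
alongside so the direction of a difference is preserved.

Two resampling tests are built on A:

* **dependent-sample test** (between null models, within one group): metric
  curves are computed for every bootstrap resample of the subjects under
  both null models; the observed statistic is the area between the two
  models' mean curves, and the null distribution is obtained by randomly
  swapping the model labels within each bootstrap sample.
* **independent-sample test** (between groups): subjects are permuted
  between pseudo-groups of the original sizes, association matrices and
  metric curves are rebuilt per permutation, and the area between group
  curves forms the null distribution.

p-values use the add-one convention (count >= observed + 1)/(n_perm + 1),
so p is in (0, 1] and never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import (
    characteristic_path_length,
    clustering_coefficient,
    degree_skewness,
)
from .netcon import (
    AssociationMatrix,
    DensityGrid,
    adjacency_over_grid,
    association_matrix,
    threshold_by_density,
)
from .nullmodels import null_ensemble
from .preprocess import CorrectedRGV

__all__ = [
    "MetricCurve",
    "FDAResult",
    "fda_area",
    "bootstrap_association",
    "raw_metric_curves",
    "normalized_curves",
    "bootstrap_model_curves",
    "dependent_model_test",
    "independent_group_test",
    "replicability_analysis",
    "skewness_correlation",
    "bonferroni",
]

RAW_METRICS = ("CC", "CPL")
NORMALIZED_METRICS = ("CC_norm", "CPL_norm", "SW")


@dataclass
class MetricCurve:
    """A network metric sampled along a density grid."""

    grid: np.ndarray
    values: np.ndarray
    metric: str  # CC | CPL | SW | CC_norm | CPL_norm
    model: str = "none"  # TOP | HQS | COR | none
    group_label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have one value per grid point")
        if not np.isfinite(self.values).all():
            raise ValueError("curve contains missing values")


@dataclass
class FDAResult:
    """Outcome of an FDA-area resampling test."""

    area: float
    signed_area: float
    window: tuple[float, float] | None
    n_resamples: int
    p_value: float
    null_quantiles: dict[str, float] = field(default_factory=dict)
    seed: int | None = None
    metric: str = ""
    model: str = ""
    note: str = ""


def _curve_values(c) -> np.ndarray:
    return np.asarray(getattr(c, "values", c), dtype=float)


def _window_mask(grid: np.ndarray, window) -> np.ndarray:
    if window is None:
        return np.ones_like(grid, dtype=bool)
    lo, hi = window
    mask = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window {window} contains no grid point")
    return mask


def fda_area(c1, c2, window=None, grid=None) -> tuple[float, float]:
    """Area and signed area between two sampled curves.

    ``c1``/``c2`` are :class:`MetricCurve` or plain value arrays on a shared
    grid.  Returns ``(area, signed_area)`` with
    area = sum |y2 - y1| and signed_area = sum (y2 - y1) over the window.
    """
    y1 = _curve_values(c1)
    y2 = _curve_values(c2)
    g1 = getattr(c1, "grid", grid)
    g2 = getattr(c2, "grid", grid)
    if y1.shape != y2.shape:
        raise ValueError("curves have mismatched lengths")
    if g1 is not None and g2 is not None and not np.allclose(g1, g2):
        raise ValueError("curves are sampled on different grids")
    g = np.asarray(g1 if g1 is not None else np.arange(y1.size), dtype=float)
    mask = _window_mask(g, window)
    diff = y2[mask] - y1[mask]
    return float(np.abs(diff).sum()), float(diff.sum())


def bootstrap_association(
    data: CorrectedRGV, n_boot: int = 300, seed: int = 0
) -> list[AssociationMatrix]:
    """Bootstrap the association matrix by resampling subjects.

    Each of the ``n_boot`` samples draws subjects with replacement (same n)
    and recomputes the Pearson matrix.  Note that sampling with replacement
    duplicates subjects and therefore inflates correlations relative to the
    original matrix; comparisons *across* models on the same bootstrap
    samples are unaffected.  Draws that produce a zero-variance region are
    redrawn (bounded retries).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    values = np.asarray(data.values, dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    out: list[AssociationMatrix] = []
    retries = 0
    while len(out) < n_boot:
        idx = rng.integers(0, n, n)
        sub = values[idx]
        if np.any(sub.std(axis=0) == 0):
            retries += 1
            if retries > 10 * n_boot:
                raise RuntimeError("bootstrap redraw budget exhausted "
                                   "(persistent zero-variance region)")
            continue
        A = association_matrix(sub)
        A.region_names = list(data.region_names)
        out.append(A)
    return out


def raw_metric_curves(
    r: np.ndarray, grid: DensityGrid, metrics=RAW_METRICS
) -> dict[str, np.ndarray]:
    """CC and/or CPL of the thresholded network at every grid density."""
    densities = grid.densities
    out = {met: np.empty(densities.size) for met in metrics}
    for k, (_, adj) in enumerate(adjacency_over_grid(r, densities)):
        if "CC" in out:
            out["CC"][k] = clustering_coefficient(adj)
        if "CPL" in out:
            out["CPL"][k] = characteristic_path_length(adj)
    return out


def normalized_curves(
    assoc: AssociationMatrix,
    grid: DensityGrid,
    model: str,
    m: int = 20,
    seed: int = 0,
    data: CorrectedRGV | np.ndarray | None = None,
    swaps_per_edge: int = 10,
    fragment_policy: str = "keep",
) -> dict[str, np.ndarray]:
    """Raw and normalized metric curves for one null model.

    Returns arrays keyed "CC", "CPL", "CC_norm", "CPL_norm", "SW", plus the
    ensemble means "C_null" and "L_null" and the per-density fragmentation
    counts "n_fragmented".  ``data`` (the corrected values) is required for
    the COR model.
    """
    model = model.upper()
    if model == "COR" and data is None:
        raise ValueError("COR curves need the corrected subject x region data")
    densities = grid.densities
    seeds = np.random.SeedSequence(seed).generate_state(densities.size) % (2**31 - 1)
    out = {k: np.empty(densities.size) for k in
           ("CC", "CPL", "CC_norm", "CPL_norm", "SW", "C_null", "L_null")}
    frag = np.zeros(densities.size, dtype=int)
    for k, (d, adj) in enumerate(adjacency_over_grid(assoc.r, densities)):
        C = clustering_coefficient(adj)
        L = characteristic_path_length(adj)
        if model == "TOP":
            G = threshold_by_density(assoc, d)
            ens = null_ensemble(G, "TOP", m=m, seed=int(seeds[k]),
                                swaps_per_edge=swaps_per_edge,
                                fragment_policy=fragment_policy)
        elif model == "HQS":
            ens = null_ensemble(assoc, "HQS", m=m, seed=int(seeds[k]),
                                density=d, fragment_policy=fragment_policy)
        else:
            ens = null_ensemble(data, "COR", m=m, seed=int(seeds[k]),
                                density=d, fragment_policy=fragment_policy)
        out["CC"][k] = C
        out["CPL"][k] = L
        out["C_null"][k] = ens.C_null_mean
        out["L_null"][k] = ens.L_null_mean
        out["CC_norm"][k] = C / ens.C_null_mean
        out["CPL_norm"][k] = L / ens.L_null_mean
        out["SW"][k] = out["CC_norm"][k] / out["CPL_norm"][k]
        frag[k] = ens.n_fragmented
    out["n_fragmented"] = frag
    return out


def bootstrap_model_curves(
    data: CorrectedRGV,
    grid: DensityGrid,
    models=("TOP", "HQS", "COR"),
    n_boot: int = 300,
    m: int = 20,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> dict[str, dict[str, np.ndarray]]:
    """Normalized metric curves per bootstrap sample and null model.

    The same bootstrap samples underlie every model, which is what makes
    the dependent-sample label swap valid.  Returns
    ``{model: {metric: array (n_boot, n_densities)}}`` for the normalized
    metrics, plus key "skewness" (per-bootstrap degree skewness of the
    network at the lowest grid density) under ``"_boot"``.
    """
    ss = np.random.SeedSequence(seed)
    boots = bootstrap_association(data, n_boot=n_boot,
                                  seed=int(ss.generate_state(1)[0] % (2**31 - 1)))
    model_seeds = {mod: int(s) for mod, s in
                   zip(models, ss.generate_state(len(models) + 1)[1:] % (2**31 - 1))}
    n_d = grid.densities.size
    out: dict[str, dict[str, np.ndarray]] = {
        mod: {met: np.empty((n_boot, n_d)) for met in NORMALIZED_METRICS + RAW_METRICS}
        for mod in models
    }
    skew = np.empty(n_boot)
    for b, A in enumerate(boots):
        skew[b] = degree_skewness(threshold_by_density(A, float(grid.densities[0])))
        for mod in models:
            curves = normalized_curves(
                A, grid, mod, m=m,
                seed=(model_seeds[mod] + b) % (2**31 - 1),
                data=data if mod.upper() == "COR" else None,
                swaps_per_edge=swaps_per_edge,
            )
            for met in NORMALIZED_METRICS + RAW_METRICS:
                out[mod][met][b] = curves[met]
    out["_boot"] = {"skewness": skew}
    return out


def _null_quantiles(null: np.ndarray) -> dict[str, float]:
    qs = np.quantile(null, [0.5, 0.9, 0.95, 0.99])
    return {"q50": float(qs[0]), "q90": float(qs[1]),
            "q95": float(qs[2]), "q99": float(qs[3])}


def dependent_model_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    grid: DensityGrid | np.ndarray,
    n_perm: int = 5000,
    window: tuple[float, float] | None = None,
    seed: int = 0,
    statistic: str = "mean_curve",
) -> FDAResult:
    """Permutation test for dependent samples (two null models, one group).

    ``curves_a``/``curves_b`` are (n_boot, n_points) arrays of one metric's
    curves under the two models, computed on the *same* bootstrap samples.
    Observed statistic: FDA area between the two models' mean curves.  Null:
    the model labels are randomly swapped within each bootstrap sample and
    the area recomputed, ``n_perm`` times.

    ``statistic="per_boot_signed"`` instead uses |mean over bootstraps of
    the per-bootstrap signed area| (the absolute per-bootstrap area is
    invariant under label swaps and cannot be used).
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("curve stacks must be equal-shape (n_boot, n_points)")
    grid_values = grid.densities if isinstance(grid, DensityGrid) else np.asarray(grid)
    if grid_values.size != a.shape[1]:
        raise ValueError("grid length does not match curves")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable p-value", stacklevel=2)
    mask = _window_mask(grid_values, window)
    diff = (b - a)[:, mask]  # (n_boot, n_win)
    n_boot = diff.shape[0]
    mean_diff = diff.mean(axis=0)
    if statistic == "mean_curve":
        observed = float(np.abs(mean_diff).sum())
    elif statistic == "per_boot_signed":
        observed = float(abs(diff.sum(axis=1).mean()))
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    signed = float(mean_diff.sum())

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_boot))
    if statistic == "mean_curve":
        null_means = (signs @ diff) / n_boot  # (n_perm, n_win)
        null = np.abs(null_means).sum(axis=1)
    else:
        null = np.abs((signs * diff.sum(axis=1)).mean(axis=1))
    p = (int((null >= observed - 1e-12).sum()) + 1) / (n_perm + 1)
    return FDAResult(
        area=observed,
        signed_area=signed,
        window=window,
        n_resamples=n_perm,
        p_value=float(p),
        null_quantiles=_null_quantiles(null),
        seed=int(seed),
        note=f"dependent-sample label swap, statistic={statistic}",
    )


def _group_curve(
    values: np.ndarray,
    grid: DensityGrid,
    metric: str,
    model: str | None,
    m: int,
    seed: int,
    null_means: tuple[np.ndarray, np.ndarray] | None,
    swaps_per_edge: int,
) -> np.ndarray:
    A = association_matrix(values)
    if metric in RAW_METRICS:
        return raw_metric_curves(A.r, grid, metrics=(metric,))[metric]
    if model is None:
        raise ValueError(f"metric {metric!r} needs a null model")
    if null_means is not None:  # approximate fast mode
        raw = raw_metric_curves(A.r, grid)
        cc_n = raw["CC"] / null_means[0]
        cpl_n = raw["CPL"] / null_means[1]
        return {"CC_norm": cc_n, "CPL_norm": cpl_n, "SW": cc_n / cpl_n}[metric]
    curves = normalized_curves(A, grid, model, m=m, seed=seed, data=values,
                               swaps_per_edge=swaps_per_edge)
    return curves[metric]


def _group_perm_diffs(
    data1: CorrectedRGV,
    data2: CorrectedRGV,
    grid: DensityGrid,
    metric: str,
    model: str | None,
    n_perm: int,
    seed: int,
    m: int,
    null_mode: str,
    swaps_per_edge: int,
):
    """Observed group curves and (n_perm, n_points) permutation differences."""
    if data1.n_subjects < 3 or data2.n_subjects < 3:
        raise ValueError("each group needs at least 3 subjects")
    ids1 = getattr(data1, "subject_ids", None)
    ids2 = getattr(data2, "subject_ids", None)
    if ids1 and ids2 and set(ids1) & set(ids2):
        raise ValueError("groups must have disjoint subject sets")
    if metric not in RAW_METRICS + NORMALIZED_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives an unstable p-value", stacklevel=2)
    v1 = np.asarray(data1.values, dtype=float)
    v2 = np.asarray(data2.values, dtype=float)
    pooled = np.vstack([v1, v2])
    n1 = v1.shape[0]
    ss = np.random.SeedSequence(seed)
    base = ss.generate_state(n_perm + 3) % (2**31 - 1)

    null_means = None
    note = "independent-sample subject permutation"
    if metric in NORMALIZED_METRICS and null_mode == "reuse":
        A_pool = association_matrix(pooled)
        pool_curves = normalized_curves(A_pool, grid, model, m=m,
                                        seed=int(base[0]), data=pooled,
                                        swaps_per_edge=swaps_per_edge)
        null_means = (pool_curves["C_null"], pool_curves["L_null"])
        note = "approximate: null means reused from pooled data"

    c1 = _group_curve(v1, grid, metric, model, m, int(base[1]), null_means,
                      swaps_per_edge)
    c2 = _group_curve(v2, grid, metric, model, m, int(base[2]), null_means,
                      swaps_per_edge)
    rng = np.random.default_rng(int(base[0]) + 1)
    diffs = np.empty((n_perm, c1.size))
    for p_idx in range(n_perm):
        idx = rng.permutation(pooled.shape[0])
        s = int(base[3 + p_idx])
        pc1 = _group_curve(pooled[idx[:n1]], grid, metric, model, m, s,
                           null_means, swaps_per_edge)
        pc2 = _group_curve(pooled[idx[n1:]], grid, metric, model, m,
                           (s + 1) % (2**31 - 1), null_means, swaps_per_edge)
        diffs[p_idx] = pc2 - pc1
    return c1, c2, diffs, note


def _fda_result_from_diffs(c1, c2, diffs, grid, window, n_perm, seed, metric,
                           model, note) -> FDAResult:
    mask = _window_mask(grid.densities, window)
    observed = float(np.abs((c2 - c1)[mask]).sum())
    signed = float((c2 - c1)[mask].sum())
    null = np.abs(diffs[:, mask]).sum(axis=1)
    p = (int((null >= observed - 1e-12).sum()) + 1) / (n_perm + 1)
    return FDAResult(
        area=observed, signed_area=signed, window=window, n_resamples=n_perm,
        p_value=float(p), null_quantiles=_null_quantiles(null),
        seed=int(seed), metric=metric, model=model or "none", note=note,
    )


def independent_group_test(
    data1: CorrectedRGV,
    data2: CorrectedRGV,
    grid: DensityGrid,
    metric: str = "CC",
    model: str | None = None,
    n_perm: int = 1000,
    window: tuple[float, float] | None = None,
    seed: int = 0,
    m: int = 20,
    null_mode: str = "regenerate",
    swaps_per_edge: int = 10,
) -> FDAResult:
    """Permutation test for independent samples (between groups).

    Subjects are randomly reassigned to pseudo-groups of the original
    sizes; association matrices, thresholded networks and metric curves are
    rebuilt per permutation.  For normalized metrics, null ensembles are by
    default regenerated per permutation (``null_mode="regenerate"``,
    faithful but expensive); ``null_mode="reuse"`` normalizes all curves by
    null means computed once from the pooled data and is labeled
    approximate.
    """
    c1, c2, diffs, note = _group_perm_diffs(
        data1, data2, grid, metric, model, n_perm, seed, m, null_mode,
        swaps_per_edge)
    return _fda_result_from_diffs(c1, c2, diffs, grid, window, n_perm, seed,
                                  metric, model, note)


def independent_group_test_windows(
    data1: CorrectedRGV,
    data2: CorrectedRGV,
    grid: DensityGrid,
    metric: str = "CC",
    model: str | None = None,
    n_perm: int = 1000,
    windows=(None,),
    seed: int = 0,
    m: int = 20,
    null_mode: str = "regenerate",
    swaps_per_edge: int = 10,
) -> dict:
    """As :func:`independent_group_test`, evaluated on several windows at
    once from a single permutation pass (``None`` = cumulative)."""
    c1, c2, diffs, note = _group_perm_diffs(
        data1, data2, grid, metric, model, n_perm, seed, m, null_mode,
        swaps_per_edge)
    return {w: _fda_result_from_diffs(c1, c2, diffs, grid, w, n_perm, seed,
                                      metric, model, note)
            for w in windows}


def replicability_analysis(
    targets: dict[str, object],
    density: float,
    n_sets: int = 50,
    m: int = 20,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> dict:
    """Replicability of null ensemble means, and dispersion across models.

    ``targets`` maps model name ("TOP"/"HQS"/"COR") to the object the model
    needs (network, association matrix, corrected data).  For each model,
    ``n_sets`` ensembles of ``m`` nulls are generated at ``density`` and a
    one-way ANOVA compares per-set C_null and L_null values (set as factor).
    Across models, Levene's test compares the dispersion of the per-member
    values of one ensemble of ``m`` nulls.
    """
    if n_sets < 2 or m < 2:
        raise ValueError("need n_sets >= 2 and m >= 2")
    ss = np.random.SeedSequence(seed)
    report: dict = {"density": float(density), "n_sets": n_sets, "m": m,
                    "seed": int(seed), "models": {}}
    first_set: dict[str, dict[str, np.ndarray]] = {}
    for model, target in targets.items():
        seeds = ss.spawn(1)[0].generate_state(n_sets) % (2**31 - 1)
        C_sets, L_sets = [], []
        for s in range(n_sets):
            ens = null_ensemble(target, model, m=m, seed=int(seeds[s]),
                                density=density, swaps_per_edge=swaps_per_edge)
            C_sets.append(ens.C_null_values)
            L_sets.append(ens.L_null_values)
        first_set[model] = {"C": C_sets[0], "L": L_sets[0]}
        entry: dict = {
            "C_null_set_means": [float(np.mean(c)) for c in C_sets],
            "L_null_set_means": [float(np.mean(v)) for v in L_sets],
        }
        for name, sets in (("C", C_sets), ("L", L_sets)):
            if all(np.ptp(s) == 0 for s in sets):
                entry[f"anova_{name}"] = {"F": None, "p": None,
                                          "degenerate": True}
                continue
            F, p = stats.f_oneway(*sets)
            entry[f"anova_{name}"] = {"F": float(F), "p": float(p),
                                      "degenerate": False}
        report["models"][model] = entry
    if len(targets) >= 2:
        report["levene"] = {}
        for name in ("C", "L"):
            samples = [first_set[mod][name] for mod in targets]
            if all(np.ptp(s) == 0 for s in samples):
                report["levene"][name] = {"W": None, "p": None, "degenerate": True}
            else:
                W, p = stats.levene(*samples)
                report["levene"][name] = {"W": float(W), "p": float(p),
                                          "degenerate": False}
    return report


def skewness_correlation(skewness: np.ndarray, series: dict[str, np.ndarray]) -> dict:
    """Pearson correlation of per-network degree skewness with metric series.

    ``series`` maps a label (e.g. "CC_norm_TOP_minus_HQS" or "C_TOP_null")
    to one value per network.  A constant series (or constant skewness)
    has no defined correlation and raises.
    """
    skewness = np.asarray(skewness, dtype=float)
    if skewness.size < 10:
        raise ValueError("need at least 10 networks for the skewness analysis")
    if np.ptp(skewness) == 0:
        raise ValueError("degree skewness is constant across networks")
    out: dict = {}
    for name, vals in series.items():
        vals = np.asarray(vals, dtype=float)
        if vals.shape != skewness.shape:
            raise ValueError(f"series {name!r} length mismatch")
        if np.ptp(vals) == 0:
            raise ValueError(f"series {name!r} is constant; correlation undefined")
        r, p = stats.pearsonr(skewness, vals)
        out[name] = {"r": float(r), "p": float(p), "n": int(vals.size)}
    return out


def bonferroni(p_values: dict[str, float]) -> dict[str, float]:
    """Bonferroni-adjust a family of p-values (clipped at 1)."""
    k = len(p_values)
    return {name: min(1.0, p * k) for name, p in p_values.items()}
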