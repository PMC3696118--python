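"""End-to-end orchestration of the null-model benchmarking pipeline.

Stages: simulate (or load) two-group morphometry -> covariate correction ->
association matrices -> D_min -> normalized metric curves per null model ->
dependent-sample (between-model) tests -> independent-sample (between-group)
tests, cumulative and windowed -> replicability and skewness reports.

Every stage writes its artifacts (with embedded seeds) to the output
directory, a log records parameters and association-matrix checksums, and a
rerun with the same resolved configuration reproduces the exact same files.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as swio
from .inference import (
    NORMALIZED_METRICS,
    bonferroni,
    bootstrap_association,
    bootstrap_model_curves,
    dependent_model_test,
    independent_group_test_windows,
    normalized_curves,
    skewness_correlation,
    replicability_analysis,
)
from .metrics import clustering_coefficient
from .netcon import (
    DensityGrid,
    association_matrix,
    minimum_connected_density,
    threshold_by_density,
)
from .nullmodels import top_null
from .preprocess import correct_regional_volumes
from .simulate import SimulationConfig, generate_group_morphometry

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("swnull")

MODELS = ("TOP", "HQS", "COR")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    Either ``simulate`` holds a :class:`SimulationConfig` (synthetic mode)
    or ``values_paths``/``covariates_paths`` point at two groups' input
    tables.  Resampling sizes default to the full-scale analysis (300
    bootstraps, 5000 dependent-test shuffles, 1000 group permutations, 20
    nulls); reduced values are appropriate for demonstrations.
    """

    simulate: SimulationConfig | None = None
    values_paths: tuple[str, str] | None = None
    covariates_paths: tuple[str, str] | None = None
    covariate_names: tuple[str, ...] = ("age", "sex", "tbv")
    grid: DensityGrid = field(default_factory=DensityGrid)
    m_nulls: int = 20
    swaps_per_edge: int = 10
    fragment_policy: str = "keep"
    n_boot: int = 300
    n_perm_dependent: int = 5000
    n_perm_group: int = 1000
    n_sets_replicability: int = 50
    group_null_mode: str = "reuse"
    seed: int = 0
    models: tuple[str, ...] = MODELS
    group_labels: tuple[str, str] = ("group1", "group2")

    def resolved_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = {"start": self.grid.start, "step": self.grid.step,
                     "stop": self.grid.stop,
                     "windows": [list(w) for w in self.grid.windows]}
        if self.simulate is not None:
            d["simulate"] = asdict(self.simulate)
        return d


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _setup_logging(outdir: Path) -> list[logging.Handler]:
    handlers: list[logging.Handler] = [logging.FileHandler(outdir / "pipeline.log")]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        handlers.append(logging.StreamHandler())
    for handler in handlers:
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handlers


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle to ``outdir``.

    Returns a summary dict (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handlers = _setup_logging(outdir)
    t0 = time.time()
    try:
        return _run(config, outdir)
    finally:
        logger.info("pipeline finished in %.1f s", time.time() - t0)
        for handler in handlers:
            logger.removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    ss = np.random.SeedSequence(config.seed)
    stage_seed = {name: int(s) for name, s in zip(
        ("curves", "dependent", "group", "replicability", "skewness"),
        ss.generate_state(5) % (2**31 - 1))}
    swio.write_config(config.resolved_dict(), outdir / "resolved_config.yaml")

    # --- stage: input -----------------------------------------------------
    try:
        if config.simulate is not None:
            datasets = [generate_group_morphometry(config.simulate, g) for g in (0, 1)]
        elif config.values_paths is not None:
            cps = config.covariates_paths or (None, None)
            datasets = [swio.read_morphometry_table(v, c)
                        for v, c in zip(config.values_paths, cps)]
        else:
            raise ValueError("config needs either a simulate block or input paths")
        for label, data in zip(config.group_labels, datasets):
            swio.write_morphometry_table(
                data, outdir / f"morphometry_{label}.csv",
                outdir / f"covariates_{label}.csv")
            logger.info("input %s: %d subjects x %d regions (seed=%s)",
                        label, data.n_subjects, data.n_regions, data.seed)
    except Exception as exc:
        raise PipelineError("input", str(exc)) from exc

    # --- stage: correct ---------------------------------------------------
    try:
        cov_names = [c for c in config.covariate_names
                     if c in datasets[0].covariates.columns]
        corrected = [correct_regional_volumes(d, cov_names) for d in datasets]
    except Exception as exc:
        raise PipelineError("correct", str(exc)) from exc

    # --- stage: construct -------------------------------------------------
    try:
        assocs = [association_matrix(c) for c in corrected]
        for label, A in zip(config.group_labels, assocs):
            swio.write_association_matrix(A, outdir / f"association_{label}.csv")
            logger.info("association %s: checksum=%s", label, _checksum(A.r))
        d_min = minimum_connected_density(assocs, config.grid)
        logger.info("D_min = %.2f", d_min)
        swio.write_json_report({"d_min": d_min, "grid_start": config.grid.start},
                               outdir / "d_min.json")
        grid = config.grid
        if d_min > grid.start + 1e-9:
            windows = [(max(lo, d_min), hi) for lo, hi in grid.windows
                       if hi > d_min - 1e-9]
            grid = DensityGrid(start=d_min, step=grid.step, stop=grid.stop,
                               windows=windows)
            logger.warning("grid start raised to D_min=%.2f", d_min)
    except Exception as exc:
        raise PipelineError("construct", str(exc)) from exc

    summary: dict = {"seed": config.seed, "d_min": d_min,
                     "stage_seeds": stage_seed}

    # --- stage: curves ----------------------------------------------------
    try:
        rows = []
        group_curves: dict[str, dict[str, dict[str, np.ndarray]]] = {}
        for label, A, C in zip(config.group_labels, assocs, corrected):
            group_curves[label] = {}
            for model in config.models:
                curves = normalized_curves(
                    A, grid, model, m=config.m_nulls,
                    seed=stage_seed["curves"],
                    data=C, swaps_per_edge=config.swaps_per_edge,
                    fragment_policy=config.fragment_policy)
                group_curves[label][model] = curves
                for met in ("CC", "CPL", "CC_norm", "CPL_norm", "SW"):
                    for d, v in zip(grid.densities, curves[met]):
                        rows.append({"grid_value": d, "metric": met,
                                     "model": model, "group": label,
                                     "value": v,
                                     "seed": stage_seed["curves"]})
        swio.write_curves(pd.DataFrame(rows), outdir / "curves.csv")
    except Exception as exc:
        raise PipelineError("curves", str(exc)) from exc

    # --- stage: compare models (dependent test, group 1) ------------------
    try:
        boot = bootstrap_model_curves(
            corrected[0], grid, models=config.models, n_boot=config.n_boot,
            m=config.m_nulls, seed=stage_seed["dependent"],
            swaps_per_edge=config.swaps_per_edge)
        dep_report: dict = {"n_boot": config.n_boot,
                            "n_perm": config.n_perm_dependent,
                            "seed": stage_seed["dependent"], "tests": {}}
        raw_p: dict[str, float] = {}
        windows: list[tuple[float, float] | None] = [None] + list(grid.windows)
        for met in NORMALIZED_METRICS:
            for m1, m2 in itertools.combinations(config.models, 2):
                for w in windows:
                    res = dependent_model_test(
                        boot[m1][met], boot[m2][met], grid,
                        n_perm=config.n_perm_dependent, window=w,
                        seed=stage_seed["dependent"])
                    key = f"{met}:{m1}-vs-{m2}:{'cumulative' if w is None else w}"
                    dep_report["tests"][key] = {
                        "area": res.area, "signed_area": res.signed_area,
                        "p": res.p_value}
                    if w is None:
                        raw_p[f"{met}:{m1}-vs-{m2}"] = res.p_value
        dep_report["bonferroni_cumulative"] = bonferroni(raw_p)
        swio.write_json_report(dep_report, outdir / "model_comparison.json")
        summary["model_comparison_p"] = raw_p
    except Exception as exc:
        raise PipelineError("compare-models", str(exc)) from exc

    # --- stage: compare groups (independent test) -------------------------
    try:
        grp_report: dict = {"n_perm": config.n_perm_group,
                            "seed": stage_seed["group"],
                            "null_mode": config.group_null_mode, "tests": {}}
        tasks = [("CC", None), ("CPL", None)]
        tasks += [(met, model) for met in NORMALIZED_METRICS
                  for model in config.models]
        for met, model in tasks:
            results = independent_group_test_windows(
                corrected[0], corrected[1], grid, metric=met, model=model,
                n_perm=config.n_perm_group,
                windows=[None] + list(grid.windows),
                seed=stage_seed["group"], m=config.m_nulls,
                null_mode=config.group_null_mode,
                swaps_per_edge=config.swaps_per_edge)
            for w, res in results.items():
                key = (f"{met}{':' + model if model else ''}:"
                       f"{'cumulative' if w is None else w}")
                grp_report["tests"][key] = {
                    "area": res.area, "signed_area": res.signed_area,
                    "p": res.p_value, "note": res.note}
        swio.write_json_report(grp_report, outdir / "group_comparison.json")
        summary["group_comparison_p"] = {
            k: v["p"] for k, v in grp_report["tests"].items()
            if k.endswith("cumulative")}
    except Exception as exc:
        raise PipelineError("compare-groups", str(exc)) from exc

    # --- stage: replicability ---------------------------------------------
    try:
        G_dmin = threshold_by_density(assocs[0], d_min)
        targets = {}
        for model in config.models:
            targets[model] = {"TOP": G_dmin, "HQS": assocs[0],
                              "COR": corrected[0]}[model]
        rep = replicability_analysis(
            targets, d_min, n_sets=config.n_sets_replicability,
            m=config.m_nulls, seed=stage_seed["replicability"],
            swaps_per_edge=config.swaps_per_edge)
        swio.write_json_report(rep, outdir / "replicability.json")
        summary["levene_p"] = {k: v.get("p") for k, v in
                               rep.get("levene", {}).items()}
    except Exception as exc:
        raise PipelineError("replicability", str(exc)) from exc

    # --- stage: skewness ---------------------------------------------------
    try:
        skew = boot["_boot"]["skewness"]
        idx0 = 0  # lowest grid density
        series = {}
        for met in ("CC_norm", "SW"):
            for other in [mo for mo in config.models if mo != "TOP"]:
                if "TOP" in config.models:
                    series[f"{met}:TOP-minus-{other}"] = (
                        boot["TOP"][met][:, idx0] - boot[other][met][:, idx0])
        # clustering of a TOP null matched to each bootstrap network; the
        # bootstrap seed derivation mirrors bootstrap_model_curves so these
        # are the same resamples the dependent-test curves came from
        boot_seed = int(np.random.SeedSequence(
            stage_seed["dependent"]).generate_state(1)[0] % (2**31 - 1))
        boots_at_dmin = [
            threshold_by_density(A, d_min)
            for A in bootstrap_association(corrected[0], n_boot=config.n_boot,
                                           seed=boot_seed)]
        top_seeds = np.random.SeedSequence(stage_seed["skewness"]).generate_state(
            len(boots_at_dmin)) % (2**31 - 1)
        series["C_TOP_null"] = np.array([
            clustering_coefficient(top_null(g, seed=int(s),
                                            swaps_per_edge=config.swaps_per_edge,
                                            allow_fragmented=True))
            for g, s in zip(boots_at_dmin, top_seeds)])
        skew_report = skewness_correlation(skew, series)
        skew_report["seed"] = stage_seed["skewness"]
        skew_report["density"] = d_min
        swio.write_json_report(skew_report, outdir / "skewness.json")
        summary["skewness_r"] = {k: v["r"] for k, v in skew_report.items()
                                 if isinstance(v, dict) and "r" in v}
    except Exception as exc:
        raise PipelineError("skewness", str(exc)) from exc

    swio.write_json_report(summary, outdir / "summary.json")
    return summary
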