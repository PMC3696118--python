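"""Nuisance-covariate correction of regional morphometry values.

Structural correlation networks are built from across-subject correlations
of regional gray-matter volume (RGV).  Before correlating, the shared
effects of nuisance covariates (typically age, sex, and total brain volume)
are removed from each region by ordinary least squares, and the residuals
are substituted for the raw values ("corrected RGV").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MorphometryDataset",
    "CorrectedRGV",
    "correct_regional_volumes",
    "correct_regional_volumes_pooled",
]


@dataclass
class MorphometryDataset:
    """Subject x region table of regional volumes plus per-subject covariates.

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_regions)
        Regional volumes in arbitrary volume units.
    region_names : sequence of str
        Unique region labels, one per column of ``values``.
    subject_ids : sequence of str
        Subject labels, one per row of ``values``.
    covariates : DataFrame, shape (n_subjects, n_covariates)
        Named covariate columns (e.g. age, sex, tbv), indexed like
        ``subject_ids``.
    seed : int or None
        Seed that generated the dataset, if synthetic.
    """

    values: np.ndarray
    region_names: list[str]
    subject_ids: list[str]
    covariates: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_names = list(self.region_names)
        self.subject_ids = list(self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subject x region array")
        n_sub, n_reg = self.values.shape
        if n_sub < 3:
            raise ValueError(
                f"need at least 3 subjects for downstream Pearson correlation, got {n_sub}"
            )
        if len(self.region_names) != n_reg:
            raise ValueError("region_names length does not match values columns")
        if len(self.subject_ids) != n_sub:
            raise ValueError("subject_ids length does not match values rows")
        if len(set(self.region_names)) != n_reg:
            dupes = sorted(
                {r for r in self.region_names if self.region_names.count(r) > 1}
            )
            raise ValueError(f"duplicate region names: {dupes}")
        if not np.isfinite(self.values).all():
            raise ValueError("values contain missing or non-finite entries")
        if len(self.covariates) != n_sub:
            raise ValueError("covariates must have one row per subject")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.region_names
        )


@dataclass
class CorrectedRGV:
    """Residualized regional values after covariate removal.

    ``residuals`` has the same shape and labels as the source dataset.  With
    an intercept in the design, every column has mean zero.
    """

    residuals: np.ndarray
    region_names: list[str]
    subject_ids: list[str]
    covariate_names_removed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.residuals.shape[0]

    @property
    def n_regions(self) -> int:
        return self.residuals.shape[1]

    @property
    def values(self) -> np.ndarray:
        # alias so association_matrix() accepts either container
        return self.residuals


def _design_matrix(
    data: MorphometryDataset, covariate_names: Sequence[str]
) -> np.ndarray:
    missing = [c for c in covariate_names if c not in data.covariates.columns]
    if missing:
        raise KeyError(f"covariates not present in dataset: {missing}")
    n = data.n_subjects
    X = np.column_stack(
        [np.ones(n)] + [data.covariates[c].to_numpy(dtype=float) for c in covariate_names]
    )
    if X.shape[1] > n - 2:
        raise ValueError(
            f"{len(covariate_names)} covariates leave fewer than 2 residual "
            f"degrees of freedom with {n} subjects"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify collinear columns by checking rank drop on removal
        names = ["intercept"] + list(covariate_names)
        full_rank = np.linalg.matrix_rank(X)
        collinear = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    return X


def correct_regional_volumes(
    data: MorphometryDataset, covariate_names: Sequence[str] = ("age", "sex", "tbv")
) -> CorrectedRGV:
    """Regress nuisance covariates out of each region by OLS.

    For every region a linear model ``volume ~ intercept + covariates`` is
    fitted across subjects and the residuals replace the raw values.  An
    intercept is always included, so residual columns are mean-centred and
    orthogonal to each covariate.

    Parameters
    ----------
    data : MorphometryDataset
    covariate_names : sequence of str
        Covariate columns to remove.  An empty sequence mean-centres the
        regions without removing anything else.

    Returns
    -------
    CorrectedRGV
    """
    X = _design_matrix(data, covariate_names)
    beta, *_ = np.linalg.lstsq(X, data.values, rcond=None)
    residuals = data.values - X @ beta
    return CorrectedRGV(
        residuals=residuals,
        region_names=list(data.region_names),
        subject_ids=list(data.subject_ids),
        covariate_names_removed=list(covariate_names),
    )


def correct_regional_volumes_pooled(
    datasets: Sequence[MorphometryDataset],
    covariate_names: Sequence[str] = ("age", "sex", "tbv"),
) -> list[CorrectedRGV]:
    """Fit one covariate regression across all groups pooled, then split.

    Alternative to per-group fitting: the OLS coefficients are estimated on
    the concatenation of all datasets, so group mean differences leak into
    the residuals.  Both modes are provided because published pipelines are
    rarely explicit about which was used.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    region_names = datasets[0].region_names
    for d in datasets[1:]:
        if d.region_names != region_names:
            raise ValueError("all datasets must share the same region names")
    pooled_values = np.vstack([d.values for d in datasets])
    pooled_cov = pd.concat([d.covariates for d in datasets], ignore_index=True)
    pooled_ids = [sid for d in datasets for sid in d.subject_ids]
    pooled = MorphometryDataset(
        values=pooled_values,
        region_names=region_names,
        subject_ids=pooled_ids,
        covariates=pooled_cov,
    )
    X = _design_matrix(pooled, covariate_names)
    beta, *_ = np.linalg.lstsq(X, pooled.values, rcond=None)
    residuals = pooled.values - X @ beta
    out: list[CorrectedRGV] = []
    start = 0
    for d in datasets:
        stop = start + d.n_subjects
        out.append(
            CorrectedRGV(
                residuals=residuals[start:stop],
                region_names=list(region_names),
                subject_ids=list(d.subject_ids),
                covariate_names_removed=list(covariate_names),
            )
        )
        start = stop
    return out
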