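"""Synthetic two-group morphometry generator.

The raw data behind published structural-covariance studies are usually
private, so the whole pipeline is exercised on synthetic cohorts instead:
two groups of subjects (defaults 31 and 28, emulating a healthy-control and
a patient cohort) with regional volumes for 90 regions drawn from a
multivariate normal whose correlation matrix has block (community)
structure.  Blocks of mutually correlated regions are what make the
thresholded network clustered — hence small-world — relative to
degree-matched random graphs, which is the phenomenon the downstream null
models probe.

Group differences are introduced by multiplicatively attenuating the
between-block correlation of the second group; linear covariate effects
(age, sex, total-brain-volume proxy) are added on top so the correction
step has something real to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MorphometryDataset

__all__ = ["SimulationConfig", "build_target_correlation", "generate_group_morphometry"]

_PSD_TOL = -1e-8


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group block-correlation generator.

    Attributes
    ----------
    n_subjects_per_group : (int, int)
        Cohort sizes; defaults mirror a 31-control / 28-patient design.
    n_regions : int
        Number of regions (network nodes), default 90.
    n_blocks : int
        Number of correlation blocks; regions are split evenly with the
        remainder assigned to the last block.
    within_block_r, between_block_r : float
        Target Pearson correlation inside / outside blocks, in [0, 1),
        with ``within_block_r > between_block_r``.
    group_effect : float
        Multiplicative attenuation in (0, 1] applied to the second group's
        between-block correlation; 1 means no group difference.
    covariate_effects : dict
        Slope per covariate (volume units per covariate unit) applied
        uniformly to all regions.
    noise_sd : float
        Standard deviation of each region's correlated component.
    seed : int
        Master seed; each group draws from a deterministic substream.
    """

    n_subjects_per_group: tuple[int, int] = (31, 28)
    n_regions: int = 90
    n_blocks: int = 6
    within_block_r: float = 0.6
    between_block_r: float = 0.15
    group_effect: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.5, "sex": 2.0, "tbv": 0.01}
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_subjects_per_group) != 2 or any(
            n < 1 for n in self.n_subjects_per_group
        ):
            raise ValueError("n_subjects_per_group must be a pair of positive integers")
        if self.n_regions < 1 or self.n_blocks < 1:
            raise ValueError("n_regions and n_blocks must be positive")
        if self.n_blocks > self.n_regions:
            raise ValueError("cannot have more blocks than regions")
        for name in ("within_block_r", "between_block_r"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.within_block_r <= self.between_block_r and self.within_block_r != 0.0:
            raise ValueError("within_block_r must exceed between_block_r")
        if self.within_block_r == 0.0 and self.between_block_r != 0.0:
            raise ValueError("within_block_r must exceed between_block_r")
        if not (0.0 < self.group_effect <= 1.0):
            raise ValueError("group_effect must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def block_sizes(self) -> list[int]:
        base = self.n_regions // self.n_blocks
        sizes = [base] * self.n_blocks
        sizes[-1] += self.n_regions - base * self.n_blocks
        return sizes


def build_target_correlation(
    config: SimulationConfig, group_index: int = 0
) -> np.ndarray:
    """Block-constant target correlation matrix for one group.

    Entries are ``within_block_r`` inside blocks, ``between_block_r``
    (attenuated by ``group_effect`` for group 1) outside, and 1 on the
    diagonal.  The matrix is checked for positive semidefiniteness and
    rejected with a diagnostic otherwise.
    """
    if group_index not in (0, 1):
        raise ValueError("group_index must be 0 or 1")
    between = config.between_block_r
    if group_index == 1:
        between *= config.group_effect
    n = config.n_regions
    R = np.full((n, n), between)
    start = 0
    for size in config.block_sizes():
        R[start : start + size, start : start + size] = config.within_block_r
        start += size
    np.fill_diagonal(R, 1.0)
    min_eig = float(np.linalg.eigvalsh(R)[0])
    if min_eig < _PSD_TOL:
        raise ValueError(
            "target correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {min_eig:.3e}); reduce block correlations"
        )
    return R


def _sample_mvn(rng: np.random.Generator, R: np.ndarray, n: int) -> np.ndarray:
    # eigen factorization tolerates the exactly-singular PSD boundary
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    return rng.standard_normal((n, R.shape[0])) @ L.T


def generate_group_morphometry(
    config: SimulationConfig, group_index: int
) -> MorphometryDataset:
    """Draw one group's subject x region morphometry table.

    Subjects are multivariate normal with the group's target correlation,
    scaled by ``noise_sd`` around a constant baseline.  Covariates are drawn
    per subject (age uniform on a pediatric 5-19 y range, sex Bernoulli(1/2),
    total-volume proxy normal around 1200 units) and their linear effects
    added to every region according to ``covariate_effects``.
    """
    n_sub = config.n_subjects_per_group[group_index]
    if n_sub < 3:
        raise ValueError(
            f"group {group_index} has {n_sub} subjects; at least 3 are needed "
            "for downstream Pearson correlation"
        )
    R = build_target_correlation(config, group_index)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[group_index])
    values = 10.0 + config.noise_sd * _sample_mvn(rng, R, n_sub)

    cov = pd.DataFrame(
        {
            "age": rng.uniform(5.0, 19.0, n_sub),
            "sex": rng.integers(0, 2, n_sub).astype(float),
            "tbv": rng.normal(1200.0, 100.0, n_sub),
        }
    )
    effect = np.zeros(n_sub)
    for name, slope in config.covariate_effects.items():
        if name not in cov.columns:
            raise KeyError(f"unknown covariate in covariate_effects: {name!r}")
        effect += slope * cov[name].to_numpy()
    values = values + effect[:, None]

    region_names = [f"R{i + 1:03d}" for i in range(config.n_regions)]
    subject_ids = [f"G{group_index + 1}S{i + 1:03d}" for i in range(n_sub)]
    return MorphometryDataset(
        values=values,
        region_names=region_names,
        subject_ids=subject_ids,
        covariates=cov,
        seed=config.seed,
    )
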