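"""FDA area statistic, bootstrap, permutation tests, reports."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import swnull
from swnull.inference import (
    bootstrap_association,
    bonferroni,
    dependent_model_test,
    fda_area,
    independent_group_test,
    independent_group_test_windows,
    replicability_analysis,
    skewness_correlation,
)
from swnull.netcon import DensityGrid


class TestFdaArea:
    def test_identical_curves_give_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert fda_area(y, y.copy()) == (0.0, 0.0)

    def test_hand_summed_example(self):
        y1 = np.array([1.2, 1.1, 1.0])
        y2 = np.array([1.0, 1.0, 1.0])
        area, signed = fda_area(y1, y2)
        assert area == pytest.approx(0.3)
        assert signed == pytest.approx(-0.3)

    def test_argument_swap_negates_signed_area_only(self):
        rng = np.random.default_rng(0)
        y1, y2 = rng.normal(size=(2, 8))
        a12, s12 = fda_area(y1, y2)
        a21, s21 = fda_area(y2, y1)
        assert a12 == pytest.approx(a21)
        assert s12 == pytest.approx(-s21)

    def test_mismatched_grids_rejected(self):
        c1 = swnull.MetricCurve(grid=[0.1, 0.2], values=[1.0, 2.0], metric="CC")
        c2 = swnull.MetricCurve(grid=[0.1, 0.3], values=[1.0, 2.0], metric="CC")
        with pytest.raises(ValueError, match="different grids"):
            fda_area(c1, c2)

    @given(st.integers(0, 10_000))
    def test_l1_metric_properties(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.normal(size=(3, 10))
        axy = fda_area(x, y)[0]
        assert axy >= 0
        assert axy == pytest.approx(fda_area(y, x)[0])
        assert fda_area(x, x)[0] == 0
        assert fda_area(x, z)[0] <= axy + fda_area(y, z)[0] + 1e-9
        assert axy >= abs(fda_area(x, y)[1])  # area >= |signed area|

    def test_disjoint_windows_sum_to_cumulative(self):
        grid = np.round(np.arange(0.22, 0.501, 0.02), 10)
        rng = np.random.default_rng(1)
        y1, y2 = rng.normal(size=(2, grid.size))
        c1 = swnull.MetricCurve(grid=grid, values=y1, metric="SW")
        c2 = swnull.MetricCurve(grid=grid, values=y2, metric="SW")
        windows = [(0.22, 0.28), (0.30, 0.38), (0.40, 0.48), (0.50, 0.50)]
        parts = [fda_area(c1, c2, window=w)[0] for w in windows]
        assert sum(parts) == pytest.approx(fda_area(c1, c2)[0])


@pytest.fixture(scope="module")
def corrected(small_config):
    data = swnull.generate_group_morphometry(small_config, 0)
    return swnull.correct_regional_volumes(data)


@pytest.fixture(scope="module")
def groups(small_config):
    d1 = swnull.generate_group_morphometry(small_config, 0)
    d2 = swnull.generate_group_morphometry(small_config, 1)
    return (swnull.correct_regional_volumes(d1),
            swnull.correct_regional_volumes(d2))


@pytest.fixture(scope="module")
def grid():
    return DensityGrid(start=0.25, step=0.05, stop=0.45,
                       windows=[(0.25, 0.35), (0.4, 0.45)])


class TestBootstrap:
    def test_same_seed_identical_samples(self, corrected):
        a = bootstrap_association(corrected, n_boot=3, seed=5)
        b = bootstrap_association(corrected, n_boot=3, seed=5)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.r, y.r)

    def test_correlation_inflation_direction(self, corrected):
        """Resampling with replacement duplicates subjects and inflates the
        mean absolute correlation relative to the original matrix."""
        A = swnull.association_matrix(corrected)
        iu, ju = np.triu_indices(A.n_regions, k=1)
        boots = bootstrap_association(corrected, n_boot=100, seed=2)
        boot_mean = np.mean([np.abs(b.r[iu, ju]).mean() for b in boots])
        assert boot_mean >= np.abs(A.r[iu, ju]).mean()

    def test_requires_positive_count(self, corrected):
        with pytest.raises(ValueError):
            bootstrap_association(corrected, n_boot=0)


class TestDependentModelTest:
    def _grid(self, n):
        return np.linspace(0.2, 0.5, n)

    def test_identical_curves_give_p_one(self):
        curves = np.random.default_rng(0).normal(size=(20, 6))
        res = dependent_model_test(curves, curves.copy(), self._grid(6),
                                   n_perm=200, seed=1)
        assert res.area == 0.0
        assert res.p_value == 1.0

    def test_large_offset_reaches_minimum_p(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 6), scale=0.01)
        res = dependent_model_test(base, base + 0.5, self._grid(6),
                                   n_perm=500, seed=2)
        assert res.p_value == pytest.approx(1 / 501)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 15, 6))
        r1 = dependent_model_test(a, b, self._grid(6), n_perm=300, seed=9)
        r2 = dependent_model_test(a, b, self._grid(6), n_perm=300, seed=9)
        assert r1.p_value == r2.p_value

    def test_low_n_perm_warns(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(2, 10, 4))
        with pytest.warns(UserWarning, match="unstable"):
            dependent_model_test(a, b, self._grid(4), n_perm=50, seed=0)

    def test_exchangeable_labels_give_uniform_p(self):
        """Calibration: when both 'models' draw from one distribution the
        test rejects at the nominal rate."""
        rng = np.random.default_rng(4)
        n_runs, alpha = 200, 0.05
        rejections = 0
        for _ in range(n_runs):
            a, b = rng.normal(size=(2, 15, 6))
            res = dependent_model_test(
                a, b, self._grid(6), n_perm=500,
                seed=int(rng.integers(2**31 - 1)))
            rejections += res.p_value <= alpha
        # 95% binomial interval around 0.05 at 200 runs: [4, 17]
        assert 4 <= rejections <= 17


class TestIndependentGroupTest:
    def test_deterministic_under_seed(self, groups, grid):
        kw = dict(metric="CC", n_perm=120, seed=3)
        r1 = independent_group_test(*groups, grid, **kw)
        r2 = independent_group_test(*groups, grid, **kw)
        assert r1.p_value == r2.p_value
        assert r1.area == r2.area

    def test_windows_share_one_permutation_pass(self, groups, grid):
        multi = independent_group_test_windows(
            *groups, grid, metric="CC", n_perm=120,
            windows=[None, (0.25, 0.35)], seed=3)
        single = independent_group_test(*groups, grid, metric="CC",
                                        n_perm=120, seed=3)
        assert multi[None].p_value == single.p_value

    def test_overlapping_subjects_rejected(self, groups, grid):
        with pytest.raises(ValueError, match="disjoint"):
            independent_group_test(groups[0], groups[0], grid, n_perm=120)

    def test_small_groups_rejected(self, small_config, grid):
        data = swnull.generate_group_morphometry(small_config, 0)
        c = swnull.correct_regional_volumes(data)
        tiny = swnull.CorrectedRGV(
            residuals=c.residuals[:2], region_names=c.region_names,
            subject_ids=c.subject_ids[:2])
        with pytest.raises(ValueError, match="at least 3"):
            independent_group_test(tiny, c, grid, n_perm=120)

    def test_normalized_metric_with_reuse_mode_is_labeled(self, groups, grid):
        res = independent_group_test(*groups, grid, metric="SW", model="HQS",
                                     n_perm=100, seed=1, m=4,
                                     null_mode="reuse")
        assert "approximate" in res.note
        assert 0 < res.p_value <= 1

    def test_group_effect_detected_more_often_than_null(self, grid):
        """Power check: attenuating group 2's between-block correlation
        yields smaller p than the matched no-effect configuration."""
        effect = swnull.SimulationConfig(
            n_subjects_per_group=(25, 25), n_regions=40, n_blocks=4,
            between_block_r=0.3, group_effect=0.3, seed=21)
        null = swnull.SimulationConfig(
            n_subjects_per_group=(25, 25), n_regions=40, n_blocks=4,
            between_block_r=0.3, group_effect=1.0, seed=21)
        p_eff, p_null = [], []
        for seed in range(5):
            for cfg, acc in ((effect, p_eff), (null, p_null)):
                cfg2 = swnull.SimulationConfig(
                    **{**cfg.__dict__, "seed": seed})
                g1 = swnull.correct_regional_volumes(
                    swnull.generate_group_morphometry(cfg2, 0))
                g2 = swnull.correct_regional_volumes(
                    swnull.generate_group_morphometry(cfg2, 1))
                acc.append(independent_group_test(
                    g1, g2, grid, metric="CC", n_perm=150, seed=seed).p_value)
        assert np.mean(p_eff) < np.mean(p_null)


class TestReplicability:
    def test_report_structure_and_levene(self, small_config):
        data = swnull.generate_group_morphometry(small_config, 0)
        corrected = swnull.correct_regional_volumes(data)
        A = swnull.association_matrix(corrected)
        G = swnull.threshold_by_density(A, 0.3)
        rep = replicability_analysis(
            {"TOP": G, "HQS": A, "COR": corrected}, density=0.3,
            n_sets=4, m=6, seed=1)
        assert set(rep["models"]) == {"TOP", "HQS", "COR"}
        for entry in rep["models"].values():
            assert 0 <= entry["anova_C"]["p"] <= 1
        assert 0 <= rep["levene"]["C"]["p"] <= 1

    def test_degenerate_ensembles_flagged(self):
        adj = (1 - np.eye(5)).astype(np.uint8)
        net = swnull.BinaryNetwork(adjacency=adj, density=1.0,
                                   threshold_kind="density", threshold_value=1.0)
        with pytest.warns(UserWarning):
            rep = replicability_analysis({"TOP": net}, density=1.0,
                                         n_sets=2, m=2, seed=0)
        assert rep["models"]["TOP"]["anova_C"]["degenerate"] is True


class TestSkewnessCorrelation:
    def test_recovers_injected_linear_dependence(self):
        rng = np.random.default_rng(0)
        skew = rng.normal(size=200)
        diff = -0.6 * skew + rng.normal(scale=0.4, size=200)
        true_r = -0.6 / np.sqrt(0.6**2 + 0.4**2)
        out = skewness_correlation(skew, {"diff": diff})
        assert out["diff"]["r"] == pytest.approx(true_r, abs=0.12)

    def test_matches_hand_pearson_on_five_pairs(self):
        skew = np.array([0.1, 0.5, -0.2, 0.8, 0.3] * 2)
        vals = np.array([1.0, 0.7, 1.3, 0.4, 0.9] * 2)
        out = skewness_correlation(skew, {"d": vals})
        # hand Pearson via covariance formula
        r_hand = (np.mean(skew * vals) - skew.mean() * vals.mean()) / (
            skew.std() * vals.std())
        assert out["d"]["r"] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_series_rejected(self):
        skew = np.linspace(0, 1, 12)
        with pytest.raises(ValueError, match="constant"):
            skewness_correlation(skew, {"d": np.ones(12)})
        with pytest.raises(ValueError, match="constant"):
            skewness_correlation(np.ones(12), {"d": skew})


def test_bonferroni_clips_at_one():
    adj = bonferroni({"a": 0.01, "b": 0.5, "c": 0.9})
    assert adj["a"] == pytest.approx(0.03)
    assert adj["c"] == 1.0
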