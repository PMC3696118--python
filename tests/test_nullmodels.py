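"""TOP / HQS / COR null models: invariants, moments, ensembles."""

import itertools

import numpy as np
import pytest

import swnull
from swnull.metrics import clustering_coefficient
from swnull.nullmodels import (
    cor_null,
    cor_null_correlation,
    hqs_moments,
    hqs_null_covariance,
    hqs_null_network,
    null_ensemble,
    top_null,
)

from conftest import make_network, random_connected_adjacency


@pytest.fixture(scope="module")
def block_assoc(default_config):
    data = swnull.generate_group_morphometry(default_config, 0)
    corrected = swnull.correct_regional_volumes(data)
    return corrected, swnull.association_matrix(corrected)


class TestTop:
    def test_preserves_degrees_simplicity_connectivity(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            adj = random_connected_adjacency(rng, int(rng.integers(8, 40)), 0.2)
            net = make_network(adj)
            out = top_null(net, seed=seed)
            assert np.array_equal(out.degrees(), net.degrees())
            assert np.array_equal(out.adjacency, out.adjacency.T)
            assert np.all(np.diag(out.adjacency) == 0)
            assert out.is_connected()

    def test_complete_graph_returned_unchanged_with_warning(self):
        adj = (1 - np.eye(5)).astype(np.uint8)
        net = make_network(adj)
        with pytest.warns(UserWarning, match="no rewirable"):
            out = top_null(net, seed=0)
        np.testing.assert_array_equal(out.adjacency, net.adjacency)

    def test_disconnected_input_rejected(self):
        adj = np.zeros((4, 4), dtype=np.uint8)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        with pytest.raises(ValueError, match="connected"):
            top_null(make_network(adj), seed=0)

    def test_same_seed_same_output(self):
        rng = np.random.default_rng(1)
        net = make_network(random_connected_adjacency(rng, 20, 0.2))
        a = top_null(net, seed=99)
        b = top_null(net, seed=99)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)

    def test_p6_outputs_are_relabeled_paths(self):
        """Exhaustive claim: every connected simple graph on 6 nodes with
        degree multiset {1,1,2,2,2,2} is a path; rewiring P6 must therefore
        return relabeled paths."""
        # verify the enumeration claim by brute force over all 6-node graphs
        pairs = list(itertools.combinations(range(6), 2))
        target = sorted([1, 1, 2, 2, 2, 2])
        for bits in range(1 << len(pairs)):
            if bin(bits).count("1") != 5:
                continue
            adj = np.zeros((6, 6), dtype=np.uint8)
            for k, (a, b) in enumerate(pairs):
                if bits >> k & 1:
                    adj[a, b] = adj[b, a] = 1
            if sorted(adj.sum(axis=0)) != target:
                continue
            if not make_network(adj).is_connected():
                continue
            # a connected graph with n-1 edges is a tree; max degree 2 -> path
            assert adj.sum() // 2 == 5 and adj.sum(axis=0).max() == 2
        p6 = np.zeros((6, 6), dtype=np.uint8)
        for i in range(5):
            p6[i, i + 1] = p6[i + 1, i] = 1
        net = make_network(p6)
        import warnings
        for seed in range(30):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # swap-count floor warnings
                out = top_null(net, seed=seed)
            assert out.is_connected()
            assert sorted(out.degrees().tolist()) == target


class TestHQS:
    def test_moment_constants_satisfy_identities(self, block_assoc):
        _, A = block_assoc
        mom = hqs_moments(A.cov)
        assert mom.m_f >= 2
        # analytic expectations of the Gram construction
        assert mom.m_f * mom.mu**2 == pytest.approx(mom.e)
        var_offdiag = mom.m_f * ((mom.mu**2 + mom.sigma**2) ** 2 - mom.mu**4)
        assert var_offdiag == pytest.approx(mom.v, rel=1e-6)

    def test_every_draw_is_psd(self, block_assoc):
        _, A = block_assoc
        for seed in range(20):
            C = hqs_null_covariance(A, seed)
            assert np.linalg.eigvalsh(C)[0] >= -1e-8

    def test_same_seed_same_matrix(self, block_assoc):
        _, A = block_assoc
        np.testing.assert_array_equal(hqs_null_covariance(A, 7),
                                      hqs_null_covariance(A, 7))

    def test_nonpositive_mean_covariance_rejected(self):
        cov = np.eye(4)
        cov[0, 1] = cov[1, 0] = -0.5
        cov[2, 3] = cov[3, 2] = -0.1
        with pytest.raises(ValueError, match="non-positive mean"):
            hqs_moments(cov)

    def test_zero_offdiagonal_variance_rejected(self):
        cov = np.eye(4) + 0.2
        with pytest.raises(ValueError, match="variance"):
            hqs_moments(cov)

    def test_network_density_matches_request(self, block_assoc):
        _, A = block_assoc
        net = hqs_null_network(A, 0.22, seed=3)
        assert net.n_edges == 881
        assert net.provenance == "HQS"

    def test_full_density_is_complete(self, block_assoc):
        _, A = block_assoc
        assert hqs_null_network(A, 1.0, seed=0).n_edges == 4005

    def test_null_clustering_exceeds_top_null_clustering(self, block_assoc):
        """The transitivity effect: moment-matched covariance nulls stay
        clustered, degree-preserving rewiring does not."""
        corrected, A = block_assoc
        G = swnull.threshold_by_density(A, 0.22)
        hqs = null_ensemble(A, "HQS", m=10, seed=1, density=0.22)
        top = null_ensemble(G, "TOP", m=10, seed=1)
        assert hqs.C_null_mean > top.C_null_mean


class TestCOR:
    def test_row_multisets_preserved(self, block_assoc):
        corrected, _ = block_assoc
        r, permuted = cor_null_correlation(corrected, seed=0,
                                           return_permuted=True)
        values = corrected.values
        np.testing.assert_allclose(np.sort(permuted, axis=1),
                                   np.sort(values, axis=1))
        assert permuted.sum(axis=1) == pytest.approx(values.sum(axis=1))
        assert r.shape == (90, 90)

    def test_network_density_and_provenance(self, block_assoc):
        corrected, _ = block_assoc
        net = cor_null(corrected, 0.22, seed=5)
        assert net.n_edges == 881
        assert net.provenance == "COR"

    def test_output_is_valid_correlation_matrix(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(10, 6))
        r = cor_null_correlation(values, seed=1)
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1 + 1e-12)

    def test_structure_destroyed_on_block_data(self, block_assoc):
        corrected, A = block_assoc
        iu, ju = np.triu_indices(90, k=1)
        orig = np.abs(A.r[iu, ju]).mean()
        perm = np.mean([
            np.abs(cor_null_correlation(corrected, seed=s)[iu, ju]).mean()
            for s in range(10)
        ])
        assert perm < orig

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            cor_null_correlation(np.zeros((2, 5)), seed=0)


class TestNullEnsemble:
    def test_single_member_top_on_k5(self):
        adj = (1 - np.eye(5)).astype(np.uint8)
        with pytest.warns(UserWarning):
            ens = null_ensemble(make_network(adj), "TOP", m=1, seed=0)
        assert ens.C_null_mean == 1.0
        assert ens.L_null_mean == 1.0

    def test_same_seed_identical_ensembles(self, block_assoc):
        _, A = block_assoc
        e1 = null_ensemble(A, "HQS", m=4, seed=3, density=0.3)
        e2 = null_ensemble(A, "HQS", m=4, seed=3, density=0.3)
        np.testing.assert_array_equal(e1.C_null_values, e2.C_null_values)
        np.testing.assert_array_equal(e1.L_null_values, e2.L_null_values)

    def test_means_are_arithmetic_means(self, block_assoc):
        corrected, _ = block_assoc
        ens = null_ensemble(corrected, "COR", m=5, seed=2, density=0.25)
        assert ens.C_null_mean == pytest.approx(ens.C_null_values.mean())
        assert ens.L_null_mean == pytest.approx(ens.L_null_values.mean())

    def test_discard_policy_yields_connected_members(self, block_assoc):
        corrected, A = block_assoc
        ens = null_ensemble(A, "HQS", m=5, seed=4, density=0.22,
                            fragment_policy="discard")
        assert all(g.is_connected() for g in ens.members)

    def test_error_policy_raises_on_fragmentation(self, block_assoc):
        _, A = block_assoc
        # at the lowest density HQS draws fragment frequently
        with pytest.raises(RuntimeError, match="fragmented"):
            for seed in range(20):
                null_ensemble(A, "HQS", m=20, seed=seed, density=0.22,
                              fragment_policy="error")

    def test_top_dispersion_below_hqs(self, block_assoc):
        """Replicability premise: TOP ensemble C_null varies less across
        draws than HQS ensemble C_null."""
        corrected, A = block_assoc
        G = swnull.threshold_by_density(A, 0.22)
        top = null_ensemble(G, "TOP", m=20, seed=8)
        hqs = null_ensemble(A, "HQS", m=20, seed=8, density=0.22)
        assert top.C_null_values.var() < hqs.C_null_values.var()

    def test_unknown_model_rejected(self, block_assoc):
        _, A = block_assoc
        with pytest.raises(ValueError, match="unknown null model"):
            null_ensemble(A, "XYZ", m=2, seed=0, density=0.3)
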