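import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hemosys.cluster import (
    UNASSIGNED,
    cluster_niches,
    master_correlation_matrix,
    refine_clusters,
    seed_correlation_map,
    svd_initial_clusters,
)
from tests.conftest import make_grid


def _pearson_oracle(x, y):
    """Textbook sum formula, written independently of the implementation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den


class TestSeedCorrelationMap:
    def test_seed_against_itself_and_negation(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=20)
        values = np.stack([[s, -s], [2 * s + 1, rng.normal(size=20)]])
        cmap = seed_correlation_map(make_grid(values), (0, 0), (0, 20))
        assert cmap.r_values[0, 0] == pytest.approx(1.0)
        assert cmap.r_values[0, 1] == pytest.approx(-1.0)
        assert cmap.r_values[1, 0] == pytest.approx(1.0)  # affine copy

    def test_printed_example_r(self):
        values = np.zeros((1, 2, 4))
        values[0, 0] = [1, 2, 3, 4]
        values[0, 1] = [2, 1, 4, 3]
        cmap = seed_correlation_map(make_grid(values), (0, 0), (0, 4))
        assert cmap.r_values[0, 1] == pytest.approx(0.6, abs=1e-12)

    def test_constant_seed_warns_and_returns_all_missing(self):
        values = np.ones((1, 2, 10))
        values[0, 1] = np.random.default_rng(0).normal(size=10)
        with pytest.warns(UserWarning, match="constant"):
            cmap = seed_correlation_map(make_grid(values), (0, 0), (0, 10))
        assert np.isnan(cmap.r_values).all()


class TestMasterCorrelationMatrix:
    def test_identical_series_give_unit_matrix(self):
        s = np.sin(np.arange(12.0))
        master = master_correlation_matrix(make_grid(np.stack([[s, s]])), (0, 12))
        np.testing.assert_allclose(master.matrix, 1.0)

    def test_orthogonal_series_uncorrelated(self):
        t = np.arange(12.0)
        a = np.cos(2 * np.pi * t / 12)
        b = np.cos(2 * np.pi * 2 * t / 12)
        master = master_correlation_matrix(make_grid(np.stack([[a, b]])), (0, 12))
        assert abs(master.matrix[0, 1]) < 1e-12

    def test_symmetric_unit_diagonal_on_random_input(self):
        rng = np.random.default_rng(3)
        master = master_correlation_matrix(make_grid(rng.normal(size=(4, 5, 30))), (0, 30))
        assert master.n_cells == 20
        np.testing.assert_allclose(master.matrix, master.matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(master.matrix), 1.0)
        assert np.abs(master.matrix).max() <= 1.0

    def test_pearson_matches_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(2, 3, 25))
        master = master_correlation_matrix(make_grid(values), (0, 25))
        for i, (ri, ci) in enumerate(master.cell_index):
            for j, (rj, cj) in enumerate(master.cell_index):
                expected = _pearson_oracle(values[ri, ci], values[rj, cj])
                assert master.matrix[i, j] == pytest.approx(expected, abs=1e-12)


def _planted_grid(profiles, labels, noise_sd, seed=0, n=28):
    rng = np.random.default_rng(seed)
    R, C = labels.shape
    values = np.empty((R, C, n))
    for r in range(R):
        for c in range(C):
            values[r, c] = profiles[labels[r, c]] + rng.normal(0, noise_sd, n)
    return make_grid(values)


class TestSvdInitialClusters:
    def test_anticorrelated_blocks_split_into_two_groups(self):
        t = np.arange(28.0)
        p = np.cos(2 * np.pi * t / 14)
        labels = np.array([[0, 0, 1, 1]] * 2)
        grid = _planted_grid([p, -p], labels, noise_sd=0.05)
        init = svd_initial_clusters(master_correlation_matrix(grid, (0, 28)))
        truth = [labels[r, c] for r, c in init.cell_index]
        assert len(np.unique(init.labels)) == 2
        assert adjusted_rand_score(truth, init.labels) == 1.0

    def test_identical_series_form_one_group(self):
        t = np.arange(28.0)
        grid = _planted_grid([np.cos(2 * np.pi * t / 14)], np.zeros((2, 3), int), 1e-6)
        init = svd_initial_clusters(master_correlation_matrix(grid, (0, 28)))
        assert len(np.unique(init.labels)) == 1

    def test_three_orthogonal_profiles_recovered_exactly(self):
        t = np.arange(28.0)
        profiles = [np.cos(2 * np.pi * k * t / 28) for k in (1, 2, 3)]
        labels = (np.arange(12) % 3).reshape(3, 4)
        grid = _planted_grid(profiles, labels, noise_sd=0.02)
        master = master_correlation_matrix(grid, (0, 28))
        final = refine_clusters(svd_initial_clusters(master), grid)
        truth = [labels[r, c] for r, c in final.cell_index]
        assert adjusted_rand_score(truth, final.cell_labels) == 1.0
        assert final.n_niches == 3


class TestRefineClusters:
    def test_noisy_planted_niches_recovered(self):
        t = np.arange(28.0)
        profiles = [np.cos(2 * np.pi * k * t / 28) for k in (1, 2, 3)]
        labels = (np.arange(24) % 3).reshape(4, 6)
        grid = _planted_grid(profiles, labels, noise_sd=0.25 / np.sqrt(2), seed=4)
        final = cluster_niches(grid, windows=[(0, 28)])[0]
        truth = [labels[r, c] for r, c in final.cell_index]
        assert adjusted_rand_score(truth, final.cell_labels) >= 0.9

    def test_pure_noise_dissolves_to_empty_labeling(self):
        # large grid so the 5% minimum size rule has teeth
        for seed in range(5):
            rng = np.random.default_rng(seed)
            grid = make_grid(rng.normal(size=(20, 28, 28)))
            master = master_correlation_matrix(grid, (0, 28))
            init = svd_initial_clusters(master)
            with pytest.warns(UserWarning, match="empty labeling"):
                final = refine_clusters(init, grid)
            assert final.n_niches == 0
            assert (final.cell_labels == UNASSIGNED).all()

    def test_member_and_size_rules_hold_on_random_structured_input(self):
        rng = np.random.default_rng(12)
        t = np.arange(40.0)
        profiles = [np.cos(2 * np.pi * t / p) for p in (20, 8)]
        labels = (np.arange(30) % 2).reshape(5, 6)
        grid = _planted_grid(profiles, labels, noise_sd=0.3, seed=12, n=40)
        final = cluster_niches(grid, windows=[(0, 40)])[0]
        M = len(final.cell_index)
        for k in range(final.n_niches):
            members = final.cell_labels == k
            assert members.sum() >= int(np.ceil(0.05 * M))
            cent = final.centroids[k]
            for idx in np.nonzero(members)[0]:
                r, c = final.cell_index[idx]
                assert _pearson_oracle(grid.values[r, c, 0:40], cent) > 0.7

    def test_refinement_is_deterministic(self):
        t = np.arange(28.0)
        profiles = [np.cos(2 * np.pi * k * t / 28) for k in (1, 2)]
        labels = (np.arange(16) % 2).reshape(4, 4)
        grid = _planted_grid(profiles, labels, noise_sd=0.2, seed=7)
        a = cluster_niches(grid, windows=[(0, 28)])[0]
        b = cluster_niches(grid, windows=[(0, 28)])[0]
        np.testing.assert_array_equal(a.cell_labels, b.cell_labels)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestSharedProfileMerge:
    def test_windows_with_shared_profile_collapse_to_one_niche(self):
        # three distinct profiles in the first half, one shared afterwards
        t = np.arange(56.0)
        early = [np.cos(2 * np.pi * k * t / 28) for k in (1, 2, 3)]
        shared = np.cos(2 * np.pi * t / 14)
        labels = (np.arange(16) % 3).reshape(4, 4)
        rng = np.random.default_rng(2)
        values = np.empty((4, 4, 56))
        for r in range(4):
            for c in range(4):
                sig = np.where(t < 28, early[labels[r, c]], shared)
                values[r, c] = sig + rng.normal(0, 0.1, 56)
        grid = make_grid(values)
        w1, w2 = cluster_niches(grid, windows=[(0, 28), (28, 56)])
        assert w1.n_niches == 3
        assert w2.n_niches == 1
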