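import numpy as np
import pytest
from scipy.stats import norm

from chlorospec import (
    DensityPair,
    MSDConfig,
    SubsetPlan,
    density_distance_sq,
    fit_pca,
    kde_gaussian,
    msd,
    msd_sweep,
    nominate_size,
    silverman_bandwidth,
)
from chlorospec.representativeness import MSDResult


class TestPCA:
    def test_collinear_points_put_all_variance_on_first_pc(self, rng):
        direction = rng.normal(size=10)
        X = np.outer(rng.normal(size=20), direction)
        proj = fit_pca(X, k=1)
        assert proj.explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_explained_variance_sums_to_one_at_full_rank(self, rng):
        X = rng.normal(size=(12, 5))
        proj = fit_pca(X)
        assert proj.explained.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_have_zero_column_means(self, rng):
        proj = fit_pca(rng.normal(size=(30, 8)), k=4)
        assert np.abs(proj.scores.mean(axis=0)).max() < 1e-10

    def test_loadings_columns_orthonormal(self, rng):
        proj = fit_pca(rng.normal(size=(30, 8)), k=4)
        np.testing.assert_allclose(
            proj.loadings.T @ proj.loadings, np.eye(4), atol=1e-8
        )

    def test_projecting_training_rows_reproduces_scores(self, rng):
        X = rng.normal(size=(25, 6))
        proj = fit_pca(X, k=3)
        np.testing.assert_allclose(proj.project(X), proj.scores, atol=1e-10)

    def test_k_beyond_rank_is_error(self, rng):
        with pytest.raises(ValueError, match="rank"):
            fit_pca(rng.normal(size=(4, 10)), k=5)

    def test_variance_threshold_picks_smallest_sufficient_k(self, rng):
        X = np.column_stack([
            10 * rng.normal(size=50), rng.normal(size=50), 0.1 * rng.normal(size=50)
        ])
        proj = fit_pca(X, var_threshold=0.90)
        assert proj.k < 3


class TestKDE:
    def test_single_sample_collapses_to_kernel_pdf(self):
        grid = np.linspace(-5, 5, 301)
        dens = kde_gaussian([0.0], grid, h=1.0)
        np.testing.assert_allclose(dens, norm.pdf(grid), atol=1e-12)

    def test_density_integrates_to_one(self, rng):
        x = rng.normal(2.0, 3.0, size=40)
        h = silverman_bandwidth(x)
        grid = np.linspace(x.min() - 5 * h, x.max() + 5 * h, 4001)
        mass = np.trapezoid(kde_gaussian(x, grid, h), grid)
        assert mass == pytest.approx(1.0, abs=1e-4)

    def test_matches_direct_sum_of_scaled_kernels(self):
        grid = np.linspace(-4, 4, 101)
        dens = kde_gaussian([-1.0, 1.0], grid, h=0.5)
        brute = 0.5 * (
            norm.pdf(grid, loc=-1, scale=0.5) + norm.pdf(grid, loc=1, scale=0.5)
        )
        np.testing.assert_allclose(dens, brute, atol=1e-12)

    def test_nonpositive_bandwidth_is_error(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde_gaussian([0.0], np.linspace(-1, 1, 10), h=0.0)

    def test_silverman_rule_matches_formula(self, rng):
        x = rng.normal(size=100)
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)


class TestDensityDistance:
    def test_identical_densities_have_zero_distance(self):
        grid = np.linspace(-3, 3, 200)
        d = kde_gaussian([0.0, 1.0], grid, 0.7)
        pair = DensityPair(0, grid, d, d.copy(), 0.7)
        assert density_distance_sq(pair) == 0.0

    def test_unit_separated_kernels_match_closed_form(self):
        """d2 between N(0,1) and N(1,1) kernels: the Gaussian product
        integral gives (1/sqrt(pi)) (1 - exp(-1/4)) ~ 0.1248."""
        grid = np.linspace(-6, 7, 2048)
        pair = DensityPair(
            0, grid, kde_gaussian([0.0], grid, 1.0), kde_gaussian([1.0], grid, 1.0), 1.0
        )
        expected = (1 - np.exp(-0.25)) / np.sqrt(np.pi)
        assert density_distance_sq(pair) == pytest.approx(expected, abs=1e-6)

    def test_grid_refinement_changes_little(self, rng):
        s, p = rng.normal(size=20), rng.normal(0.5, 1.2, size=30)
        h = silverman_bandwidth(p)
        lo = min(s.min(), p.min()) - 3 * h
        hi = max(s.max(), p.max()) + 3 * h
        vals = []
        for g in (2048, 4096):
            grid = np.linspace(lo, hi, g)
            pair = DensityPair(
                0, grid, kde_gaussian(s, grid, h), kde_gaussian(p, grid, h), h
            )
            vals.append(density_distance_sq(pair))
        assert abs(vals[0] - vals[1]) < 1e-6

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            DensityPair(0, np.linspace(0, 1, 10), np.zeros(10), np.zeros(9), 1.0)


class TestMSD:
    def test_subset_equal_to_population_gives_zero(self, rng):
        scores = rng.normal(size=(40, 3))
        res = msd(scores, scores, MSDConfig(k=3))
        assert res.msd == pytest.approx(0.0, abs=1e-10)

    def test_single_pc_msd_equals_its_d2(self, rng):
        s, p = rng.normal(size=(15, 1)), rng.normal(size=(25, 1))
        res = msd(s, p, MSDConfig(k=1))
        assert res.msd == pytest.approx(res.d2[0], abs=1e-15)

    def test_msd_is_mean_of_per_pc_distances(self, rng):
        res = msd(rng.normal(size=(15, 4)), rng.normal(size=(25, 4)), MSDConfig(k=4))
        assert res.msd == pytest.approx(res.d2.mean(), abs=1e-12)
        assert (res.d2 >= 0).all()

    def test_invariant_to_pc_column_order(self, rng):
        s, p = rng.normal(size=(15, 3)), rng.normal(size=(25, 3))
        a = msd(s, p, MSDConfig(k=3)).msd
        b = msd(s[:, ::-1], p[:, ::-1], MSDConfig(k=3)).msd
        assert a == pytest.approx(b, rel=1e-12)

    def test_each_density_pair_integrates_to_one(self, rng):
        res = msd(rng.normal(size=(20, 2)), rng.normal(size=(30, 2)), MSDConfig(k=2))
        for pair in res.pairs:
            for dens in (pair.p_subset, pair.p_pop):
                assert np.trapezoid(dens, pair.grid) == pytest.approx(1.0, abs=0.02)

    def test_mismatched_pc_counts_rejected(self, rng):
        with pytest.raises(ValueError):
            msd(rng.normal(size=(10, 2)), rng.normal(size=(10, 3)))


class TestSweepAndNomination:
    def test_nomination_is_smallest_size_near_the_minimum(self):
        def res(size, value):
            return MSDResult(subset_size=size, d2=np.array([value]), k=1)

        results = [res(60, 0.5), res(100, 0.105), res(140, 0.1)]
        assert nominate_size(results, rel_tol=0.10) == 100
        assert nominate_size(results, rel_tol=0.01) == 140

    def test_sweep_emits_one_result_per_size_and_nominates_one(self, rng):
        cal = rng.normal(size=(60, 30))
        val = rng.normal(size=(20, 30))
        plan = SubsetPlan(sizes=(10, 20, 40))
        results, nominated = msd_sweep(cal, val, plan, MSDConfig(k=3))
        assert [r.subset_size for r in results] == [10, 20, 40]
        assert nominated in {10, 20, 40}

    def test_sweep_is_deterministic(self, rng):
        cal = rng.normal(size=(50, 20))
        val = rng.normal(size=(15, 20))
        plan = SubsetPlan(sizes=(10, 30))
        r1, n1 = msd_sweep(cal, val, plan)
        r2, n2 = msd_sweep(cal, val, plan)
        assert n1 == n2
        np.testing.assert_array_equal(
            [r.msd for r in r1], [r.msd for r in r2]
        )
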