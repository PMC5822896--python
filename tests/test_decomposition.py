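import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from petage.decomposition import (
    AssociationResult,
    FitStats,
    NoAgingComponentError,
    SpatialICA,
    decompose,
    grouped_association,
    polynomial_age_fit,
    screen_components,
    select_aging_component,
)
from petage.volumes import Cohort, SubjectRecord, VolumeGrid

GRID = VolumeGrid((12, 15, 12), (4.0, 4.0, 4.0))


def planted_mixture(n_subjects=60, noise=0.01, seed=0, age_linked=False):
    """Stack = mixture of 3 disjoint sparse block sources with random weights.

    Supports are kept to ~5% of the grid each: disjoint indicators are only
    approximately uncorrelated, and dense supports would break the spatial
    independence that ICA assumes.
    """
    rng = np.random.default_rng(seed)
    v = GRID.n_voxels
    sources = np.zeros((3, v))
    sources[0, :100] = 1.0
    sources[1, 200:300] = 1.0
    sources[2, 400:500] = 1.0
    ages = rng.uniform(20, 80, size=n_subjects)
    weights = rng.normal(0.0, 1.0, size=(n_subjects, 3))
    if age_linked:
        weights[:, 0] = -0.04 * ages + rng.normal(0, 0.05, size=n_subjects)
    X = weights @ sources + rng.normal(0, noise, size=(n_subjects, v))
    subjects = [SubjectRecord(id=f"s{i}", age=float(ages[i]), sex="M")
                for i in range(n_subjects)]
    cohort = Cohort(subjects, GRID, X.reshape(n_subjects, *GRID.shape))
    return cohort, sources, weights


def matched_abs_correlation(recovered: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Hungarian matching on |corr| between recovered and true source maps."""
    k = truth.shape[0]
    c = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            c[i, j] = abs(np.corrcoef(recovered[i], truth[j])[0, 1])
    rows, cols = linear_sum_assignment(-c)
    return c[rows, cols]


class TestSpatialICA:
    def test_recovers_planted_disjoint_sources(self):
        cohort, sources, _ = planted_mixture()
        cs = decompose(cohort, n_components=3, seed=0)
        cors = matched_abs_correlation(cs.maps, sources)
        assert np.all(cors >= 0.95)

    def test_deterministic_given_seed(self):
        cohort, _, _ = planted_mixture(n_subjects=30)
        cs1 = decompose(cohort, n_components=3, seed=42)
        cs2 = decompose(cohort, n_components=3, seed=42)
        assert np.array_equal(cs1.loadings, cs2.loadings)
        assert np.array_equal(cs1.maps, cs2.maps)

    def test_scale_convention_and_reconstruction(self):
        cohort, _, _ = planted_mixture(noise=0.001)
        cs = decompose(cohort, n_components=3, seed=0)
        assert np.allclose(np.linalg.norm(cs.maps, axis=1), 1.0)
        assert np.allclose(cs.loadings.std(axis=0), 1.0)
        assert np.all(stats.skew(cs.maps, axis=1) >= 0)
        X = cohort.stack.reshape(len(cohort), -1)
        resid = X - cs.reconstruct()
        explained = 1 - (resid**2).sum() / ((X - X.mean(0))**2).sum()
        assert explained >= 0.99  # 3 true sources, near-noiseless

    def test_voxel_order_invariance_up_to_matching(self):
        cohort, sources, _ = planted_mixture(n_subjects=30, seed=3)
        cs = decompose(cohort, n_components=3, seed=5)
        rng = np.random.default_rng(0)
        perm = rng.permutation(GRID.n_voxels)
        stack_p = cohort.stack.reshape(len(cohort), -1)[:, perm].reshape(cohort.stack.shape)
        cohort_p = Cohort(cohort.subjects, GRID, stack_p)
        cs_p = decompose(cohort_p, n_components=3, seed=5)
        cors = matched_abs_correlation(cs_p.maps, sources[:, perm])
        assert np.all(cors >= 0.95)
        # loadings agree up to permutation/sign as well
        lc = matched_abs_correlation(cs_p.loadings.T, cs.loadings.T)
        assert np.all(lc >= 0.95)

    def test_duplicated_subject_is_rank_deficient(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=GRID.n_voxels)
        X = np.tile(row, (10, 1)).reshape(10, *GRID.shape)
        subjects = [SubjectRecord(id=f"s{i}", age=20.0 + i, sex="F") for i in range(10)]
        cohort = Cohort(subjects, GRID, X)
        with pytest.raises(ValueError, match="rank"):
            decompose(cohort, n_components=3, seed=0)

    def test_too_many_components_rejected(self):
        cohort, _, _ = planted_mixture(n_subjects=10)
        with pytest.raises(ValueError, match="n_components"):
            decompose(cohort, n_components=11, seed=0)

    def test_sklearn_param_interface(self):
        est = SpatialICA(n_components=4, random_state=9)
        assert est.get_params()["n_components"] == 4
        est.set_params(n_components=2)
        assert est.n_components == 2


class TestScreening:
    def test_exact_linear_loading(self):
        ages = np.linspace(20, 80, 40)
        loadings = (-0.004 * ages)[:, None]
        res = screen_components(loadings, ages)[0]
        assert res.linear.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.monotone
        assert res.direction < 0

    def test_pure_quadratic_is_not_monotone(self):
        ages = np.linspace(20, 80, 40)
        loadings = (0.001 * (ages - 50.0) ** 2)[:, None]
        res = screen_components(loadings, ages)[0]
        assert res.quadratic.r_squared == pytest.approx(1.0, abs=1e-12)
        assert not res.monotone

    def test_constant_ages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            screen_components(np.zeros((5, 1)), np.full(5, 50.0))

    @pytest.mark.parametrize("degree", [1, 2])
    def test_p_value_matches_brute_force_f_statistic(self, degree):
        """p from the fit equals the F-test computed from residual sums of
        squares by explicit formula at small n."""
        rng = np.random.default_rng(8)
        n = 17
        ages = rng.uniform(20, 80, n)
        y = rng.normal(size=n)
        fit = polynomial_age_fit(y, ages, degree)
        # brute-force: design matrix OLS, RSS-based F
        X = np.vander(ages, degree + 1)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = np.sum((y - X @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        f = ((tss - rss) / degree) / (rss / (n - degree - 1))
        p = stats.f.sf(f, degree, n - degree - 1)
        assert fit.p_value == pytest.approx(p, abs=1e-10)
        assert fit.r_squared == pytest.approx(1 - rss / tss, abs=1e-10)

    def test_null_type_one_rate_small_batch(self):
        """Sanity-size version of the type-I calibration: quadratic screening
        p-values under the null reject at roughly the nominal rate."""
        rng = np.random.default_rng(123)
        ages = rng.uniform(20, 80, 100)
        loadings = rng.normal(size=(100, 60))
        res = screen_components(loadings, ages)
        rate = np.mean([r.p_value < 0.05 for r in res])
        assert 0.0 <= rate <= 0.15


class TestGroupedAssociation:
    def test_cumulative_final_row_equals_whole_sample(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(20, 80, 120)
        loading = -0.01 * ages + rng.normal(0, 0.2, 120)
        tabs = grouped_association(loading, ages, [20, 40, 60, 80])
        whole = polynomial_age_fit(loading, ages, 2)
        last = tabs["cumulative"].iloc[-1]
        assert last["n"] == 120
        assert last["p"] == pytest.approx(whole.p_value, rel=1e-12)
        assert last["R"] == pytest.approx(np.sqrt(whole.r_squared), rel=1e-12)

    def test_single_bin(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 80, 30)
        loading = rng.normal(size=30)
        tabs = grouped_association(loading, ages, [20, 80])
        assert len(tabs["per_group"]) == 1
        assert len(tabs["cumulative"]) == 1

    def test_thin_bin_skipped_with_warning(self):
        ages = np.array([21.0, 22, 23, 24, 25, 26, 27, 79])
        loading = np.arange(8.0)
        with pytest.warns(UserWarning, match="skipped"):
            tabs = grouped_association(loading, ages, [20, 70, 80])
        assert list(tabs["per_group"]["group"]) == ["20-70"]

    def test_similar_bins_give_similar_r_under_null(self):
        rng = np.random.default_rng(11)
        rs = {"20-30": [], "31-40": []}
        for _ in range(50):
            ages = np.concatenate([rng.uniform(20, 30, 60), rng.uniform(31, 40, 60)])
            loading = rng.normal(size=120)
            tabs = grouped_association(loading, ages, [20, 30.5, 40])
            for _, row in tabs["per_group"].iterrows():
                key = "20-30" if row["group"].startswith("20") else "31-40"
                rs[key].append(row["R"])
        m1, m2 = np.mean(rs["20-30"]), np.mean(rs["31-40"])
        assert abs(m1 - m2) < 0.05  # identical null distributions


def _assoc(idx, r2, p, monotone=True, direction=-1):
    fit = FitStats(2, r2, p, (0.0, -1.0, 0.0))
    lin = FitStats(1, r2, p, (float(direction), 0.0))
    return AssociationResult(idx, lin, fit, monotone, direction)


class TestSelectAgingComponent:
    def test_higher_r_squared_wins(self):
        results = [_assoc(0, 0.3, 1e-5), _assoc(1, 0.6, 1e-8)]
        assert select_aging_component(results) == 1

    def test_tie_broken_by_lower_index(self):
        results = [_assoc(0, 0.5, 1e-6), _assoc(1, 0.5, 1e-6)]
        assert select_aging_component(results) == 0

    def test_requires_monotone_negative_significant(self):
        results = [_assoc(0, 0.9, 1e-9, monotone=False),
                   _assoc(1, 0.9, 1e-9, direction=+1),
                   _assoc(2, 0.9, 0.2)]
        with pytest.raises(NoAgingComponentError):
            select_aging_component(results)

    def test_pure_noise_components_rejected(self):
        rng = np.random.default_rng(21)
        ages = rng.uniform(20, 80, 50)
        loadings = rng.normal(size=(50, 5))
        res = screen_components(loadings, ages)
        # force insignificance regardless of sampling accidents
        with pytest.raises(NoAgingComponentError):
            select_aging_component(res, alpha=1e-12)

    def test_oriented_flips_loading_and_map_together(self):
        cohort, _, _ = planted_mixture(n_subjects=30, age_linked=True, seed=4)
        cs = decompose(cohort, n_components=3, seed=0)
        res = screen_components(cs, cohort.ages)
        best = max(res, key=lambda r: r.r_squared).component_index
        flipped = cs.oriented(best, cohort.ages)
        slope = np.polyfit(cohort.ages, flipped.loadings[:, best], 1)[0]
        assert slope <= 0
        # product loading*map unchanged by the flip
        assert np.allclose(np.outer(flipped.loadings[:, best], flipped.maps[best]),
                           np.outer(cs.loadings[:, best], cs.maps[best]))
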