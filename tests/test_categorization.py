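"""Background thresholding, EM mixture fitting and category thresholds."""

import numpy as np
import pytest
from scipy.integrate import trapezoid

from ihc_catscore.categorization import (
    CategoryThresholds,
    MixtureModel,
    categorize_intensities,
    component_intersections,
    fit_gmm_em,
    global_threshold,
    kmeans_1d,
)
from ihc_catscore.errors import ComponentCollapseError, DegenerateDataWarning, ValidationError
from ihc_catscore.synthetic import generate_mixture_sample

FIG2_LIKE = MixtureModel(
    weights=(0.3, 0.4, 0.3), means=(40.0, 130.0, 205.0), sds=(15.0, 25.0, 12.0)
)


def otsu_brute_force(hist):
    """Independent oracle: exhaustive between-class-variance maximization.

    Evaluates w0*w1*(mu0 - mu1)^2 = (s0*w1 - s1*w0)^2 / (w0*w1) for every
    candidate threshold in exact integer arithmetic (cross-multiplied
    comparisons) and returns the smallest argmax.
    """
    counts = [int(c) for c in hist]
    total_w = sum(counts)
    total_s = sum(i * c for i, c in enumerate(counts))
    best_t, best_num, best_den = None, None, None
    w0 = s0 = 0
    for t in range(len(counts) - 1):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total_w - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (total_s - s0) * w0) ** 2
        den = w0 * w1
        if best_t is None or num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return best_t


class TestGlobalThreshold:
    def test_two_spike_histogram_tie_breaks_low(self):
        h = np.zeros(256)
        h[50] = 10
        h[200] = 10
        assert global_threshold(h) == 50

    def test_single_valued_histogram_flagged(self):
        h = np.zeros(256)
        h[123] = 7
        with pytest.warns(DegenerateDataWarning):
            assert global_threshold(h) == 123

    def test_override_bypasses_computation(self):
        h = np.zeros(256)
        h[50] = 10
        h[200] = 10
        assert global_threshold(h, override=230) == 230

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            global_threshold(np.zeros(256))

    def test_matches_brute_force_on_random_histograms(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            h = rng.integers(0, 500, size=256)
            h[rng.integers(0, 256, size=rng.integers(0, 200))] = 0
            if h.sum() == 0:
                continue
            assert global_threshold(h) == otsu_brute_force(h.tolist())


class TestKMeans1D:
    def test_three_well_separated_clusters(self):
        x = np.repeat([0.0, 100.0, 200.0], 10)
        res = kmeans_1d(x, k=3)
        np.testing.assert_allclose(res.centers, [0, 100, 200])

    def test_k1_center_is_mean(self, rng):
        x = rng.normal(50, 5, size=100)
        res = kmeans_1d(x, k=1)
        np.testing.assert_allclose(res.centers, [x.mean()])

    def test_inertia_never_increases(self, rng):
        x = rng.uniform(0, 255, size=500)
        res = kmeans_1d(x, k=4)
        assert np.all(np.diff(res.inertia_history) <= 1e-9)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValidationError, match="distinct"):
            kmeans_1d([1.0, 1.0, 2.0], k=3)

    def test_default_init_is_deterministic(self, rng):
        x = rng.uniform(0, 255, size=300)
        a = kmeans_1d(x, k=3)
        b = kmeans_1d(x, k=3)
        np.testing.assert_array_equal(a.centers, b.centers)


class TestEMFit:
    def test_parameter_recovery_fig2_like(self):
        x = generate_mixture_sample(FIG2_LIKE, 10_000, seed=42)
        fit = fit_gmm_em(x, k=3)
        assert np.abs(fit.means - FIG2_LIKE.means).max() < 2.0
        assert np.all(np.diff(fit.log_likelihood_history) >= -1e-8)

    def test_k1_is_sample_moments_fixed_point(self, rng):
        x = rng.normal(100, 20, size=500)
        fit = fit_gmm_em(x, k=1)
        np.testing.assert_allclose(fit.means, [x.mean()], rtol=1e-12)
        np.testing.assert_allclose(fit.sds, [x.std()], rtol=1e-12)

    def test_single_gaussian_data_fit_with_k3_matches_density(self):
        rng = np.random.default_rng(3)
        x = rng.normal(130, 25, size=20_000)
        fit = fit_gmm_em(x, k=3)
        grid = np.linspace(0, 255, 2551)
        truth = np.exp(-0.5 * ((grid - 130) / 25) ** 2) / (25 * np.sqrt(2 * np.pi))
        tv = 0.5 * trapezoid(np.abs(fit.pdf(grid) - truth), grid)
        assert tv < 0.02

    def test_matches_reference_em_implementation(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        x = generate_mixture_sample(FIG2_LIKE, 5_000, seed=11)
        ours = fit_gmm_em(x, k=3)
        ref = sklearn.GaussianMixture(3, n_init=5, random_state=0).fit(x[:, None])
        np.testing.assert_allclose(
            ours.means, np.sort(ref.means_.ravel()), atol=1.0
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_gmm_em(np.arange(10.0), k=3)

    def test_component_collapse_diagnosed(self):
        # 30 copies of two values cannot support three components
        x = np.repeat([50.0, 200.0], 15)
        with pytest.raises((ComponentCollapseError, ValidationError)):
            fit_gmm_em(x, k=3)


class TestIntersections:
    def test_symmetric_midpoint(self):
        m = MixtureModel(weights=(0.5, 0.5), means=(50.0, 150.0), sds=(10.0, 10.0))
        (t,) = component_intersections(m)
        assert t == pytest.approx(100.0, abs=1e-9)

    def test_equal_sigma_closed_form(self):
        for w1 in (0.2, 0.5, 0.7):
            m = MixtureModel(weights=(w1, 1 - w1), means=(60.0, 170.0), sds=(12.0, 12.0))
            (t,) = component_intersections(m)
            expected = (60 + 170) / 2 + 12**2 * np.log(w1 / (1 - w1)) / (170 - 60)
            assert t == pytest.approx(expected, abs=1e-9)

    def test_unequal_sigma_matches_grid_search(self, rng):
        for _ in range(20):
            mu = np.sort(rng.uniform(20, 230, size=2))
            if mu[1] - mu[0] < 20:
                continue
            w1 = rng.uniform(0.2, 0.8)
            m = MixtureModel(
                weights=(w1, 1 - w1),
                means=tuple(mu),
                sds=tuple(rng.uniform(5, 25, size=2)),
            )
            (t,) = component_intersections(m)
            grid = np.arange(mu[0], mu[1], 0.001)
            diff = m.component_density(grid, 0) - m.component_density(grid, 1)
            sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
            assert sign_change.size > 0
            t_grid = grid[sign_change[0]]
            assert abs(t - t_grid) < 0.01

    def test_k3_thresholds_ordered(self):
        t1, t2 = component_intersections(FIG2_LIKE)
        assert t1 < t2

    def test_equal_means_rejected(self):
        m = MixtureModel(weights=(0.5, 0.5), means=(100.0, 100.0), sds=(10.0, 20.0))
        with pytest.raises(ValidationError, match="ascending"):
            component_intersections(m)

    def test_unweighted_option_ignores_weights(self):
        m = MixtureModel(weights=(0.1, 0.9), means=(50.0, 150.0), sds=(10.0, 10.0))
        (t,) = component_intersections(m, weighted=False)
        assert t == pytest.approx(100.0, abs=1e-9)


class TestCategorize:
    HER2 = CategoryThresholds(t0=230, t1=85, t2=180)

    def test_paper_interval_examples(self):
        cats, _ = categorize_intensities([40, 120, 200, 250], self.HER2)
        assert cats.tolist() == ["strong", "moderate", "weak", "negative"]

    def test_boundary_values_go_to_stronger_side(self):
        cats, _ = categorize_intensities([85, 180, 230], self.HER2)
        assert cats.tolist() == ["strong", "moderate", "weak"]

    def test_all_negative_flagged(self):
        cats, frac = categorize_intensities([240, 250], self.HER2)
        assert frac.all_negative
        assert frac.as_tuple() == (0.0, 0.0, 0.0)

    def test_fractions_sum_to_one_over_positive_denominator(self, rng):
        vals = rng.uniform(0, 255, size=1000)
        _, frac = categorize_intensities(vals, self.HER2)
        assert frac.weak + frac.moderate + frac.strong == pytest.approx(1.0)

    def test_all_cells_denominator_counts_negatives(self):
        _, frac = categorize_intensities([40, 250], self.HER2, denominator="all")
        assert frac.strong == pytest.approx(0.5)

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError):
            CategoryThresholds(t0=230, t1=180, t2=85)


class TestThresholdRecovery:
    def test_em_thresholds_near_true_intersections_over_replicates(self):
        """Median recovered thresholds across seeded replicates stay within
        a few grey levels of the analytic intersections of the true mixture."""
        true_t = component_intersections(FIG2_LIKE)
        errs_mu, errs_t = [], []
        for seed in range(20):
            x = generate_mixture_sample(FIG2_LIKE, 10_000, seed=seed)
            fit = fit_gmm_em(x, k=3)
            errs_mu.append(np.abs(fit.means - FIG2_LIKE.means).max())
            fit_t = component_intersections(fit)
            errs_t.append(np.abs(np.array(fit_t) - np.array(true_t)).max())
        assert np.median(errs_mu) < 2.0
        assert np.median(errs_t) < 3.0
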