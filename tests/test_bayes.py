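"""Gaussian Bayes classifier: analytic accuracy, ROC identities, grid search."""

import numpy as np
import pytest
from scipy import integrate, stats

from mirbayes import (
    GaussianClassModel,
    analytic_accuracy,
    fit_gaussian_classes,
    grid_search_combination,
    roc_curve,
    shapiro_wilk,
)

# fixed 20-value vector with its Shapiro-Wilk result frozen from an
# independent reference implementation (R stats::shapiro.test)
SHAPIRO_VECTOR = [
    0.532143, -0.933626, 1.041661, 1.208501, -1.71752, -1.243788, 0.267857,
    -0.303101, 0.029486, -0.648129, 1.102827, 1.068045, 0.163778, 1.238379,
    0.608376, -0.802451, 0.407727, -0.816171, 0.946523, 0.151018,
]
SHAPIRO_W_REF = 0.9331212728
SHAPIRO_P_REF = 0.1772893149


def bayes_accuracy_quadrature(model):
    """Independent oracle: integrate max of the prior-weighted densities."""
    f = lambda x: max(
        model.prior0 * stats.norm.pdf(x, model.mu0, model.sigma0),
        model.prior1 * stats.norm.pdf(x, model.mu1, model.sigma1),
    )
    val, _ = integrate.quad(f, -60, 60, limit=400)
    return val


class TestAnalyticAccuracy:
    def test_identical_classes_chance(self):
        acc, thr = analytic_accuracy(GaussianClassModel(0, 1, 0, 1))
        assert acc == 0.5 and thr == []

    def test_equal_variance_closed_form(self):
        acc, thr = analytic_accuracy(GaussianClassModel(0, 1, 2, 1))
        assert thr == [1.0]
        assert acc == pytest.approx(stats.norm.cdf(1.0), abs=1e-10)

    def test_equal_variance_midpoint_threshold(self, rng):
        for _ in range(20):
            mu0, mu1 = rng.normal(0, 5, 2)
            s = rng.uniform(0.2, 3)
            if mu0 == mu1:
                continue
            _, thr = analytic_accuracy(GaussianClassModel(mu0, s, mu1, s))
            assert thr[0] == pytest.approx((mu0 + mu1) / 2, abs=1e-12)

    def test_unequal_variance_matches_quadrature(self):
        model = GaussianClassModel(0, 1, 0, 2)
        acc, thr = analytic_accuracy(model)
        assert len(thr) == 2
        assert acc == pytest.approx(bayes_accuracy_quadrature(model), abs=1e-6)

    def test_random_models_match_quadrature(self, rng):
        for _ in range(30):
            m = GaussianClassModel(
                rng.normal(0, 3), rng.uniform(0.3, 3),
                rng.normal(0, 3), rng.uniform(0.3, 3),
                *(lambda p: (p, 1 - p))(rng.uniform(0.2, 0.8)),
            )
            acc, _ = analytic_accuracy(m)
            # adaptive quadrature loses a few 1e-7 at the density-crossing kink
            assert acc == pytest.approx(bayes_accuracy_quadrature(m), abs=1e-6)
            assert acc >= max(m.prior0, m.prior1) - 1e-12

    def test_no_real_root_degenerates_to_prior(self):
        # narrow class nested far inside a wide one, tiny prior: the
        # quadratic may have no real roots and one class always wins
        m = GaussianClassModel(0.0, 10.0, 0.0, 0.1, 0.999, 0.001)
        acc, thr = analytic_accuracy(m)
        if not thr:
            assert acc == pytest.approx(max(m.prior0, m.prior1))


class TestFit:
    def test_two_point_sample(self):
        m = fit_gaussian_classes([-1, 1, 4, 6], [0, 0, 1, 1])
        assert m.mu0 == 0 and m.sigma0 == pytest.approx(np.sqrt(2))
        assert m.mu1 == 5 and m.prior0 == 0.5

    def test_matches_two_pass_reference(self, rng):
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(1, 2, 50)])
        y = np.r_[np.zeros(50), np.ones(50)]
        m = fit_gaussian_classes(x, y)
        ref_mean = sum(x[:50]) / 50
        ref_sd = np.sqrt(sum((v - ref_mean) ** 2 for v in x[:50]) / 49)
        assert m.mu0 == pytest.approx(ref_mean, abs=1e-12)
        assert m.sigma0 == pytest.approx(ref_sd, abs=1e-12)

    def test_equal_classes_give_chance_accuracy(self):
        x = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        m = fit_gaussian_classes(x, [0, 0, 0, 1, 1, 1])
        acc, _ = analytic_accuracy(m)
        assert acc == 0.5

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_gaussian_classes([1, 1, 2, 3], [0, 0, 1, 1])


class TestRoc:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 4], [0, 0, 1, 1], positive_class=1)
        assert r.auc == 1.0 and r.best_accuracy == 1.0

    def test_pure_ties_chance(self):
        r = roc_curve([5, 5, 5, 5], [0, 0, 1, 1], positive_class=1)
        assert r.auc == pytest.approx(0.5)

    def test_brute_force_pair_counting(self):
        # {1,3} vs {2,4}: 3 of 4 cross-class pairs concordant
        r = roc_curve([1, 3, 2, 4], [0, 0, 1, 1], positive_class=1)
        assert r.auc == pytest.approx(0.75, abs=1e-12)

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(50):
            n0, n1 = rng.integers(3, 25, 2)
            scores = np.round(rng.normal(0, 1, n0 + n1), 1)  # forces ties
            y = np.r_[np.zeros(n0), np.ones(n1)]
            r = roc_curve(scores, y, positive_class=1)
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            auc_mw = u / (n0 * n1)
            assert r.auc == pytest.approx(max(auc_mw, 1 - auc_mw), abs=1e-10)

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[:2], y[-2:] = 0, 1
        base = roc_curve(scores, y, positive_class=1).auc
        for f in (np.exp, np.arctan, lambda s: s**3, lambda s: 5 * s - 2):
            assert roc_curve(f(scores), y, positive_class=1).auc == pytest.approx(
                base, abs=1e-12
            )

    def test_best_accuracy_beats_majority_vote(self, rng):
        scores = rng.normal(0, 1, 60)
        y = np.r_[np.zeros(40), np.ones(20)]
        r = roc_curve(scores, y, positive_class=1)
        assert r.best_accuracy >= max(1 / 3, 2 / 3) - 1 / 60

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2, 3], [0, 0, 0], positive_class=1)


class TestShapiro:
    def test_statistic_range(self, rng):
        w, _ = shapiro_wilk(rng.normal(0, 1, 30))
        assert 0 < w <= 1

    def test_matches_reference_implementation(self):
        w, p = shapiro_wilk(SHAPIRO_VECTOR)
        assert w == pytest.approx(SHAPIRO_W_REF, abs=1e-6)
        assert p == pytest.approx(SHAPIRO_P_REF, abs=1e-6)

    def test_two_point_mass_detected(self, rng):
        x = rng.choice([0.0, 1.0], size=50)
        _, p = shapiro_wilk(x)
        assert p < 0.01

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestGridSearch:
    def _fixture(self, rng, n=10):
        x0 = rng.normal([0, 0.5, -0.5], 1.0, (n, 3))
        x1 = rng.normal([1.5, 1.0, 0.5], 1.2, (n, 3))
        x = np.vstack([x0, x1])
        y = np.r_[np.zeros(n), np.ones(n)]
        return x, y

    def test_coarse_grid_matches_exhaustive_oracle(self, rng):
        x, y = self._fixture(rng)
        combo = grid_search_combination(
            x, y, positive_class=1, coeff_range=(-50, 50), step=10.0
        )
        # brute force: refit a model per grid point, no shortcuts
        best = (-1.0, None)
        for a in np.arange(-50, 51, 10.0):
            for b in np.arange(-50, 51, 10.0):
                score = x[:, 0] + a * x[:, 1] + b * x[:, 2]
                m = fit_gaussian_classes(score, y)
                acc, _ = analytic_accuracy(m)
                if acc > best[0] + 1e-12:
                    best = (acc, (a, b))
        assert (combo.a, combo.b) == best[1]
        assert combo.accuracy == pytest.approx(best[0], abs=1e-9)

    def test_constant_extra_markers_reduce_to_single_marker(self, rng):
        n = 12
        x1 = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        x = np.column_stack([x1, np.full(2 * n, 3.0), np.full(2 * n, -1.0)])
        y = np.r_[np.zeros(n), np.ones(n)]
        single = fit_gaussian_classes(x1, y)
        acc_single, _ = analytic_accuracy(single)
        combo = grid_search_combination(
            x, y, positive_class=1, coeff_range=(-2, 2), step=1.0
        )
        assert combo.accuracy == pytest.approx(acc_single, abs=1e-9)
        # constants only shift the score: tie-break picks the origin
        assert (combo.a, combo.b) == (0.0, 0.0)

    def test_noise_markers_suppressed(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            n = 25
            x1 = np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)])
            noise = rng.normal(0, 10, (2 * n, 2))
            x = np.column_stack([x1, noise])
            y = np.r_[np.zeros(n), np.ones(n)]
            combo = grid_search_combination(
                x, y, positive_class=1, coeff_range=(-10, 10), step=0.1
            )
            hits += abs(combo.a) <= 0.5 and abs(combo.b) <= 0.5
        assert hits >= 18

    def test_non_binary_labels_rejected(self, rng):
        x, _ = self._fixture(rng)
        with pytest.raises(ValueError, match="binary|two"):
            grid_search_combination(x, np.arange(len(x)) % 3)

    def test_reported_model_reproduces_score(self, rng):
        x, y = self._fixture(rng)
        combo = grid_search_combination(
            x, y, positive_class=1, coeff_range=(-5, 5), step=0.5
        )
        rebuilt = x[:, 0] + combo.a * x[:, 1] + combo.b * x[:, 2]
        assert np.allclose(rebuilt, combo.scores)
        assert set(combo.shapiro) == {"0.0", "1.0"}
        for w, p in combo.shapiro.values():
            assert 0 < w <= 1 and 0 <= p <= 1
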