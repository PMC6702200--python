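"""Cost matrices, discriminant fitting, posteriors and decisions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import pvtvuln as pv
from pvtvuln import lda
from pvtvuln.stratify import CLASSES


def _gaussian_data(rng, n_per=(30, 60, 30), dim=3, sep=2.0):
    means = np.vstack([np.zeros(dim), np.full(dim, sep), np.full(dim, 2 * sep)])
    X, y = [], []
    for k, n in enumerate(n_per):
        X.append(rng.normal(means[k], 1.0, (n, dim)))
        y += [CLASSES[k]] * n
    return np.vstack(X), np.array(y, dtype=object)


class TestCostMatrix:
    def test_uniform_at_one(self):
        m = pv.make_cost_matrix(1.0).matrix
        assert np.all(m[~np.eye(3, dtype=bool)] == 1.0)
        assert np.all(np.diag(m) == 0.0)

    def test_extreme_classes_weighted(self):
        m = pv.make_cost_matrix(3.0).matrix
        # rows are true classes in (resilient, intermediate, vulnerable) order
        assert m[2, 1] == 3.0      # vulnerable mistaken for intermediate
        assert m[1, 2] == 1.0      # intermediate mistaken for vulnerable
        assert m[0, 2] == 3.0

    def test_grid_has_nine_matrices(self):
        assert pv.cost_grid() == [1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0]

    def test_invalid_scalar(self):
        with pytest.raises(ValueError):
            pv.make_cost_matrix(0.5)

    def test_arbitrary_matrix_accepted(self):
        m = np.array([[0, 2, 1], [1, 0, 1], [5, 2, 0]], dtype=float)
        assert lda.CostMatrix(m).scalar is None
        with pytest.raises(ValueError):
            lda.CostMatrix(np.eye(3))


class TestFit:
    def test_one_dimensional_boundary_at_midpoint(self):
        # two well-separated 1-D classes with equal size/variance: the
        # decision boundary sits at the midpoint of the class means
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(-3, 1e-3, 20), rng.normal(3, 1e-3, 20),
                            rng.normal(50, 1e-3, 4)])[:, None]
        y = np.array(["resilient"] * 20 + ["intermediate"] * 20
                     + ["vulnerable"] * 4, dtype=object)
        model = lda.fit(X, y)
        m_r = X[:20].mean()
        m_i = X[20:40].mean()
        mid = (m_r + m_i) / 2
        eps = 0.05
        assert lda.predict(model, np.array([[mid - eps]]))[0] == "resilient"
        assert lda.predict(model, np.array([[mid + eps]]))[0] == "intermediate"

    def test_z_scoring_uses_training_moments(self):
        rng = np.random.default_rng(1)
        X, y = _gaussian_data(rng)
        model = lda.fit(X, y)
        Z = (X - model.z_mu) / model.z_sigma
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)

    def test_requires_two_per_class(self):
        X = np.arange(8, dtype=float)[:, None]
        y = np.array(["resilient"] * 4 + ["intermediate"] * 3 + ["vulnerable"],
                     dtype=object)
        with pytest.raises(ValueError):
            lda.fit(X, y)

    def test_empty_subset_prior_only_model(self):
        y = np.array(["resilient"] * 10 + ["intermediate"] * 20
                     + ["vulnerable"] * 10, dtype=object)
        X = pd.DataFrame(index=range(40))
        model = lda.fit(X, y, subset=())
        P = lda.posterior(model, np.empty((5, 0)))
        np.testing.assert_allclose(P, np.tile([0.25, 0.5, 0.25], (5, 1)))
        assert all(lda.predict(model, np.empty((5, 0))) == "intermediate")


class TestPosterior:
    def test_matches_gaussian_density_oracle(self):
        rng = np.random.default_rng(2)
        X, y = _gaussian_data(rng, sep=1.0)
        model = lda.fit(X, y)
        # oracle: Bayes posterior from the model's fitted Gaussians
        Z = (X - model.z_mu) / model.z_sigma
        yidx = np.array([CLASSES.index(l) for l in y])
        means = np.vstack([Z[yidx == k].mean(axis=0) for k in range(3)])
        pooled = sum((Z[yidx == k] - means[k]).T @ (Z[yidx == k] - means[k])
                     for k in range(3)) / (len(y) - 3)
        pts = rng.normal(1.0, 2.0, (50, X.shape[1]))
        zpts = (pts - model.z_mu) / model.z_sigma
        dens = np.vstack([model.priors[k]
                          * multivariate_normal.pdf(zpts, means[k], pooled)
                          for k in range(3)]).T
        oracle = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(lda.posterior(model, pts), oracle, atol=1e-9)

    def test_sums_to_one(self):
        rng = np.random.default_rng(3)
        X, y = _gaussian_data(rng)
        model = lda.fit(X, y)
        P = lda.posterior(model, rng.normal(3, 4, (200, X.shape[1])))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_class_means_give_priors(self):
        rng = np.random.default_rng(4)
        n = 80
        X = rng.normal(0, 1, (n, 2))
        y = np.array(["resilient"] * 20 + ["intermediate"] * 40
                     + ["vulnerable"] * 20, dtype=object)
        model = lda.fit(X, y)
        # force exactly identical class means
        model.weights[:] = 0.0
        model.constants[:] = np.log(model.priors)
        P = lda.posterior(model, rng.normal(0, 1, (10, 2)))
        np.testing.assert_allclose(P, np.tile(model.priors, (10, 1)), atol=1e-12)

    def test_missing_feature_undefined_prediction(self):
        rng = np.random.default_rng(5)
        X, y = _gaussian_data(rng)
        model = lda.fit(X, y)
        q = X[:3].copy()
        q[1, 0] = np.nan
        pred = lda.predict(model, q)
        assert pred[1] is None and pred[0] is not None

    def test_matches_sklearn_class_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(6)
        X, y = _gaussian_data(rng, sep=1.5)
        model = lda.fit(X, y)
        sk = LinearDiscriminantAnalysis().fit(X, y)
        ours = lda.predict(model, X)
        agree = np.mean([a == b for a, b in zip(ours, sk.predict(X))])
        assert agree > 0.98


class TestDecide:
    def test_uniform_cost_is_argmax(self):
        assert lda.decide([0.5, 0.3, 0.2], pv.make_cost_matrix(1.0)) == "resilient"

    def test_worked_cost_example(self):
        # posteriors (R .30, I .36, V .34) at c = 3: expected costs are
        # R: 3*.36? no - cost of predicting R = C[I,R]*.36 + C[V,R]*.34
        p = np.array([0.30, 0.36, 0.34])
        cm = pv.make_cost_matrix(3.0)
        exp = cm.matrix.T @ p
        # hand enumeration: predict R -> 1*.36 + 3*.34 = 1.38
        #                   predict I -> 3*.30 + 3*.34 = 1.92
        #                   predict V -> 3*.30 + 1*.36 = 1.26
        np.testing.assert_allclose(exp, [1.38, 1.92, 1.26])
        assert lda.decide(p, cm) == "vulnerable"

    def test_exact_tie_takes_lowest_class(self):
        assert lda.decide([1 / 3, 1 / 3, 1 / 3], pv.make_cost_matrix(1.0)) == "resilient"

    def test_cost_one_equals_argmax_on_random_simplex(self):
        rng = np.random.default_rng(7)
        P = rng.dirichlet([1, 1, 1], 10_000)
        cm = pv.make_cost_matrix(1.0)
        for p in P:
            assert lda.decide(p, cm) == CLASSES[int(np.argmax(p))]

    def test_higher_cost_weakly_increases_extreme_predictions(self):
        rng = np.random.default_rng(8)
        X, y = _gaussian_data(rng, sep=0.7)
        model = lda.fit(X, y)
        P = lda.posterior(model, rng.normal(1, 2, (500, X.shape[1])))
        n_extreme = []
        for c in (1.0, 2.0, 3.0, 5.0):
            cm = pv.make_cost_matrix(c)
            preds = [lda.decide(p, cm) for p in P]
            n_extreme.append(sum(p != "intermediate" for p in preds))
        assert n_extreme == sorted(n_extreme)


class TestInvariances:
    def test_feature_scale_equivariance(self):
        rng = np.random.default_rng(9)
        X, y = _gaussian_data(rng)
        scale = np.array([10.0, 1.0, 0.01])
        m1 = lda.fit(X, y)
        m2 = lda.fit(X * scale, y)
        pts = rng.normal(2, 2, (40, X.shape[1]))
        np.testing.assert_allclose(lda.posterior(m1, pts),
                                   lda.posterior(m2, pts * scale), atol=1e-9)

    def test_full_shrinkage_diagonal_lda_well_defined(self):
        rng = np.random.default_rng(10)
        X, y = _gaussian_data(rng)
        model = lda.fit(X, y, shrinkage=1.0)
        assert model.shrinkage == 1.0
        P = lda.posterior(model, X)
        assert np.isfinite(P).all()

    def test_singular_covariance_climbs_ladder(self):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, (40, 1))
        X = np.hstack([base, base])          # perfectly collinear
        y = np.array(["resilient"] * 10 + ["intermediate"] * 20
                     + ["vulnerable"] * 10, dtype=object)
        model = lda.fit(X, y)
        assert model.shrinkage > 0.0
        assert np.isfinite(lda.posterior(model, X)).all()

    def test_json_round_trip_reproduces_predictions(self):
        rng = np.random.default_rng(12)
        X, y = _gaussian_data(rng)
        model = lda.fit(pd.DataFrame(X, columns=["a", "b", "c"]), y,
                        cost=pv.make_cost_matrix(2.5))
        back = lda.DiscriminantModel.from_json(model.to_json())
        pts = rng.normal(2, 2, (30, 3))
        np.testing.assert_array_equal(lda.predict(model, pts),
                                      lda.predict(back, pts))
        np.testing.assert_allclose(lda.posterior(model, pts),
                                   lda.posterior(back, pts))
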