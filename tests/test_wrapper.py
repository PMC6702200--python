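"""Stratified folds, subset scoring and the best-first search."""

import hashlib

import numpy as np
import pandas as pd
import pytest

import pvtvuln as pv
from pvtvuln import lda, wrapper as wr
from pvtvuln.stratify import CLASSES


def labels_121(n):
    q = n // 4
    return pd.Series(["resilient"] * q + ["intermediate"] * (n - 2 * q)
                     + ["vulnerable"] * q,
                     index=[f"P{i:03d}" for i in range(n)])


def planted_frame(rng, n=160, n_noise=20, informative=True):
    y = labels_121(n)
    cols = {f"noise{i:02d}": rng.normal(0, 1, n) for i in range(n_noise)}
    if informative:
        code = y.map({"resilient": 0.0, "intermediate": 1.0, "vulnerable": 2.0})
        cols["signal"] = code.to_numpy() + rng.normal(0, 0.05, n)
    return pd.DataFrame(cols, index=y.index), y


class TestStratifiedFolds:
    @pytest.mark.parametrize("n,per_fold", [(160, (8, 16, 8)), (60, (3, 6, 3))])
    def test_exact_fold_composition(self, n, per_fold):
        y = labels_121(n)
        folds = pv.stratified_folds(y, 5, seed=0)
        for f in range(5):
            sub = y[folds == f]
            assert (sub == "resilient").sum() == per_fold[0]
            assert (sub == "intermediate").sum() == per_fold[1]
            assert (sub == "vulnerable").sum() == per_fold[2]

    def test_seed_determinism(self):
        y = labels_121(60)
        a = pv.stratified_folds(y, 5, seed=1)
        b = pv.stratified_folds(y, 5, seed=1)
        c = pv.stratified_folds(y, 5, seed=2)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_small_class_rejected(self):
        y = pd.Series(["resilient"] * 3 + ["intermediate"] * 10
                      + ["vulnerable"] * 10)
        with pytest.raises(ValueError):
            pv.stratified_folds(y, 5, seed=0)

    def test_near_proportional_when_not_divisible(self):
        y = labels_121(37)   # 9 / 19 / 9
        folds = pv.stratified_folds(y, 5, seed=3)
        for cls in CLASSES:
            counts = [((folds == f) & (y == cls).to_numpy()).sum() for f in range(5)]
            assert max(counts) - min(counts) <= 1


class TestEvaluateSubset:
    def test_perfectly_separating_feature(self):
        rng = np.random.default_rng(0)
        X, y = planted_frame(rng, n=80, n_noise=3)
        cv = wr.CVConfig(repeats=5, seed=0)
        mean, sd = pv.evaluate_subset(X, y, ("signal",), 1.0, cv)
        assert mean > 0.95

    def test_pure_noise_predictions_carry_no_label_information(self):
        # on uninformative features the classifier drifts to its priors, so
        # the right null is independence given its own prediction marginals:
        # accuracy ~= sum_k q_k p_k (q = prediction marginal, p = truth
        # marginal) and kappa ~= 0
        rng = np.random.default_rng(1)
        X, y = planted_frame(rng, n=160, informative=False)
        cv = wr.CVConfig(repeats=10, seed=1)
        preds = pv.cross_validate(X, y, ("noise00", "noise01"), 1.0, cv)
        flat = preds.to_numpy().ravel()
        q = np.array([(flat == c).mean() for c in CLASSES])
        p = np.array([(y == c).mean() for c in CLASSES])
        expected = float(q @ p)
        mean, sd = pv.evaluate_subset(X, y, ("noise00", "noise01"), 1.0, cv)
        se = np.sqrt(expected * (1 - expected) / len(y))
        assert abs(mean - expected) <= 3 * se
        kappas = [pv.kappa(pv.confusion(y, preds[c])) for c in preds.columns]
        assert abs(np.mean(kappas)) < 0.1

    def test_bit_identical_under_seed(self):
        rng = np.random.default_rng(2)
        X, y = planted_frame(rng, n=60, n_noise=4)
        cv = wr.CVConfig(repeats=4, seed=5)
        assert pv.evaluate_subset(X, y, ("signal", "noise00"), 2.0, cv) == \
            pv.evaluate_subset(X, y, ("signal", "noise00"), 2.0, cv)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(3)
        X, y = planted_frame(rng, n=80, n_noise=2)
        X.loc[X.index[0], "signal"] = np.nan
        cv = wr.CVConfig(repeats=3, seed=0)
        mean, _ = pv.evaluate_subset(X, y, ("signal",), 1.0, cv)
        assert mean > 0.9


class TestBestFirstSearch:
    def test_recovers_planted_feature(self):
        rng = np.random.default_rng(4)
        X, y = planted_frame(rng)
        res = pv.best_first_search(X, y, list(X.columns),
                                   cost_scalars=[1.0, 2.0],
                                   cv=wr.CVConfig(repeats=5, seed=0))
        assert "signal" in res.subset

    def test_single_candidate_terminates_quickly(self):
        rng = np.random.default_rng(5)
        X, y = planted_frame(rng, n=60, n_noise=1, informative=False)
        res = pv.best_first_search(X, y, ["noise00"], cost_scalars=[1.0],
                                   cv=wr.CVConfig(repeats=3, seed=0))
        assert res.n_expansions <= 2

    def test_all_noise_terminates_by_patience(self):
        rng = np.random.default_rng(6)
        X, y = planted_frame(rng, n=60, n_noise=6, informative=False)
        res = pv.best_first_search(X, y, list(X.columns), cost_scalars=[1.0],
                                   cv=wr.CVConfig(repeats=3, seed=0),
                                   patience=2)
        assert res.n_expansions <= 2 + 25   # improvements can reset patience

    def test_trace_global_best_monotone(self):
        rng = np.random.default_rng(7)
        X, y = planted_frame(rng, n=60, n_noise=5)
        res = pv.best_first_search(X, y, list(X.columns), cost_scalars=[1.0, 3.0],
                                   cv=wr.CVConfig(repeats=3, seed=0))
        running = res.trace.groupby("iteration")["mean_acc"].max().cummax()
        assert (running.diff().dropna() >= -1e-12).all()
        assert res.score == pytest.approx(res.trace["mean_acc"].max())

    def test_degenerate_grid_reduces_to_accuracy_search(self):
        rng = np.random.default_rng(8)
        X, y = planted_frame(rng, n=60, n_noise=3)
        res = pv.best_first_search(X, y, list(X.columns), cost_scalars=[1.0],
                                   cv=wr.CVConfig(repeats=3, seed=0))
        assert res.cost_scalar == 1.0

    def test_search_deterministic(self):
        rng = np.random.default_rng(9)
        X, y = planted_frame(rng, n=60, n_noise=4)
        kw = dict(cost_scalars=[1.0, 2.0], cv=wr.CVConfig(repeats=3, seed=1))
        a = pv.best_first_search(X, y, list(X.columns), **kw)
        b = pv.best_first_search(X, y, list(X.columns), **kw)
        assert a.subset == b.subset and a.score == b.score
        pd.testing.assert_frame_equal(a.trace, b.trace)


class TestLeakageAndFinalFit:
    def test_heldout_label_permutation_leaves_fold_models_identical(self):
        rng = np.random.default_rng(10)
        X, y = planted_frame(rng, n=80, n_noise=2)
        M = X[["signal", "noise00"]].to_numpy()
        folds = pv.stratified_folds(y, 5, seed=0)

        def fold_hashes(labels):
            hashes = []
            for f in range(5):
                train = folds != f
                model = lda.fit(M[train], labels[train].to_numpy())
                hashes.append(hashlib.sha256(model.to_json().encode()).hexdigest())
            return hashes

        y_perm = y.copy()
        test = folds == 0
        y_perm[test] = rng.permutation(y_perm[test].to_numpy())
        assert fold_hashes(y)[0] == fold_hashes(y_perm)[0]

    def test_final_fit_optimism(self):
        # training accuracy of the refit model is not below its CV estimate
        deltas = []
        for rep in range(5):
            rng = np.random.default_rng(20 + rep)
            X, y = planted_frame(rng, n=80, n_noise=6, informative=False)
            subset = ("noise00", "noise01", "noise02")
            cv = wr.CVConfig(repeats=5, seed=rep)
            cv_mean, _ = pv.evaluate_subset(X, y, subset, 1.0, cv)
            model = pv.fit_final(X, y, subset, 1.0)
            train_acc = np.mean(lda.predict(model, X[list(subset)].to_numpy())
                                == y.to_numpy())
            deltas.append(train_acc - cv_mean)
        assert np.mean(deltas) >= 0

    def test_empty_subset_majority_model(self):
        y = labels_121(40)
        X = pd.DataFrame(index=y.index)
        model = pv.fit_final(X, y, (), 1.0)
        pred = lda.predict(model, np.empty((len(y), 0)))
        assert all(p == "intermediate" for p in pred)
        assert np.mean(pred == y.to_numpy()) == 0.5

    def test_cross_validate_shape_and_determinism(self):
        rng = np.random.default_rng(11)
        X, y = planted_frame(rng, n=60, n_noise=2)
        cv = wr.CVConfig(repeats=6, seed=2)
        a = pv.cross_validate(X, y, ("signal",), 1.0, cv)
        b = pv.cross_validate(X, y, ("signal",), 1.0, cv)
        assert a.shape == (60, 6)
        pd.testing.assert_frame_equal(a, b)
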