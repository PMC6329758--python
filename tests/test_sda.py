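import numpy as np
import pytest
from scipy.stats import ortho_group

import multilink as ml
from multilink.sda import SparseDiscriminantAnalysis

from cd_oracle import cd_elastic_net


class TestSolveElasticNet:
    def test_orthonormal_design_soft_threshold(self):
        """With X^T X = I and gamma=0 the one-variable solution is the
        largest |x_j^T y|, soft-thresholded at the runner-up correlation."""
        rng = np.random.default_rng(0)
        Q = ortho_group.rvs(8, random_state=rng)
        X = Q[:, :5]
        y = rng.standard_normal(8)
        c = X.T @ y
        beta, eta = ml.solve_elastic_net(X, y, 1, 0.0, return_eta=True)
        j = np.argmax(np.abs(c))
        assert beta.nonzero()[0].tolist() == [j]
        order = np.sort(np.abs(c))
        expected = np.sign(c[j]) * (order[-1] - order[-2])
        assert beta[j] == pytest.approx(expected, abs=1e-10)

    def test_huge_ridge_shrinks_weights(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        beta = ml.solve_elastic_net(X, y, 3, 1e8)
        assert np.linalg.norm(beta) < 1e-4

    def test_matches_coordinate_descent_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 20))
        y = rng.standard_normal(10)
        beta, eta = ml.solve_elastic_net(X, y, 3, 0.1, return_eta=True)
        oracle = cd_elastic_net(X, y, eta, 0.1)
        np.testing.assert_allclose(beta, oracle, atol=1e-6)

    def test_kkt_conditions_at_returned_eta(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 25))
        y = rng.standard_normal(15)
        for gamma in (0.0, 0.5):
            beta, eta = ml.solve_elastic_net(X, y, 4, gamma, return_eta=True)
            grad = X.T @ (y - X @ beta) - gamma * beta
            active = np.flatnonzero(beta)
            inactive = np.setdiff1d(np.arange(25), active)
            assert np.abs(np.abs(grad[active]) - eta / 2).max() < 1e-6
            assert np.abs(grad[inactive]).max() <= eta / 2 + 1e-6

    def test_sparsity_never_exceeds_alpha(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 30))
        y = rng.standard_normal(10)
        for a in (1, 5, 9):
            assert np.count_nonzero(ml.solve_elastic_net(X, y, a, 0.2)) <= a

    @pytest.mark.parametrize(
        "bad", [dict(alpha_stop=31), dict(alpha_stop=0), dict(gamma=-1.0)]
    )
    def test_parameter_validation(self, bad):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 30))
        y = rng.standard_normal(10)
        kw = dict(alpha_stop=3, gamma=0.1)
        kw.update(bad)
        with pytest.raises(ml.DataError):
            ml.solve_elastic_net(X, y, **kw)

    def test_constant_response_rejected(self):
        X = np.random.default_rng(6).standard_normal((8, 4))
        with pytest.raises(ml.DataError, match="constant"):
            ml.solve_elastic_net(X, np.ones(8), 2, 0.1)


def _two_group_design(n0=10, n1=10, p=8, d=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n0 + n1, p))
    y = np.array([0] * n0 + [1] * n1)
    X[y == 1, 0] += d
    return X, y


class TestSparseDiscriminantAnalysis:
    def test_single_informative_feature(self):
        X, y = _two_group_design(d=10.0)
        model = SparseDiscriminantAnalysis(alpha=1, gamma=0.1).fit(X, y)
        assert model.active_set_[0].tolist() == [0]
        assert (model.predict(X) == y).all()

    def test_theta_constraints(self):
        X, y = _two_group_design(n0=7, n1=13, seed=1)
        model = SparseDiscriminantAnalysis(alpha=4, gamma=0.5).fit(X, y)
        n = len(y)
        Y = np.zeros((n, 2))
        Y[np.arange(n), y] = 1.0
        D = Y.T @ Y
        th = model.theta_[0]
        assert th @ D @ th / n == pytest.approx(1.0, abs=1e-6)
        assert th @ D @ np.ones(2) == pytest.approx(0.0, abs=1e-6)

    def test_objective_non_increasing(self):
        X, y = _two_group_design(seed=2)
        model = SparseDiscriminantAnalysis(alpha=3, gamma=0.2).fit(X, y)
        hist = np.array(model.objective_history_)
        assert (np.diff(hist) <= 1e-8 * max(1.0, hist[0])).all()

    def test_unregularized_limit_matches_lda_direction(self):
        """alpha=p, gamma=0 on a well-conditioned n>p problem recovers the
        classical LDA discriminant up to sign and scale."""
        X, y = _two_group_design(n0=30, n1=30, p=5, d=1.5, seed=3)
        X = X - X.mean(axis=0)  # scoring regression has no intercept
        model = SparseDiscriminantAnalysis(alpha=5, gamma=0.0).fit(X, y)
        mu0, mu1 = X[y == 0].mean(axis=0), X[y == 1].mean(axis=0)
        Sw = np.cov(X[y == 0].T) * 29 + np.cov(X[y == 1].T) * 29
        lda = np.linalg.solve(Sw, mu1 - mu0)
        b = model.beta_[0]
        cos = abs(b @ lda) / (np.linalg.norm(b) * np.linalg.norm(lda))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_planted_support_recovery(self):
        """Five planted columns of d=2 among p=200 are exactly recovered."""
        rng = np.random.default_rng(11)
        n, p = 30, 200
        X = rng.standard_normal((n, p))
        y = np.array([0] * 15 + [1] * 15)
        planted = [3, 40, 90, 150, 199]
        for j in planted:
            X[y == 1, j] += 2.0
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        model = SparseDiscriminantAnalysis(alpha=5, gamma=30.0).fit(X, y)
        assert model.active_set_[0].tolist() == planted
        n_ = len(y)
        Y = np.zeros((n_, 2))
        Y[np.arange(n_), y] = 1.0
        D = Y.T @ Y
        th = model.theta_[0]
        assert th @ D @ th / n_ == pytest.approx(1.0, abs=1e-6)

    def test_heldout_accuracy_on_planted_cohort(self):
        p, planted = 100, [2, 17, 55]
        def draw(n_per_group, seed):
            r = np.random.default_rng(seed)
            X = r.standard_normal((2 * n_per_group, p))
            y = np.array([0] * n_per_group + [1] * n_per_group)
            for j in planted:
                X[y == 1, j] += 3.0
            return X, y
        Xtr, ytr = draw(15, 100)
        Xte, yte = draw(10, 200)
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
        model = SparseDiscriminantAnalysis(alpha=3, gamma=10.0).fit((Xtr - mu) / sd, ytr)
        acc = np.mean(model.predict((Xte - mu) / sd) == yte)
        assert acc >= 0.95

    def test_degenerate_model_ties_to_lower_class(self):
        X, y = _two_group_design(seed=4)
        model = SparseDiscriminantAnalysis(alpha=2, gamma=0.1).fit(X, y)
        model.beta_ = np.zeros_like(model.beta_)
        model.centroids_ = np.zeros_like(model.centroids_)
        with pytest.warns(UserWarning, match="degenerate"):
            pred = model.predict(X)
        assert (pred == model.classes_[0]).all()

    def test_permutation_equivariance(self):
        X, y = _two_group_design(seed=5)
        perm = np.random.default_rng(6).permutation(len(y))
        m1 = SparseDiscriminantAnalysis(alpha=4, gamma=0.3).fit(X, y)
        m2 = SparseDiscriminantAnalysis(alpha=4, gamma=0.3).fit(X[perm], y[perm])
        np.testing.assert_allclose(m1.beta_, m2.beta_, atol=1e-10)

    def test_column_mismatch_rejected(self):
        X, y = _two_group_design()
        model = SparseDiscriminantAnalysis(alpha=2, gamma=0.1).fit(X, y)
        with pytest.raises(ml.DataError, match="columns"):
            model.predict(X[:, :4])

    def test_json_round_trip(self):
        X, y = _two_group_design(seed=7)
        model = SparseDiscriminantAnalysis(alpha=3, gamma=0.2).fit(X, y)
        clone = SparseDiscriminantAnalysis.from_json(model.to_json())
        np.testing.assert_allclose(clone.beta_, model.beta_)
        np.testing.assert_array_equal(clone.predict(X), model.predict(X))

    def test_hyperparameter_validation(self):
        X, y = _two_group_design()
        with pytest.raises(ml.DataError):
            SparseDiscriminantAnalysis(alpha=0).fit(X, y)
        with pytest.raises(ml.DataError, match="alpha"):
            SparseDiscriminantAnalysis(alpha=999).fit(X, y)


class TestOracleEquivalence:
    def test_random_small_instances_match_oracle(self):
        """Path solver and brute-force coordinate descent agree elementwise
        on a batch of random problems across (alpha, gamma)."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            n = int(rng.integers(6, 16))
            p = int(rng.integers(5, 31))
            X = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            alpha = int(rng.integers(1, min(6, p + 1)))
            gamma = float(rng.choice([0.0, 0.1, 1.0]))
            beta, eta = ml.solve_elastic_net(X, y, alpha, gamma, return_eta=True)
            oracle = cd_elastic_net(X, y, eta, gamma)
            np.testing.assert_allclose(beta, oracle, atol=1e-6)
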