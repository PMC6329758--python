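"""Sparse discriminant analysis by optimal scoring with elastic-net penalties.

Linear discriminant analysis is recast as a regression problem: class
indicators ``Y`` are mapped to real score vectors ``theta`` and a penalized
least-squares fit of ``X beta`` onto ``Y theta`` is solved,

    min_{beta, theta}  ||Y theta - X beta||^2 + eta ||beta||_1 + gamma ||beta||_2^2
    s.t.  (1/n) theta^T Y^T Y theta = 1,   theta^T Y^T Y theta_l = 0  (l < k),

which for an identity smoothing matrix is an elastic-net problem.  The l1
weight ``eta`` is reparameterized as ``alpha``, the number of variables left
in the model: the elastic-net path is followed until ``alpha`` variables are
active, and the ``eta`` at that knot is recorded (the alpha <-> eta duality).

The alternating solver iterates (i) an elastic-net fit of ``beta`` for fixed
scores and (ii) the constrained update of ``theta``; for the two-class case
the constraint set contains a single score vector up to sign, so the
alternation converges in one or two sweeps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import lars_path

from .exceptions import DataError, NumericalError
from .io import DesignMatrix

__all__ = [
    "SDAHyperparams",
    "SparseDiscriminantAnalysis",
    "solve_elastic_net",
    "fit_sda",
    "classify",
]


@dataclass
class SDAHyperparams:
    """Hyperparameters of one sparse discriminant fit.

    alpha : int
        Target number of retained variables (the l1 penalty expressed as a
        model size).
    gamma : float
        l2 (ridge) penalty weight; grouping of correlated edges.
    omega_is_identity : bool
        Fixed True here: the smoothing matrix is the identity, making the
        beta subproblem a plain elastic net.
    tol : float
        Convergence tolerance on the change of the score vector.
    max_iter : int
        Cap on alternating iterations.
    """

    alpha: int
    gamma: float = 0.1
    omega_is_identity: bool = True
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self):
        if int(self.alpha) != self.alpha or self.alpha < 1:
            raise DataError(f"alpha must be a positive integer, got {self.alpha}")
        self.alpha = int(self.alpha)
        if self.gamma < 0:
            raise DataError(f"gamma must be nonnegative, got {self.gamma}")
        if self.tol <= 0:
            raise DataError("tol must be positive")
        if self.max_iter < 1:
            raise DataError("max_iter must be >= 1")
        if not self.omega_is_identity:
            raise DataError("only the identity smoothing matrix is supported")


def solve_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    alpha_stop: int,
    gamma: float,
    return_eta: bool = False,
):
    """Elastic net ``min ||y - X b||^2 + eta ||b||_1 + gamma ||b||_2^2`` with
    ``eta`` chosen implicitly so that ``alpha_stop`` variables are active.

    The ridge term is absorbed by the standard augmentation
    ``X* = [X; sqrt(gamma) I]``, ``y* = [y; 0]`` and the lasso path of the
    augmented problem is followed (LARS with the lasso modification) until
    ``alpha_stop`` variables are active.  At the returned knot the KKT
    conditions hold in the 1/2-gradient convention:
    ``|x_j^T (y - X b) - gamma b_j| = eta/2`` for active j, ``<= eta/2``
    otherwise.

    Returns ``beta`` (and ``eta`` when ``return_eta``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise DataError("non-finite values in elastic-net input")
    n, p = X.shape
    if y.shape[0] != n:
        raise DataError(f"X has {n} rows but y has {y.shape[0]} entries")
    if np.ptp(y) == 0:
        raise DataError("degenerate response: y is constant")
    if int(alpha_stop) != alpha_stop or alpha_stop < 1:
        raise DataError(f"alpha_stop must be a positive integer, got {alpha_stop}")
    alpha_stop = int(alpha_stop)
    if alpha_stop > p:
        raise DataError(f"alpha_stop={alpha_stop} exceeds the number of features p={p}")
    if gamma < 0:
        raise DataError("gamma must be nonnegative")

    if gamma > 0:
        Xa = np.vstack([X, np.sqrt(gamma) * np.eye(p)])
        ya = np.concatenate([y, np.zeros(p)])
    else:
        Xa, ya = X, y
    n_aug = Xa.shape[0]

    # follow the path only until alpha_stop variables are active; retry with
    # a longer path if lasso drop steps consumed the iteration budget
    max_steps = alpha_stop + 10
    while True:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # benign collinearity notices on tiny designs
            alphas, _, coefs = lars_path(
                Xa, ya, method="lasso", alpha_min=0.0, max_iter=max_steps
            )
        if coefs.size == 0:  # pragma: no cover - lars_path always returns >= 1 knot
            raise NumericalError("empty elastic-net path")
        nnz = (coefs != 0).sum(axis=0)
        if nnz.max() >= alpha_stop or max_steps >= 2 * min(n_aug, p) + 20:
            break
        max_steps *= 2

    hit = np.flatnonzero(nnz == alpha_stop)
    if hit.size:
        k = int(hit[0])
    else:
        # path skipped alpha_stop (simultaneous entries or saturation):
        # fall back to the last knot not exceeding alpha_stop actives
        below = np.flatnonzero(nnz <= alpha_stop)
        k = int(below[-1]) if below.size else 0
    beta = coefs[:, k].copy()
    # sklearn's lasso objective is (1/(2 n)) ||.||^2 + a ||b||_1, so the knot
    # penalty converts to our convention as eta = 2 * n_aug * a
    eta = 2.0 * n_aug * float(alphas[k])
    if return_eta:
        return beta, eta
    return beta


class SparseDiscriminantAnalysis(BaseEstimator, ClassifierMixin):
    """Sparse discriminant analysis via penalized optimal scoring.

    Parameters
    ----------
    alpha : int
        Number of variables retained in each discriminant vector.
    gamma : float, default 0.1
        Ridge penalty weight.
    tol : float, default 1e-6
        Stopping tolerance on the score-vector change.
    max_iter : int, default 100
        Maximum alternating iterations per discriminant.

    Attributes
    ----------
    beta_ : ndarray (n_discriminants, p)
        Sparse discriminant vectors.
    theta_ : ndarray (n_discriminants, K)
        Class score vectors; satisfy (1/n) theta^T Y^T Y theta = 1 and mutual
        Y^T Y orthogonality.
    eta_ : ndarray (n_discriminants,)
        l1 penalty weight at which the alpha-th variable entered.
    active_set_ : list of ndarray
        Indices of nonzero beta entries per discriminant.
    centroids_ : ndarray (K, n_discriminants)
        Class means in discriminant-score space; classification assigns the
        nearest centroid, ties to the lower class code.
    objective_history_ : list of float
        Penalized objective after each alternating iteration.
    """

    def __init__(self, alpha: int = 1, gamma: float = 0.1, tol: float = 1e-6, max_iter: int = 100):
        self.alpha = alpha
        self.gamma = gamma
        self.tol = tol
        self.max_iter = max_iter

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        if X.ndim != 2:
            raise DataError("X must be 2-dimensional")
        n, p = X.shape
        if y.shape[0] != n:
            raise DataError(f"X has {n} rows but y has {y.shape[0]} labels")
        hp = SDAHyperparams(alpha=self.alpha, gamma=self.gamma, tol=self.tol, max_iter=self.max_iter)
        if hp.alpha > p:
            raise DataError(f"alpha={hp.alpha} exceeds p={p}")
        self.classes_, codes = np.unique(y, return_inverse=True)
        K = len(self.classes_)
        if K < 2:
            raise DataError("need at least two classes")
        if n < K:
            raise DataError(f"need n >= K, got n={n}, K={K}")
        counts = np.bincount(codes, minlength=K).astype(float)
        if counts.min() < 1:  # pragma: no cover - unique() guarantees nonzero
            raise DataError("empty class")

        Y = np.zeros((n, K))
        Y[np.arange(n), codes] = 1.0
        D = np.diag(counts)  # Y^T Y for an indicator matrix

        n_disc = K - 1
        betas = np.zeros((n_disc, p))
        thetas = np.zeros((n_disc, K))
        etas = np.zeros(n_disc)
        self.converged_ = True
        self.n_iter_ = 0
        self.objective_history_ = []

        ones = np.ones(K)
        for k in range(n_disc):
            theta = self._init_theta(k, counts, thetas[:k], D, n)
            converged = False
            for it in range(hp.max_iter):
                resp = Y @ theta
                beta, eta = solve_elastic_net(X, resp, hp.alpha, hp.gamma, return_eta=True)
                obj = (
                    float(np.sum((resp - X @ beta) ** 2))
                    + eta * float(np.abs(beta).sum())
                    + hp.gamma * float(beta @ beta)
                )
                self.objective_history_.append(obj)
                # theta update: D^{-1} Y^T X beta projected onto the constraint set
                t = (Y.T @ (X @ beta)) / counts
                t = self._project_theta(t, ones, thetas[:k], D, n)
                if t is None:
                    warnings.warn("degenerate discriminant (X beta = 0); keeping current scores")
                    converged = True
                    break
                if t @ (D @ theta) < 0:
                    t = -t  # align sign with the previous iterate
                delta = float(np.linalg.norm(t - theta))
                theta = t
                if delta <= hp.tol:
                    converged = True
                    break
            self.n_iter_ += it + 1
            if not converged:
                self.converged_ = False
                warnings.warn(
                    f"optimal-scoring alternation did not converge in {hp.max_iter} iterations"
                )
            # canonical sign: first nonzero score entry positive (the elastic
            # net is sign-equivariant, so beta flips with theta)
            nz = np.flatnonzero(np.abs(theta) > 1e-12)
            if nz.size and theta[nz[0]] < 0:
                theta = -theta
                beta = -beta
            betas[k] = beta
            thetas[k] = theta
            etas[k] = eta

        self.beta_ = betas
        self.theta_ = thetas
        self.eta_ = etas
        self.active_set_ = [np.flatnonzero(b) for b in betas]
        self.hyperparams_ = hp
        scores = X @ betas.T  # (n, n_disc)
        self.centroids_ = np.vstack([scores[codes == c].mean(axis=0) for c in range(K)])
        self.n_features_in_ = p
        return self

    @staticmethod
    def _init_theta(k, counts, prev, D, n):
        """Deterministic start: for the first discriminant of a two-class fit
        this is the unique (up to sign) feasible score vector, taken with a
        positive leading entry."""
        K = len(counts)
        trial = np.zeros(K)
        trial[k + 1] = 1.0
        basis = [np.ones(K)] + list(prev)
        t = trial.copy()
        for b in basis:
            denom = b @ (D @ b)
            if denom > 0:
                t -= (trial @ (D @ b)) / denom * b
        norm = t @ (D @ t)
        if norm <= 0:  # pragma: no cover
            raise NumericalError("cannot initialize score vector")
        t *= np.sqrt(n / norm)
        nz = np.flatnonzero(np.abs(t) > 1e-12)
        if nz.size and t[nz[0]] < 0:
            t = -t
        return t

    @staticmethod
    def _project_theta(t, ones, prev, D, n):
        for b in [ones] + list(prev):
            denom = b @ (D @ b)
            if denom > 0:
                t = t - (t @ (D @ b)) / denom * b
        norm = t @ (D @ t)
        if norm <= 1e-24:
            return None
        return t * np.sqrt(n / norm)

    # -------------------------------------------------------------- predict
    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise DataError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns, model expects {self.n_features_in_}"
            )
        return X @ self.beta_.T

    def predict(self, X):
        """Nearest class centroid in discriminant-score space; ties go to the
        lower class code."""
        scores = self.decision_scores(X)
        if np.all(self.beta_ == 0):
            warnings.warn("degenerate model (beta = 0): assigning the lower class code")
        d2 = ((scores[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]  # argmin takes the first (lower) class on ties

    # -------------------------------------------------------- serialization
    def to_json(self) -> str:
        """Serialize the fitted model as a single JSON document (beta stored
        as sparse triplets)."""
        triplets = [
            [int(k), int(j), float(self.beta_[k, j])]
            for k in range(self.beta_.shape[0])
            for j in np.flatnonzero(self.beta_[k])
        ]
        doc = {
            "classes": [float(c) for c in self.classes_],
            "n_features": int(self.n_features_in_),
            "beta_triplets": triplets,
            "theta": self.theta_.tolist(),
            "eta": self.eta_.tolist(),
            "centroids": self.centroids_.tolist(),
            "hyperparams": {
                "alpha": self.hyperparams_.alpha,
                "gamma": self.hyperparams_.gamma,
                "tol": self.hyperparams_.tol,
                "max_iter": self.hyperparams_.max_iter,
            },
            "converged": bool(self.converged_),
            "n_iter": int(self.n_iter_),
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SparseDiscriminantAnalysis":
        doc = json.loads(text)
        hp = doc["hyperparams"]
        est = cls(alpha=hp["alpha"], gamma=hp["gamma"], tol=hp["tol"], max_iter=hp["max_iter"])
        est.classes_ = np.array(doc["classes"])
        est.n_features_in_ = doc["n_features"]
        n_disc = len(doc["theta"])
        est.beta_ = np.zeros((n_disc, doc["n_features"]))
        for k, j, v in doc["beta_triplets"]:
            est.beta_[k, j] = v
        est.theta_ = np.array(doc["theta"])
        est.eta_ = np.array(doc["eta"])
        est.centroids_ = np.array(doc["centroids"])
        est.converged_ = doc["converged"]
        est.n_iter_ = doc["n_iter"]
        est.active_set_ = [np.flatnonzero(b) for b in est.beta_]
        est.hyperparams_ = SDAHyperparams(**hp)
        return est


def fit_sda(design: DesignMatrix, hyperparams: SDAHyperparams) -> SparseDiscriminantAnalysis:
    """Fit one sparse discriminant model on a vectorized cohort."""
    est = SparseDiscriminantAnalysis(
        alpha=hyperparams.alpha,
        gamma=hyperparams.gamma,
        tol=hyperparams.tol,
        max_iter=hyperparams.max_iter,
    )
    return est.fit(design.X, design.labels)


def classify(model: SparseDiscriminantAnalysis, X_new: np.ndarray) -> np.ndarray:
    """Assign each row of ``X_new`` (standardized with the training
    statistics) to the nearest class centroid."""
    return model.predict(X_new)
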