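"""Two-stage MultiLink Analysis: an ensemble of sparse discriminant fits over
resamples of the cohort, followed by occurrence-based stability selection.

A single sparse fit is unstable: removing one subject can change which edges
are selected.  The pipeline therefore fits one model per leave-one-out (or
bootstrap) resample, counts how many ensemble members select each edge (the
occurrence profile), and keeps only edges selected at least a threshold
number of times — by default half the number of subjects, rounded up, a
trade-off between keeping every edge ever selected and keeping only edges
selected in every member.

Hyperparameters (alpha, gamma) are tuned with a nested double-holdout scheme:
for up to 1000 iterations an inner held-out subject scores each grid pair and
an outer held-out subject, removed before the optimization, validates the
resulting choice.  On a plateau of equal error the pair yielding the fewest
selected connections wins; remaining ties go to the smaller alpha, then the
smaller gamma.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import ConfigError, DataError
from .io import ConnectomeCohort, DesignMatrix, EdgeSelection, map_features_to_edges, vectorize
from .sda import SDAHyperparams, SparseDiscriminantAnalysis

__all__ = [
    "OccurrenceProfile",
    "StabilityResult",
    "TuningReport",
    "MLAConfig",
    "MLAResult",
    "MultiLinkAnalysis",
    "run_ensemble",
    "stability_select",
    "tune_parameters",
    "run_mla",
]


@dataclass
class OccurrenceProfile:
    """Per-feature selection counts across the model ensemble."""

    counts: np.ndarray
    n_members: int
    alpha: int
    gamma: float
    n_subjects: int
    resampling: str = "leave_one_out"
    heldout_true: np.ndarray | None = None
    heldout_pred: np.ndarray | None = None
    skipped_folds: int = 0

    @property
    def loo_accuracy(self) -> float | None:
        if self.heldout_true is None or len(self.heldout_true) == 0:
            return None
        return float(np.mean(self.heldout_true == self.heldout_pred))


@dataclass
class StabilityResult:
    """Stability-selected feature set derived from an occurrence profile."""

    selected: np.ndarray
    threshold: int
    profile: OccurrenceProfile
    fold_accuracy: float | None = None


@dataclass
class TuningReport:
    """Grid-search record of the nested double-holdout tuning."""

    grid: list
    misclassification: np.ndarray
    chosen_alpha: int
    chosen_gamma: float
    validation_error: float
    n_iterations: int
    selection_rule_note: str = (
        "minimal mean inner-holdout misclassification; ties broken by fewest "
        "stability-selected connections, then smallest alpha, then smallest gamma"
    )


def run_ensemble(
    design: DesignMatrix,
    hyperparams: SDAHyperparams,
    resampling: str = "leave_one_out",
    n_bootstrap: int = 100,
    random_state: int | None = None,
) -> OccurrenceProfile:
    """Fit one sparse discriminant model per resample and count, for every
    feature, the number of models whose active set contains it.

    Under ``leave_one_out`` each member is trained on n-1 subjects and its
    held-out prediction is recorded, giving an ensemble-level accuracy
    estimate.  ``bootstrap`` draws ``n_bootstrap`` stratified resamples with
    replacement (requires ``random_state``).
    """
    X, y = design.X, design.labels
    n, p = X.shape
    if n < 3:
        raise DataError(f"ensemble requires n >= 3 subjects, got {n}")
    counts = np.zeros(p, dtype=int)

    if resampling == "leave_one_out":
        if np.bincount(y.astype(int)).min() < 2:
            raise DataError("degenerate fold: a group of size 1 cannot be resampled leave-one-out")
        heldout_true, heldout_pred = [], []
        n_members = 0
        skipped = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            if len(np.unique(y[mask])) < 2:
                warnings.warn(f"fold {i} skipped: removing subject empties a group")
                skipped += 1
                continue
            model = SparseDiscriminantAnalysis(
                alpha=hyperparams.alpha,
                gamma=hyperparams.gamma,
                tol=hyperparams.tol,
                max_iter=hyperparams.max_iter,
            ).fit(X[mask], y[mask])
            counts[model.active_set_[0]] += 1
            heldout_true.append(y[i])
            heldout_pred.append(model.predict(X[i : i + 1])[0])
            n_members += 1
        return OccurrenceProfile(
            counts=counts,
            n_members=n_members,
            alpha=hyperparams.alpha,
            gamma=hyperparams.gamma,
            n_subjects=n,
            resampling="leave_one_out",
            heldout_true=np.array(heldout_true),
            heldout_pred=np.array(heldout_pred),
            skipped_folds=skipped,
        )

    if resampling == "bootstrap":
        if n_bootstrap < 1:
            raise DataError(f"bootstrap requires B >= 1, got {n_bootstrap}")
        if random_state is None:
            raise ConfigError("bootstrap resampling requires an explicit random_state")
        rng = np.random.default_rng(random_state)
        idx0 = np.flatnonzero(y == np.unique(y)[0])
        idx1 = np.flatnonzero(y == np.unique(y)[1])
        for _ in range(n_bootstrap):
            take = np.concatenate(
                [rng.choice(idx0, size=len(idx0), replace=True),
                 rng.choice(idx1, size=len(idx1), replace=True)]
            )
            model = SparseDiscriminantAnalysis(
                alpha=hyperparams.alpha,
                gamma=hyperparams.gamma,
                tol=hyperparams.tol,
                max_iter=hyperparams.max_iter,
            ).fit(X[take], y[take])
            counts[model.active_set_[0]] += 1
        return OccurrenceProfile(
            counts=counts,
            n_members=n_bootstrap,
            alpha=hyperparams.alpha,
            gamma=hyperparams.gamma,
            n_subjects=n,
            resampling="bootstrap",
        )

    raise ConfigError(f"unknown resampling scheme {resampling!r}")


def stability_select(profile: OccurrenceProfile, threshold="half_n") -> StabilityResult:
    """Keep features selected by at least ``threshold`` ensemble members.

    ``"half_n"`` resolves to ceil(n/2) occurrences, n the number of subjects
    (with leave-one-out resampling, members and subjects coincide).  A
    numeric threshold above ``n_members`` yields an empty selection with a
    warning rather than an error — a legitimate exploratory setting.
    """
    if threshold == "half_n":
        resolved = math.ceil(profile.n_subjects / 2)
    else:
        resolved = int(threshold)
        if resolved < 1:
            raise DataError(f"threshold must be a positive integer, got {threshold}")
        if resolved > profile.n_members:
            warnings.warn(
                f"threshold {resolved} exceeds the {profile.n_members} ensemble members; "
                "selection is empty"
            )
    selected = np.flatnonzero(profile.counts >= resolved)
    return StabilityResult(
        selected=selected,
        threshold=resolved,
        profile=profile,
        fold_accuracy=profile.loo_accuracy,
    )


def tune_parameters(
    design: DesignMatrix,
    alpha_grid,
    gamma_grid,
    seed: int,
    max_iterations: int = 1000,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> TuningReport:
    """Nested double-holdout grid search over (alpha, gamma).

    Ordered (validation, test) subject pairs are drawn without replacement,
    capped at ``min(max_iterations, n(n-1))``.  For each pair every grid
    point is fitted on the remaining n-2 subjects; the inner (test) subject
    scores the grid and the outer (validation) subject, removed before the
    optimization, estimates the error of the winning choice.
    """
    X, y = design.X, design.labels
    n, p = X.shape
    alpha_grid = list(alpha_grid)
    gamma_grid = list(gamma_grid)
    if not alpha_grid or not gamma_grid:
        raise ConfigError("alpha_grid and gamma_grid must be non-empty")
    for a in alpha_grid:
        if a > p:
            raise DataError(f"alpha={a} exceeds p={p}")
    sizes = np.bincount(y.astype(int), minlength=2)
    if sizes.min() < 3:
        raise DataError(
            f"tuning refused: nested holdouts need >= 3 subjects per group, got {tuple(sizes)}"
        )

    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_iter = min(max_iterations, len(pairs))
    chosen_pairs = [pairs[k] for k in order[:n_iter]]

    grid = [(a, g) for a in alpha_grid for g in gamma_grid]
    inner_err = np.zeros(len(grid))
    inner_cnt = np.zeros(len(grid))
    outer_err = np.zeros(len(grid))
    outer_cnt = np.zeros(len(grid))
    for outer, inner in chosen_pairs:
        mask = np.ones(n, dtype=bool)
        mask[[outer, inner]] = False
        if len(np.unique(y[mask])) < 2:  # pragma: no cover - guarded by size check
            continue
        for gi, (a, g) in enumerate(grid):
            model = SparseDiscriminantAnalysis(alpha=a, gamma=g, tol=tol, max_iter=max_iter).fit(
                X[mask], y[mask]
            )
            pred = model.predict(X[[inner, outer]])
            inner_err[gi] += pred[0] != y[inner]
            inner_cnt[gi] += 1
            outer_err[gi] += pred[1] != y[outer]
            outer_cnt[gi] += 1

    mis = inner_err / np.maximum(inner_cnt, 1)
    best = np.flatnonzero(mis == mis.min())
    if len(best) > 1:
        # plateau: fewest stability-selected connections, then smallest alpha/gamma
        n_connections = []
        for gi in best:
            a, g = grid[gi]
            prof = run_ensemble(design, SDAHyperparams(alpha=a, gamma=g, tol=tol, max_iter=max_iter))
            n_connections.append(len(stability_select(prof, "half_n").selected))
        ranked = sorted(
            zip(n_connections, [grid[gi][0] for gi in best], [grid[gi][1] for gi in best], best)
        )
        choice = ranked[0][3]
    else:
        choice = best[0]
    a, g = grid[choice]
    return TuningReport(
        grid=grid,
        misclassification=mis,
        chosen_alpha=int(a),
        chosen_gamma=float(g),
        validation_error=float(outer_err[choice] / max(outer_cnt[choice], 1)),
        n_iterations=n_iter,
    )


@dataclass
class MLAConfig:
    """Resolved configuration of one end-to-end MLA run."""

    mode: str = "upper_triangle"
    standardize: str = "zscore"
    alpha: int | None = None
    gamma: float | None = None
    alpha_grid: list = field(default_factory=list)
    gamma_grid: list = field(default_factory=list)
    threshold: object = "half_n"
    resampling: str = "leave_one_out"
    n_bootstrap: int = 100
    seed: int = 0
    tuning_max_iterations: int = 1000
    tol: float = 1e-6
    max_iter: int = 100


@dataclass
class MLAResult:
    edge_selection: EdgeSelection
    stability: StabilityResult
    tuning: TuningReport | None
    design: DesignMatrix
    config: MLAConfig


class MultiLinkAnalysis(BaseEstimator):
    """Stability-selecting edge detector over an ensemble of sparse
    discriminant fits (the full two-stage pipeline as a transformer).

    With ``alpha`` and ``gamma`` given, the ensemble is run directly; with
    grids given instead, the nested double-holdout tuner picks them first.

    Attributes (after ``fit``)
    --------------------------
    occurrence_counts_ : ndarray (p,)
        Selection count per feature across ensemble members.
    selected_ : ndarray
        Stability-selected feature indices.
    threshold_ : int
        Resolved occurrence cutoff.
    loo_accuracy_ : float or None
        Held-out accuracy of the leave-one-out ensemble.
    tuning_report_ : TuningReport or None
    """

    def __init__(
        self,
        alpha: int | None = None,
        gamma: float | None = None,
        alpha_grid=None,
        gamma_grid=None,
        threshold="half_n",
        resampling: str = "leave_one_out",
        n_bootstrap: int = 100,
        tuning_max_iterations: int = 1000,
        tol: float = 1e-6,
        max_iter: int = 100,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.gamma = gamma
        self.alpha_grid = alpha_grid
        self.gamma_grid = gamma_grid
        self.threshold = threshold
        self.resampling = resampling
        self.n_bootstrap = n_bootstrap
        self.tuning_max_iterations = tuning_max_iterations
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y, design: DesignMatrix | None = None):
        if design is None:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y).ravel()
            design = DesignMatrix(
                X=X,
                Y=_indicator(y),
                feature_map=[(0, j + 1) for j in range(X.shape[1])],
                labels=y,
                mode="columns",
            )
        alpha, gamma = self.alpha, self.gamma
        self.tuning_report_ = None
        if alpha is None or gamma is None:
            if not self.alpha_grid or self.gamma_grid is None or not list(self.gamma_grid):
                raise ConfigError("either fix (alpha, gamma) or provide non-empty tuning grids")
            self.tuning_report_ = tune_parameters(
                design,
                self.alpha_grid,
                self.gamma_grid,
                seed=self.random_state,
                max_iterations=self.tuning_max_iterations,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            alpha = self.tuning_report_.chosen_alpha
            gamma = self.tuning_report_.chosen_gamma
        hp = SDAHyperparams(alpha=alpha, gamma=gamma, tol=self.tol, max_iter=self.max_iter)
        profile = run_ensemble(
            design,
            hp,
            resampling=self.resampling,
            n_bootstrap=self.n_bootstrap,
            random_state=self.random_state,
        )
        result = stability_select(profile, self.threshold)
        self.alpha_, self.gamma_ = int(alpha), float(gamma)
        self.profile_ = profile
        self.occurrence_counts_ = profile.counts
        self.selected_ = result.selected
        self.threshold_ = result.threshold
        self.loo_accuracy_ = profile.loo_accuracy
        self.stability_result_ = result
        self.n_features_in_ = design.n_features
        return self

    def get_support(self, indices: bool = True):
        if indices:
            return self.selected_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X[:, self.selected_]


def _indicator(y: np.ndarray) -> np.ndarray:
    classes, codes = np.unique(y, return_inverse=True)
    Y = np.zeros((len(y), len(classes)))
    Y[np.arange(len(y)), codes] = 1.0
    return Y


def run_mla(cohort: ConnectomeCohort, config: MLAConfig) -> MLAResult:
    """End-to-end pipeline: vectorize, (optionally) tune, run the ensemble,
    stability-select, and map the surviving features back to edges."""
    stage = "vectorize"
    try:
        design = vectorize(cohort, mode=config.mode, standardize=config.standardize)
        stage = "fit"
        est = MultiLinkAnalysis(
            alpha=config.alpha,
            gamma=config.gamma,
            alpha_grid=config.alpha_grid,
            gamma_grid=config.gamma_grid,
            threshold=config.threshold,
            resampling=config.resampling,
            n_bootstrap=config.n_bootstrap,
            tuning_max_iterations=config.tuning_max_iterations,
            tol=config.tol,
            max_iter=config.max_iter,
            random_state=config.seed,
        ).fit(None, None, design=design)
        stage = "map_features_to_edges"
        edges = map_features_to_edges(
            est.selected_, design, counts=est.occurrence_counts_, method="mla"
        )
    except Exception as exc:
        exc.args = (f"[stage: {stage}] {exc}",)
        raise
    return MLAResult(
        edge_selection=edges,
        stability=est.stability_result_,
        tuning=est.tuning_report_,
        design=design,
        config=config,
    )
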