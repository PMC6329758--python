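"""Univariate and SVM-weight baselines for connectome group comparison.

Network-based statistic (NBS): every edge is tested with a two-sample t-test;
edges passing a primary threshold form a graph whose connected components are
the candidate subnetworks.  Family-wise control comes from a permutation
null: group labels are shuffled, the same pipeline is re-run, and the maximal
component statistic per permutation builds the null distribution against
which each observed component is scored.

SVM-weight selection: a linear SVM is trained on the true labels and its
primal weight for each edge is compared with a per-edge null built from
label-permutation refits; weights outside the (5th, 95th) percentile band of
the null are declared selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.svm import SVC

from .exceptions import ConfigError, DataError
from .io import ConnectomeCohort, DesignMatrix, map_features_to_edges, vectorize
from .sda import SDAHyperparams
from . import ensemble as _ens

__all__ = [
    "NBSResult",
    "SVMWeightResult",
    "NetworkBasedStatistic",
    "SVMWeightSelector",
    "nbs_test",
    "svm_weight_select",
    "compare_methods",
]


@dataclass
class NBSResult:
    edge_pvalues: np.ndarray
    edge_tvalues: np.ndarray
    suprathreshold_components: list  # list of lists of feature indices
    component_pvalues: np.ndarray
    component_statistics: np.ndarray
    primary_threshold: float
    statistic: str
    n_permutations: int
    zero_variance_edges: np.ndarray

    @property
    def significant_components(self):
        return [
            comp
            for comp, p in zip(self.suprathreshold_components, self.component_pvalues)
            if p < 0.05
        ]

    def selected_features(self, level: float = 0.05) -> np.ndarray:
        feats: list[int] = []
        for comp, p in zip(self.suprathreshold_components, self.component_pvalues):
            if p < level:
                feats.extend(comp)
        return np.array(sorted(feats), dtype=int)


@dataclass
class SVMWeightResult:
    weights: np.ndarray
    null_low: np.ndarray
    null_high: np.ndarray
    selected: np.ndarray
    percentile_band: tuple
    n_permutations: int


def _pooled_t(X: np.ndarray, g0: np.ndarray, g1: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per column; 0 where both group
    variances vanish."""
    n0, n1 = len(g0), len(g1)
    m0 = X[g0].mean(axis=0)
    m1 = X[g1].mean(axis=0)
    v0 = X[g0].var(axis=0, ddof=1)
    v1 = X[g1].var(axis=0, ddof=1)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    denom = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m0 - m1) / denom
    return np.where(denom == 0, 0.0, t)


def _components(mask: np.ndarray, feature_map, tvals: np.ndarray, statistic: str):
    """Connected components of the suprathreshold graph; returns (component
    feature lists, component statistics)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return [], np.array([])
    g = nx.Graph()
    for j in idx:
        i, k = feature_map[j]
        a, b = min(i, k), max(i, k)
        if g.has_edge(a, b):
            g[a][b]["feats"].append(j)
        else:
            g.add_edge(a, b, feats=[j])
    comps, cstats = [], []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        feats = sorted(j for _, _, d in sub.edges(data=True) for j in d["feats"])
        comps.append(feats)
        if statistic == "extent":
            cstats.append(float(sub.number_of_edges()))
        else:  # intensity
            cstats.append(float(np.abs(tvals[feats]).sum()))
    order = np.argsort([-s for s in cstats])
    return [comps[i] for i in order], np.array([cstats[i] for i in order])


def nbs_test(
    design: DesignMatrix,
    primary_p: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    statistic: str = "extent",
    welch: bool = False,
) -> NBSResult:
    """Network-based statistic on a vectorized cohort.

    Edges with two-sided p below ``primary_p`` (pooled-variance t-test by
    default, Welch with ``welch=True``) form the suprathreshold graph.  The
    null distribution of the maximal component statistic (``extent`` = number
    of edges, ``intensity`` = summed |t|) is built from ``n_permutations``
    group-label shuffles, and each observed component gets the p-value
    ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if not 0 < primary_p < 1:
        raise DataError(f"primary_p must lie in (0, 1), got {primary_p}")
    if n_permutations < 1:
        raise DataError(f"n_permutations must be >= 1, got {n_permutations}")
    if statistic not in ("extent", "intensity"):
        raise ConfigError(f"unknown NBS statistic {statistic!r}")
    X, y = design.X, design.labels
    n, p = X.shape
    g0 = np.flatnonzero(y == 0)
    g1 = np.flatnonzero(y == 1)
    if min(len(g0), len(g1)) < 2:
        raise DataError("NBS needs at least 2 subjects per group")
    df = n - 2

    zero_var = np.flatnonzero((X[g0].var(axis=0) == 0) & (X[g1].var(axis=0) == 0))
    if zero_var.size:
        warnings.warn(f"{zero_var.size} zero-variance edges set to t=0, p=1")

    if welch:
        tvals, pvals = stats.ttest_ind(X[g0], X[g1], axis=0, equal_var=False)
        tvals = np.nan_to_num(tvals)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        mask_obs = pvals < primary_p

        def supra(labels01):
            a = np.flatnonzero(labels01 == 0)
            b = np.flatnonzero(labels01 == 1)
            t, pv = stats.ttest_ind(X[a], X[b], axis=0, equal_var=False)
            return np.where(np.isnan(pv), 1.0, pv) < primary_p, np.nan_to_num(t)

    else:
        # primary threshold converted to the equivalent |t| cutoff
        t_crit = stats.t.isf(primary_p / 2.0, df)
        tvals = _pooled_t(X, g0, g1)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        pvals[zero_var] = 1.0
        mask_obs = np.abs(tvals) > t_crit

        def supra(labels01):
            a = np.flatnonzero(labels01 == 0)
            b = np.flatnonzero(labels01 == 1)
            t = _pooled_t(X, a, b)
            return np.abs(t) > t_crit, t

    comps, cstats = _components(mask_obs, design.feature_map, tvals, statistic)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(y)
        m, t = supra(perm)
        _, cs = _components(m, design.feature_map, t, statistic)
        null_max[b] = cs[0] if cs.size else 0.0

    comp_p = np.array(
        [(1.0 + np.sum(null_max >= s)) / (n_permutations + 1.0) for s in cstats]
    )
    return NBSResult(
        edge_pvalues=pvals,
        edge_tvalues=tvals,
        suprathreshold_components=comps,
        component_pvalues=comp_p,
        component_statistics=cstats,
        primary_threshold=primary_p,
        statistic=statistic,
        n_permutations=n_permutations,
        zero_variance_edges=zero_var,
    )


def svm_weight_select(
    design: DesignMatrix,
    n_permutations: int = 1000,
    percentile_band: tuple = (5.0, 95.0),
    seed: int = 0,
    svm_cost: float = 1.0,
) -> SVMWeightResult:
    """Linear-SVM weight selection against a label-permutation null.

    Features are standardized (weights are only comparable across edges on a
    common scale), one SVM is trained on the true labels, and per-feature
    percentile bands of the null weight distribution mark the selected edges.
    """
    if n_permutations < 1:
        raise DataError(f"n_permutations must be >= 1, got {n_permutations}")
    lo, hi = percentile_band
    if not 0 <= lo < hi <= 100:
        raise DataError(f"invalid percentile band {percentile_band}")
    if svm_cost <= 0:
        raise DataError("svm_cost must be positive")
    X, y = design.X, design.labels
    if len(np.unique(y)) != 2:
        raise DataError("SVM baseline requires binary labels")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd

    def weights_for(labels):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm = SVC(kernel="linear", C=svm_cost).fit(Xs, labels)
        return svm.coef_[0].copy()

    w = weights_for(y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, X.shape[1]))
    for b in range(n_permutations):
        null[b] = weights_for(rng.permutation(y))
    null_low = np.percentile(null, lo, axis=0)
    null_high = np.percentile(null, hi, axis=0)
    selected = np.flatnonzero((w < null_low) | (w > null_high))
    return SVMWeightResult(
        weights=w,
        null_low=null_low,
        null_high=null_high,
        selected=selected,
        percentile_band=(lo, hi),
        n_permutations=n_permutations,
    )


class NetworkBasedStatistic(BaseEstimator):
    """Estimator wrapper around :func:`nbs_test`.

    ``feature_map`` (column -> node pair) is required to extract graph
    components; when fitted via a :class:`DesignMatrix` it is taken from
    there.
    """

    def __init__(
        self,
        primary_p: float = 0.05,
        n_permutations: int = 1000,
        statistic: str = "extent",
        welch: bool = False,
        random_state: int = 0,
        feature_map=None,
    ):
        self.primary_p = primary_p
        self.n_permutations = n_permutations
        self.statistic = statistic
        self.welch = welch
        self.random_state = random_state
        self.feature_map = feature_map

    def fit(self, X, y, design: DesignMatrix | None = None):
        if design is None:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y).ravel()
            fmap = self.feature_map or [(0, j + 1) for j in range(X.shape[1])]
            design = DesignMatrix(
                X=X, Y=_ens._indicator(y), feature_map=fmap, labels=y, mode="columns"
            )
        self.result_ = nbs_test(
            design,
            primary_p=self.primary_p,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            statistic=self.statistic,
            welch=self.welch,
        )
        self.selected_ = self.result_.selected_features()
        self.n_features_in_ = design.n_features
        return self

    def get_support(self, indices: bool = True):
        if indices:
            return self.selected_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


class SVMWeightSelector(BaseEstimator):
    """Estimator wrapper around :func:`svm_weight_select`."""

    def __init__(
        self,
        n_permutations: int = 1000,
        percentile_band: tuple = (5.0, 95.0),
        svm_cost: float = 1.0,
        random_state: int = 0,
    ):
        self.n_permutations = n_permutations
        self.percentile_band = percentile_band
        self.svm_cost = svm_cost
        self.random_state = random_state

    def fit(self, X, y, design: DesignMatrix | None = None):
        if design is None:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y).ravel()
            design = DesignMatrix(
                X=X,
                Y=_ens._indicator(y),
                feature_map=[(0, j + 1) for j in range(X.shape[1])],
                labels=y,
                mode="columns",
            )
        self.result_ = svm_weight_select(
            design,
            n_permutations=self.n_permutations,
            percentile_band=self.percentile_band,
            seed=self.random_state,
            svm_cost=self.svm_cost,
        )
        self.selected_ = self.result_.selected
        self.n_features_in_ = design.n_features
        return self

    def get_support(self, indices: bool = True):
        if indices:
            return self.selected_
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_] = True
        return mask


def compare_methods(
    cohort: ConnectomeCohort,
    alpha_grid,
    gamma: float = 0.1,
    mode: str = "upper_triangle",
    standardize: str = "zscore",
    primary_p: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    svm_cost: float = 1.0,
) -> pd.DataFrame:
    """Set-difference comparison of MLA against NBS and SVM across an alpha
    grid.

    Both baselines run once; MLA runs per alpha.  Each row reports the sizes
    of the selection differences; ``break_even_alpha`` (attached as a frame
    attribute) is the smallest alpha at which MLA covers at least as many
    exclusive features as NBS retains exclusively.
    """
    design = vectorize(cohort, mode=mode, standardize=standardize)
    nbs = nbs_test(design, primary_p=primary_p, n_permutations=n_permutations, seed=seed)
    nbs_set = set(nbs.selected_features().tolist())
    svm = svm_weight_select(design, n_permutations=n_permutations, seed=seed, svm_cost=svm_cost)
    svm_set = set(svm.selected.tolist())

    rows = []
    break_even = None
    for a in alpha_grid:
        prof = _ens.run_ensemble(design, SDAHyperparams(alpha=int(a), gamma=gamma))
        mla_set = set(_ens.stability_select(prof, "half_n").selected.tolist())
        row = {
            "alpha": int(a),
            "n_mla": len(mla_set),
            "n_nbs": len(nbs_set),
            "n_svm": len(svm_set),
            "mla_not_nbs": len(mla_set - nbs_set),
            "nbs_not_mla": len(nbs_set - mla_set),
            "mla_not_svm": len(mla_set - svm_set),
            "svm_not_mla": len(svm_set - mla_set),
        }
        rows.append(row)
        if break_even is None and row["mla_not_nbs"] >= row["nbs_not_mla"]:
            break_even = int(a)
    if not rows:  # baseline-only comparison: no MLA columns
        frame = pd.DataFrame([{"n_nbs": len(nbs_set), "n_svm": len(svm_set)}])
        frame.attrs["break_even_alpha"] = None
        return frame
    frame = pd.DataFrame(rows)
    frame.attrs["break_even_alpha"] = break_even
    return frame
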