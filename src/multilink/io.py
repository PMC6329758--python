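"""Loading, validation and vectorization of connectivity matrices.

A cohort is a stack of per-subject R x R weighted connectivity matrices with a
binary group label per subject.  Downstream analysis works on the vectorized
form: a subjects-by-edges design matrix ``X`` whose columns are off-diagonal
matrix entries, together with the column -> (node_i, node_j) map needed to
translate selected features back into brain-network edges.

Symmetric cohorts are vectorized as the strict upper triangle (i < j,
row-major), which halves the dimensionality and avoids perfectly duplicated
columns; directed cohorts keep every off-diagonal entry.  The diagonal is
always dropped: self-loops carry no between-region information.
"""

from __future__ import annotations

import csv
import io as _stdlib_io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DataError

SYMMETRY_TOL = 1e-8

__all__ = [
    "ConnectomeCohort",
    "DesignMatrix",
    "EdgeSelection",
    "load_cohort",
    "read_matrix",
    "read_manifest",
    "vectorize",
    "map_features_to_edges",
]


@dataclass
class ConnectomeCohort:
    """Per-subject connectivity matrices with binary group labels.

    Parameters
    ----------
    subjects : list of str
        Ordered subject identifiers.
    matrices : ndarray of shape (n, R, R)
        One weighted connectivity matrix per subject (fiber counts or
        functional correlation indices; dimensionless).
    labels : ndarray of shape (n,)
        Group code per subject, in {0, 1}.
    roi_names : list of str, optional
        Region labels, length R.
    symmetric : bool
        True when every matrix equals its transpose within ``SYMMETRY_TOL``.
    label_names : dict
        Mapping from group code back to the original label value.
    """

    subjects: list
    matrices: np.ndarray
    labels: np.ndarray
    roi_names: list | None = None
    symmetric: bool = True
    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise DataError(
                f"matrices must be a stack of square matrices, got shape {self.matrices.shape}"
            )
        n = self.matrices.shape[0]
        if len(self.labels) != n or len(self.subjects) != n:
            raise DataError("subjects, matrices and labels must have equal length")
        codes = np.unique(self.labels)
        if not np.array_equal(codes, [0, 1]):
            raise DataError(f"labels must contain exactly the two group codes 0 and 1, got {codes}")
        if (self.labels == 0).sum() < 1 or (self.labels == 1).sum() < 1:
            raise DataError("both groups must be non-empty")
        if self.roi_names is not None and len(self.roi_names) != self.n_nodes:
            raise DataError(
                f"{len(self.roi_names)} ROI names for {self.n_nodes} nodes"
            )
        if self.symmetric:
            dev = np.abs(self.matrices - self.matrices.transpose(0, 2, 1)).max()
            if dev > SYMMETRY_TOL:
                raise DataError(
                    f"cohort flagged symmetric but max |M - M^T| = {dev:.3g} > {SYMMETRY_TOL}"
                )

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int((self.labels == 0).sum()), int((self.labels == 1).sum())


@dataclass
class DesignMatrix:
    """Vectorized cohort: one row per subject, one column per edge."""

    X: np.ndarray
    Y: np.ndarray
    feature_map: list
    labels: np.ndarray
    mode: str
    standardization: dict | None = None
    subjects: list | None = None
    roi_names: list | None = None
    n_nodes: int = 0

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return self.Y.shape[1]

    def raw_column(self, j: int) -> np.ndarray:
        """Column *j* of X on the original (pre-standardization) scale."""
        col = self.X[:, j].copy()
        if self.standardization is not None:
            col = col * self.standardization["scale"][j] + self.standardization["mean"][j]
        return col


@dataclass
class EdgeSelection:
    """A final set of selected edges with provenance.

    ``edges`` holds 0-based unordered node pairs (i < j); on-disk edge lists
    are written 1-based with ROI names when available, following the usual
    neuroimaging table convention.
    """

    edges: list
    counts: list
    method: str
    roi_names: list | None = None
    reciprocal: list | None = None

    def __len__(self):
        return len(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, ((i, j), c) in enumerate(zip(self.edges, self.counts)):
            rows.append(
                {
                    "edge_id": k + 1,
                    "node_i": i + 1,
                    "node_j": j + 1,
                    "roi_i": self.roi_names[i] if self.roi_names else f"node{i + 1}",
                    "roi_j": self.roi_names[j] if self.roi_names else f"node{j + 1}",
                    "occurrence_count": c,
                    "method": self.method,
                }
            )
        cols = ["edge_id", "node_i", "node_j", "roi_i", "roi_j", "occurrence_count", "method"]
        return pd.DataFrame(rows, columns=cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_graphml(self, path) -> None:
        g = nx.Graph()
        for (i, j), c in zip(self.edges, self.counts):
            ni = self.roi_names[i] if self.roi_names else f"node{i + 1}"
            nj = self.roi_names[j] if self.roi_names else f"node{j + 1}"
            g.add_edge(ni, nj, occurrence_count=int(c), method=self.method)
        nx.write_graphml(g, path)


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return r"\s+"


def read_matrix(path) -> tuple[np.ndarray, list | None]:
    """Read one square numeric matrix from a CSV/TSV/whitespace file.

    A non-numeric first row/column is interpreted as ROI names and stripped.
    Returns ``(matrix, roi_names_or_None)``.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    text = path.read_text()
    sep = _sniff_delimiter(text)
    try:
        df = pd.read_csv(_stdlib_io.StringIO(text), sep=sep, header=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse {path}: {exc}") from exc

    roi_names = None
    first_cell = df.iloc[0, 0]
    if isinstance(first_cell, str) and not _is_number(first_cell):
        # header row (and matching first column) of ROI names
        roi_names = [str(v) for v in df.iloc[0, 1:]] if df.shape[1] == df.shape[0] else [
            str(v) for v in df.iloc[0, :]
        ]
        df = df.iloc[1:, :]
        if df.shape[1] == df.shape[0] + 1:
            df = df.iloc[:, 1:]
    try:
        mat = df.astype(float).to_numpy()
    except (TypeError, ValueError):
        bad = _first_non_numeric(df)
        raise DataError(f"non-numeric cell at row {bad[0]}, column {bad[1]} in {path}")
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise DataError(f"matrix in {path} is not square: shape {mat.shape}")
    if not np.all(np.isfinite(mat)):
        raise DataError(f"non-finite entries in {path}")
    return mat, roi_names


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _first_non_numeric(df: pd.DataFrame) -> tuple[int, int]:
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            if not _is_number(str(df.iloc[i, j])):
                return i, j
    return -1, -1  # pragma: no cover


def read_manifest(path) -> tuple[list, list]:
    """Read a two-column cohort manifest (matrix path, group label).

    Relative matrix paths are resolved against the manifest's directory.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest file not found: {path}")
    paths, labels = [], []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample else ","
        for row in csv.reader(fh, delimiter=delim):
            if not row or row[0].strip().startswith("#"):
                continue
            if len(row) < 2:
                raise DataError(f"manifest row needs 2 columns (path, label): {row}")
            p = Path(row[0].strip())
            if not p.is_absolute():
                p = path.parent / p
            paths.append(p)
            labels.append(row[1].strip())
    if not paths:
        raise DataError(f"manifest {path} is empty")
    return paths, labels


def load_cohort(matrix_paths: Sequence, labels: Sequence, roi_names_path=None) -> ConnectomeCohort:
    """Load and validate a cohort from per-subject matrix files.

    Labels may be arbitrary values with exactly two distinct levels; they are
    recoded to {0, 1} in order of first appearance.  The symmetry flag is
    auto-detected.
    """
    if len(matrix_paths) != len(labels):
        raise DataError(f"{len(matrix_paths)} matrix paths but {len(labels)} labels")
    mats, roi_from_file = [], None
    for p in matrix_paths:
        m, roi = read_matrix(p)
        mats.append(m)
        if roi is not None and roi_from_file is None:
            roi_from_file = roi
    sizes = {m.shape[0] for m in mats}
    if len(sizes) > 1:
        detail = ", ".join(f"{Path(p).name}: {m.shape[0]}" for p, m in zip(matrix_paths, mats))
        raise DataError(f"matrices disagree on node count ({detail})")

    distinct = list(dict.fromkeys(labels))
    if len(distinct) != 2:
        raise DataError(f"labels must have exactly two distinct values, got {distinct}")
    codes = np.array([distinct.index(l) for l in labels], dtype=int)
    n0, n1 = int((codes == 0).sum()), int((codes == 1).sum())
    if min(n0, n1) < 2:
        raise DataError(f"degenerate cohort: group sizes {n0} and {n1} (need >= 2 each)")

    roi_names = roi_from_file
    if roi_names_path is not None:
        roi_names = [l.strip() for l in Path(roi_names_path).read_text().splitlines() if l.strip()]

    stack = np.stack(mats)
    symmetric = bool(np.abs(stack - stack.transpose(0, 2, 1)).max() <= SYMMETRY_TOL)
    subjects = [Path(p).stem for p in matrix_paths]
    return ConnectomeCohort(
        subjects=subjects,
        matrices=stack,
        labels=codes,
        roi_names=roi_names,
        symmetric=symmetric,
        label_names={0: distinct[0], 1: distinct[1]},
    )


def feature_map_for(n_nodes: int, mode: str) -> list:
    """Deterministic column -> node-pair map (row-major)."""
    if mode == "upper_triangle":
        return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    if mode == "full_offdiag":
        return [(i, j) for i in range(n_nodes) for j in range(n_nodes) if i != j]
    raise DataError(f"unknown vectorization mode {mode!r}")


def vectorize(
    cohort: ConnectomeCohort,
    mode: str = "upper_triangle",
    standardize: str = "zscore",
) -> DesignMatrix:
    """Vectorize a cohort into the design matrix X and indicator matrix Y.

    Parameters
    ----------
    mode : {"upper_triangle", "full_offdiag"}
        ``upper_triangle`` (requires a symmetric cohort) keeps strict
        upper-triangle entries, p = R(R-1)/2; ``full_offdiag`` keeps every
        off-diagonal entry, p = R(R-1).
    standardize : {"none", "zscore"}
        With ``zscore`` each column is centered and scaled by its sample
        standard deviation (ddof=1); zero-variance columns are centered only
        and recorded under ``standardization["zero_variance"]``.
    """
    if mode == "upper_triangle" and not cohort.symmetric:
        raise DataError("upper_triangle vectorization requires a symmetric cohort")
    if standardize not in ("none", "zscore"):
        raise DataError(f"unknown standardize option {standardize!r}")
    fmap = feature_map_for(cohort.n_nodes, mode)
    rows, cols = zip(*fmap)
    X = cohort.matrices[:, rows, cols].astype(float)
    n = X.shape[0]
    K = 2
    if n < K:
        raise DataError(f"need at least {K} subjects, got {n}")
    Y = np.zeros((n, K))
    Y[np.arange(n), cohort.labels] = 1.0

    standardization = None
    if standardize == "zscore":
        mean = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        zero_var = np.flatnonzero(scale == 0)
        safe = np.where(scale == 0, 1.0, scale)
        X = (X - mean) / safe
        standardization = {"mean": mean, "scale": safe, "zero_variance": zero_var}
        if zero_var.size:
            warnings.warn(
                f"{zero_var.size} zero-variance columns centered but not scaled",
                stacklevel=2,
            )
    return DesignMatrix(
        X=X,
        Y=Y,
        feature_map=fmap,
        labels=cohort.labels.copy(),
        mode=mode,
        standardization=standardization,
        subjects=list(cohort.subjects),
        roi_names=cohort.roi_names,
        n_nodes=cohort.n_nodes,
    )


def map_features_to_edges(
    selection: Iterable[int],
    design: DesignMatrix,
    roi_names: list | None = None,
    counts: np.ndarray | dict | None = None,
    method: str = "mla",
) -> EdgeSelection:
    """Translate selected design-matrix columns back to brain-network edges.

    In ``full_offdiag`` mode both directions of a connection are distinct
    columns; they are reported as one unordered edge with ``reciprocal=True``
    when both were selected (the occurrence count is the larger of the two).
    """
    p = design.n_features
    sel = sorted(set(int(j) for j in selection))
    for j in sel:
        if j < 0 or j >= p:
            raise DataError(f"feature index {j} out of bounds for p={p}")

    def count_of(j):
        if counts is None:
            return 1
        if isinstance(counts, dict):
            return int(counts[j])
        return int(np.asarray(counts)[j])

    merged: dict[tuple[int, int], dict] = {}
    for j in sel:
        i, k = design.feature_map[j]
        key = (min(i, k), max(i, k))
        if key in merged:
            merged[key]["reciprocal"] = True
            merged[key]["count"] = max(merged[key]["count"], count_of(j))
        else:
            merged[key] = {"count": count_of(j), "reciprocal": False}
    keys = sorted(merged)
    return EdgeSelection(
        edges=keys,
        counts=[merged[k]["count"] for k in keys],
        method=method,
        roi_names=roi_names if roi_names is not None else design.roi_names,
        reciprocal=[merged[k]["reciprocal"] for k in keys],
    )
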