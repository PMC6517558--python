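"""Phenotype stratification from binarized clinical questionnaires.

The similarity between two individuals is the plug-in mutual information of
their binary response vectors, estimated from the empirical 2x2 joint over
the questionnaire items:

    MI(x, y) = sum_{a,b in {0,1}} p(a,b) log2[ p(a,b) / (p(a) p(b)) ]

with the convention 0*log 0 = 0 (units: bits by default, configurable to
nats). The resulting kernel matrix is symmetric, non-negative, and its
diagonal is the entropy of each individual's responses.

Clustering uses the symmetric normalized Laplacian (Ng-Jordan-Weiss): the
top-k eigenvectors of ``D^{-1/2} S D^{-1/2}`` are row-normalized and
partitioned by k-means (k-means++ with a fixed seed and multiple restarts).
Visualization uses kernel PCA: the kernel is double-centred, eigendecomposed,
and coordinates are eigenvectors scaled by the square roots of the
(non-negative) eigenvalues; negative-eigenvalue components of the possibly
indefinite MI kernel are discarded with a logged count, and eigenvector signs
are fixed by forcing the largest-magnitude entry positive.

Both steps are also exposed as sklearn-style estimators
(:class:`MISpectralClustering`, :class:`MIKernelPCA`) that accept either a
binary questionnaire matrix or a precomputed similarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "QuestionnaireMatrix",
    "SimilarityMatrix",
    "ClusterAssignment",
    "binarize",
    "mutual_information",
    "similarity_matrix",
    "MISpectralClustering",
    "MIKernelPCA",
    "spectral_cluster",
    "kernel_pca",
    "characterize_clusters",
]

_LOG_BASE = {"bits": 2.0, "nats": np.e}


@dataclass
class QuestionnaireMatrix:
    """Individuals x items binary matrix; NaN marks a missing response."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        bad = ~(np.isnan(arr) | (arr == 0) | (arr == 1))
        if bad.any():
            raise ValueError("questionnaire entries must be 0, 1 or missing")


@dataclass
class SimilarityMatrix:
    """Pairwise mutual-information kernel over individuals."""

    values: np.ndarray
    ids: list[str]
    unit: str = "bits"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if (self.values < -1e-12).any():
            raise ValueError("mutual information entries must be non-negative")


@dataclass
class ClusterAssignment:
    """Spectral-cluster labels (0-based), 3-D kernel-PCA embedding and per-cluster feature frequencies."""

    labels: np.ndarray
    k: int
    embedding: np.ndarray
    feature_profile: pd.DataFrame | None = None
    ids: list[str] | None = None


# ---------------------------------------------------------------------------
# binarization


def binarize(raw: pd.DataFrame, rules: dict[str, dict]) -> QuestionnaireMatrix:
    """Apply per-item binarization rules; missing values stay missing.

    Rule kinds: ``{"kind": "binary"}`` (already 0/1), ``{"kind": "threshold",
    "ge": t}`` (1 iff value >= t) and ``{"kind": "category", "positive":
    [...]}`` (1 iff the value is in the positive set). Items without a rule
    raise, listing them all.
    """
    missing_rules = [c for c in raw.columns if c not in rules]
    if missing_rules:
        raise ValueError(f"no binarization rule for items: {missing_rules}")
    out = {}
    for col in raw.columns:
        rule = rules[col]
        kind = rule.get("kind")
        s = raw[col]
        na = s.isna()
        if kind == "binary":
            vals = s.astype(float)
            if not vals[~na].isin((0.0, 1.0)).all():
                raise ValueError(f"item {col!r} declared binary but has non-binary values")
        elif kind == "threshold":
            vals = (s.astype(float) >= float(rule["ge"])).astype(float)
        elif kind == "category":
            vals = s.isin(rule["positive"]).astype(float)
        else:
            raise ValueError(f"unknown rule kind {kind!r} for item {col!r}")
        vals[na] = np.nan
        out[col] = vals
    return QuestionnaireMatrix(pd.DataFrame(out, index=raw.index))


# ---------------------------------------------------------------------------
# mutual information


def mutual_information(x, y, unit: str = "bits") -> float:
    """Plug-in mutual information between two binary vectors.

    Missing entries are dropped pairwise; fewer than 2 complete pairs raise.
    The estimate is clipped at 0 against floating-point round-off (the
    plug-in MI is mathematically non-negative).
    """
    base = _LOG_BASE[unit]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 2:
        raise ValueError("need at least 2 pairwise-complete observations")
    x, y = x[keep], y[keep]
    n = len(x)
    joint = np.array(
        [
            [np.count_nonzero((x == 0) & (y == 0)), np.count_nonzero((x == 0) & (y == 1))],
            [np.count_nonzero((x == 1) & (y == 0)), np.count_nonzero((x == 1) & (y == 1))],
        ],
        dtype=float,
    ) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    def term(a: int, b: int) -> float:
        p = joint[a, b]
        return p * np.log(p / (px[a] * py[b])) / np.log(base) if p > 0 else 0.0

    # grouped so that swapping x and y gives bit-identical sums (IEEE addition
    # is commutative): the diagonal terms are swap-invariant, the off-diagonal
    # pair only exchanges its two commuting addends
    mi = (term(0, 0) + term(1, 1)) + (term(0, 1) + term(1, 0))
    return max(mi, 0.0)


def _mi_matrix_complete(X: np.ndarray, unit: str) -> np.ndarray:
    """Vectorized MI kernel for a complete (no-missing) binary matrix."""
    base = _LOG_BASE[unit]
    n, m = X.shape
    X1 = X
    X0 = 1.0 - X
    c = np.empty((4, n, n))
    c[0] = X0 @ X0.T  # (0,0)
    c[1] = X0 @ X1.T  # (0,1)
    c[2] = X1 @ X0.T  # (1,0)
    c[3] = X1 @ X1.T  # (1,1)
    joint = c / m
    p1 = X1.mean(axis=1)
    p0 = 1.0 - p1
    marg = np.empty((4, n, n))
    marg[0] = np.outer(p0, p0)
    marg[1] = np.outer(p0, p1)
    marg[2] = np.outer(p1, p0)
    marg[3] = np.outer(p1, p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * (np.log(joint) - np.log(marg)) / np.log(base)
    terms[joint == 0] = 0.0
    S = terms.sum(axis=0)
    S = np.clip((S + S.T) / 2.0, 0.0, None)  # symmetrize away round-off
    return S


def similarity_matrix(
    Q: QuestionnaireMatrix | pd.DataFrame,
    unit: str = "bits",
    max_missing: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise MI kernel over individuals.

    Individuals with more than ``max_missing`` fraction of missing responses
    (in particular all-missing ones) are excluded with logged ids.
    """
    df = Q.values if isinstance(Q, QuestionnaireMatrix) else QuestionnaireMatrix(Q).values
    arr = df.to_numpy(dtype=float)
    if len(df) < 2:
        raise ValueError("need at least 2 individuals")
    miss_frac = np.isnan(arr).mean(axis=1)
    keep = miss_frac <= max_missing
    if not keep.all():
        dropped = list(df.index[~keep].astype(str))
        logger.warning("excluding %d individuals with >%.0f%% missing responses: %s",
                       len(dropped), 100 * max_missing, dropped)
        arr = arr[keep]
        df = df.iloc[keep]
    n = len(df)
    if n < 2:
        raise ValueError("fewer than 2 individuals remain after missingness exclusion")
    if not np.isnan(arr).any():
        S = _mi_matrix_complete(arr, unit)
    else:
        S = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                S[i, j] = S[j, i] = mutual_information(arr[i], arr[j], unit=unit)
    return SimilarityMatrix(values=S, ids=list(df.index.astype(str)), unit=unit)


# ---------------------------------------------------------------------------
# estimators


def _as_similarity(X, affinity: str, unit: str, max_missing: float) -> tuple[np.ndarray, list[str]]:
    if affinity == "precomputed":
        if isinstance(X, SimilarityMatrix):
            return X.values, list(X.ids)
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("precomputed affinity must be a square matrix")
        return arr, [str(i) for i in range(arr.shape[0])]
    if affinity == "mutual_information":
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
        S = similarity_matrix(df, unit=unit, max_missing=max_missing)
        return S.values, S.ids
    raise ValueError(f"unknown affinity {affinity!r}")


class MISpectralClustering(ClusterMixin, BaseEstimator):
    """Spectral clustering on the mutual-information kernel (NJW algorithm).

    Parameters
    ----------
    n_clusters : int, default 4
        Number of clusters (four phenotype subgroups by default).
    affinity : {"mutual_information", "precomputed"}
        Whether ``X`` in :meth:`fit` is a binary questionnaire matrix or an
        already-computed similarity matrix.
    unit : {"bits", "nats"}
        Logarithm base of the MI estimates.
    n_init : int, default 50
        k-means++ restarts.
    random_state : int or None
        Seed for the k-means step; fixing it makes the pipeline
        deterministic end to end.

    Attributes
    ----------
    affinity_matrix_ : ndarray of shape (n, n)
    embedding_ : ndarray of shape (n, n_clusters)
        Row-normalized spectral embedding fed to k-means.
    labels_ : ndarray of shape (n,)
        0-based cluster labels.
    """

    def __init__(self, n_clusters: int = 4, affinity: str = "mutual_information",
                 unit: str = "bits", n_init: int = 50, random_state: int | None = None,
                 max_missing: float = 0.5):
        self.n_clusters = n_clusters
        self.affinity = affinity
        self.unit = unit
        self.n_init = n_init
        self.random_state = random_state
        self.max_missing = max_missing

    def fit(self, X, y=None):
        S, ids = _as_similarity(X, self.affinity, self.unit, self.max_missing)
        n = S.shape[0]
        if not 1 <= self.n_clusters <= n:
            raise ValueError(f"n_clusters must be in [1, {n}], got {self.n_clusters}")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("affinity matrix must be symmetric")
        if (S < -1e-10).any():
            raise ValueError("affinity matrix must be non-negative")
        n_comp, _ = connected_components(csr_matrix(S > 1e-12), directed=False)
        if n_comp > self.n_clusters:
            raise ValueError(
                f"similarity graph has {n_comp} connected components but only "
                f"{self.n_clusters} clusters were requested; lower the component "
                "count (check questionnaire connectivity) or raise n_clusters"
            )
        d = S.sum(axis=1)
        with np.errstate(divide="ignore"):
            d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(d), 0.0)
        M = d_inv_sqrt[:, None] * S * d_inv_sqrt[None, :]
        eigvals, eigvecs = np.linalg.eigh(M)
        U = eigvecs[:, ::-1][:, : self.n_clusters]  # top-k eigenvectors
        norms = np.linalg.norm(U, axis=1, keepdims=True)
        U = np.where(norms > 0, U / np.where(norms == 0, 1.0, norms), 0.0)
        km = KMeans(
            n_clusters=self.n_clusters,
            n_init=self.n_init,
            random_state=self.random_state,
        ).fit(U)
        self.affinity_matrix_ = S
        self.embedding_ = U
        self.labels_ = km.labels_
        self.ids_ = ids
        self.eigenvalues_ = eigvals[::-1][: self.n_clusters]
        return self


class MIKernelPCA(TransformerMixin, BaseEstimator):
    """Kernel PCA on the mutual-information kernel (3-D by default).

    The kernel is double-centred (row, column and grand mean), eigendecomposed
    and the embedding coordinates are eigenvectors scaled by the square roots
    of the retained non-negative eigenvalues. The MI kernel may be indefinite;
    negative-eigenvalue components are discarded with a logged count. Signs
    are fixed by forcing each component's largest-magnitude entry positive.

    Attributes
    ----------
    embedding_ : ndarray of shape (n, n_components)
    eigenvalues_ : ndarray of the retained eigenvalues (descending).
    n_discarded_ : int, count of negative-eigenvalue components discarded.
    """

    def __init__(self, n_components: int = 3, affinity: str = "mutual_information",
                 unit: str = "bits", max_missing: float = 0.5):
        self.n_components = n_components
        self.affinity = affinity
        self.unit = unit
        self.max_missing = max_missing

    def fit(self, X, y=None):
        S, ids = _as_similarity(X, self.affinity, self.unit, self.max_missing)
        n = S.shape[0]
        if not 1 <= self.n_components <= n - 1:
            raise ValueError(f"n_components must be in [1, {n - 1}], got {self.n_components}")
        row_mean = S.mean(axis=1, keepdims=True)
        grand = S.mean()
        K = S - row_mean - row_mean.T + grand
        eigvals, eigvecs = np.linalg.eigh(K)
        eigvals, eigvecs = eigvals[::-1], eigvecs[:, ::-1]
        n_neg = int(np.count_nonzero(eigvals < -1e-10))
        if n_neg:
            logger.info("MI kernel is indefinite: discarding %d negative-eigenvalue components", n_neg)
        pos = eigvals > 1e-12
        if not pos.any():
            logger.warning("kernel has no positive eigenvalues (all-equal rows?); zero embedding")
            self.embedding_ = np.zeros((n, self.n_components))
            self.eigenvalues_ = np.zeros(self.n_components)
            self.components_vectors_ = np.zeros((n, self.n_components))
            self.n_discarded_ = n_neg
            self.ids_ = ids
            self._row_mean = row_mean
            self._grand = grand
            return self
        eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
        d = min(self.n_components, len(eigvals))
        eigvals, eigvecs = eigvals[:d], eigvecs[:, :d]
        # deterministic sign: largest-|entry| positive
        for c in range(eigvecs.shape[1]):
            i_max = np.argmax(np.abs(eigvecs[:, c]))
            if eigvecs[i_max, c] < 0:
                eigvecs[:, c] = -eigvecs[:, c]
        emb = eigvecs * np.sqrt(eigvals)
        if d < self.n_components:  # pad with zero coordinates
            emb = np.hstack([emb, np.zeros((n, self.n_components - d))])
            eigvals = np.concatenate([eigvals, np.zeros(self.n_components - d)])
            eigvecs = np.hstack([eigvecs, np.zeros((n, self.n_components - d))])
        self.embedding_ = emb
        self.eigenvalues_ = eigvals
        self.components_vectors_ = eigvecs
        self.n_discarded_ = n_neg
        self.ids_ = ids
        self._train_similarity = S
        self._row_mean = row_mean
        self._grand = grand
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        """Project a similarity block against the training samples.

        ``X`` must be an (m x n_train) cross-kernel (affinity="precomputed")
        or a binary matrix whose MI against the training data can only be
        computed when the estimator itself was fit on raw data of identical
        item set; for the common in-sample use, ``transform`` of the training
        kernel reproduces ``embedding_``.
        """
        if self.affinity != "precomputed":
            raise NotImplementedError(
                "out-of-sample transform is only supported with affinity='precomputed'"
            )
        K_cross = np.asarray(X, dtype=float)
        Kc = (
            K_cross
            - K_cross.mean(axis=1, keepdims=True)
            - self._row_mean.T
            + self._grand
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(self.eigenvalues_ > 0, 1.0 / np.sqrt(self.eigenvalues_), 0.0)
        return Kc @ self.components_vectors_ * scale


# ---------------------------------------------------------------------------
# functional wrappers


def spectral_cluster(S: SimilarityMatrix | np.ndarray, k: int = 4,
                     seed: int | None = None, n_init: int = 50) -> np.ndarray:
    """NJW spectral clustering of a precomputed MI kernel; returns 0-based labels."""
    model = MISpectralClustering(
        n_clusters=k, affinity="precomputed", n_init=n_init, random_state=seed
    ).fit(S)
    return model.labels_


def kernel_pca(S: SimilarityMatrix | np.ndarray, d: int = 3) -> np.ndarray:
    """Kernel-PCA embedding of a precomputed MI kernel (n x d)."""
    return MIKernelPCA(n_components=d, affinity="precomputed").fit(S).embedding_


def characterize_clusters(
    Q: QuestionnaireMatrix | pd.DataFrame,
    labels: np.ndarray,
    top: int = 10,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """Per-cluster relative frequency of each item, plus the top-N items.

    Frequencies exclude missing responses from the denominator; top lists are
    sorted by descending frequency with lexicographic tie-break. Empty
    clusters get all-NaN rows. The same item may appear in several clusters'
    top lists (overlap is expected).
    """
    df = Q.values if isinstance(Q, QuestionnaireMatrix) else QuestionnaireMatrix(Q).values
    labels = np.asarray(labels)
    if len(labels) != len(df):
        raise ValueError("labels must cover every individual in the questionnaire")
    clusters = sorted(np.unique(labels))
    profile = pd.DataFrame(index=pd.Index(clusters, name="cluster"), columns=df.columns,
                           dtype=float)
    tops: dict[int, list[str]] = {}
    for c in clusters:
        members = df[labels == c]
        if members.empty:
            tops[int(c)] = []
            continue
        freq = members.mean(axis=0, skipna=True)
        profile.loc[c] = freq
        order = sorted(df.columns, key=lambda item: (-(0 if pd.isna(freq[item]) else freq[item]), item))
        tops[int(c)] = order[:top]
    return profile, tops
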