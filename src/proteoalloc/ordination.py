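"""Sample-level ordination of proteome profiles.

PCA treats samples as observations and proteins as variables of the
complete (imputed) log2 matrix; variables are centered and, optionally,
scaled to unit variance.  The sign of each component is fixed by convention
— the largest-magnitude loading is made positive — so results are fully
deterministic.  Hierarchical clustering is agglomerative over the same
sample profiles with a documented lowest-index tie-break (scipy's default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = ["PCAResult", "ProteomePCA", "pca_scores", "ClusterTree", "hclust_samples"]


def _require_complete(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        raise ValueError(
            "matrix contains missing values; run imputation before ordination"
        )


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # proteins x components
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


class ProteomePCA(BaseEstimator):
    """PCA of samples over protein variables of a complete log2 matrix.

    Parameters
    ----------
    n_components : int
        Number of components; must not exceed min(n_samples - 1, n_proteins).
    scale : bool, default False
        Scale proteins to unit variance before decomposition (off by
        default, the abundance-proteomics convention).
    """

    def __init__(self, n_components: int = 2, scale: bool = False):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: pd.DataFrame, y=None):
        _require_complete(X)
        data = X.to_numpy(dtype=float).T  # samples x proteins
        n_samples, n_proteins = data.shape
        max_k = min(n_samples - 1, n_proteins)
        if not 1 <= self.n_components <= max_k:
            raise ValueError(
                f"n_components must be in [1, {max_k}] for "
                f"{n_samples} samples x {n_proteins} proteins"
            )
        self.mean_ = data.mean(axis=0)
        centered = data - self.mean_
        if self.scale:
            sd = centered.std(axis=0, ddof=1)
            self.scale_ = np.where(sd > 0, sd, 1.0)
            centered = centered / self.scale_
        else:
            self.scale_ = None
        pca = PCA(n_components=self.n_components, svd_solver="full")
        scores = pca.fit_transform(centered)
        components = pca.components_  # k x proteins
        # sign convention: largest-|loading| entry of each component positive
        for k in range(components.shape[0]):
            j = np.argmax(np.abs(components[k]))
            if components[k, j] < 0:
                components[k] *= -1
                scores[:, k] *= -1
        total_var = centered.var(axis=0, ddof=1).sum()
        if total_var > 0:
            ratio = pca.explained_variance_ / total_var
        else:  # all samples identical: no variance to explain
            ratio = np.zeros(self.n_components)
            scores = np.zeros_like(scores)
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        self.result_ = PCAResult(
            scores=pd.DataFrame(scores, index=X.columns, columns=cols),
            loadings=pd.DataFrame(components.T, index=X.index, columns=cols),
            explained_variance_ratio=np.asarray(ratio),
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        _require_complete(X)
        data = X.to_numpy(dtype=float).T - self.mean_
        if self.scale_ is not None:
            data = data / self.scale_
        scores = data @ self.result_.loadings.to_numpy()
        return pd.DataFrame(
            scores, index=X.columns, columns=self.result_.scores.columns
        )


def pca_scores(
    logmatrix: pd.DataFrame, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """One-shot PCA of a complete log2 matrix (samples as observations)."""
    return ProteomePCA(n_components=n_components, scale=scale).fit(logmatrix).result_


@dataclass(frozen=True)
class ClusterTree:
    """Agglomerative merge tree over samples."""

    linkage_matrix: np.ndarray  # scipy linkage format
    labels: tuple[str, ...]
    method: str
    metric: str

    def __post_init__(self) -> None:
        heights = self.linkage_matrix[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError(f"non-monotone merge heights for linkage {self.method!r}")

    def to_newick(self) -> str:
        """Serialize the tree as Newick with branch lengths."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"


_ALLOWED_LINKAGE = {"single", "complete", "average", "ward", "centroid", "median"}


def hclust_samples(
    logmatrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusterTree:
    """Hierarchical clustering of samples on a complete log2 matrix."""
    _require_complete(logmatrix)
    if logmatrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    if method not in _ALLOWED_LINKAGE:
        raise ValueError(f"unknown linkage method {method!r}")
    data = logmatrix.to_numpy(dtype=float).T
    try:
        distances = pdist(data, metric=metric)
    except ValueError as exc:
        raise ValueError(f"unknown distance metric {metric!r}") from exc
    Z = hierarchy.linkage(distances, method=method)
    return ClusterTree(
        linkage_matrix=Z,
        labels=tuple(map(str, logmatrix.columns)),
        method=method,
        metric=metric,
    )
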