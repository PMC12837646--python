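"""Chemometric layer: correlations, standardized PCA, hierarchical clustering.

All three operate on the samples x responses table of assay means.  PCA is
performed on standardized variables (equivalently, on the correlation
matrix) because the thirteen responses carry heterogeneous units; the
cluster analysis deliberately works in raw units with City-block
(Manhattan) distances and complete linkage, the combination under which one
extraction run separates from all others at a large merge height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _SKPCA

from .data import ResponseMatrix
from .metrics import pearson_test

__all__ = ["PCAResult", "DendrogramResult", "correlation_matrix", "pca",
           "hcluster", "cut_tree"]


def correlation_matrix(responses: ResponseMatrix
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations with two-sided p-values.

    Returns (r, p) DataFrames, symmetric with unit diagonal.  A constant
    response yields NaN in its row/column.
    """
    if responses.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    names = responses.response_names
    m = len(names)
    r = np.eye(m)
    p = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                rij, pij = pearson_test(responses.means[:, i],
                                        responses.means[:, j])
            except ValueError:
                rij, pij = np.nan, np.nan
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    return (pd.DataFrame(r, index=names, columns=names),
            pd.DataFrame(p, index=names, columns=names))


@dataclass
class PCAResult:
    """Explained-variance percentages, loadings and sample scores."""

    explained_pct: np.ndarray           # one entry per component, sums to 100
    loadings: pd.DataFrame              # responses x components, orthonormal
    scores: pd.DataFrame                # samples x components


def pca(responses: ResponseMatrix, standardize: bool = True) -> PCAResult:
    """Principal component analysis of the response table.

    With ``standardize`` (the default) every response is z-scored first, so
    the decomposition is that of the correlation matrix and no response
    dominates through its units.  Components are ordered by decreasing
    variance, and each loading vector is oriented so its largest-magnitude
    entry is positive.
    """
    if responses.n_samples < 2 or len(responses.response_names) < 2:
        raise ValueError("PCA needs at least 2 samples and 2 responses")
    X = responses.means.astype(float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [responses.response_names[k]
                   for k in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant response(s) under standardization: "
                             f"{bad}")
        X = (X - X.mean(axis=0)) / sd
    n_components = min(X.shape[0] - 1, X.shape[1])
    fitter = _SKPCA(n_components=n_components, svd_solver="full")
    scores = fitter.fit_transform(X)
    loadings = fitter.components_.T          # responses x components
    # sign convention: dominant entry of every loading vector positive
    for k in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        explained_pct=fitter.explained_variance_ratio_ * 100.0,
        loadings=pd.DataFrame(loadings, index=responses.response_names,
                              columns=comp_names),
        scores=pd.DataFrame(scores,
                            index=pd.Index(responses.sample_ids,
                                           name="sample_id"),
                            columns=comp_names))


@dataclass
class DendrogramResult:
    """Agglomerative merge history over the extraction runs.

    ``linkage`` is the standard (n-1) x 4 merge matrix (node, node, height,
    size) with leaves numbered 0..n-1 in ``leaf_labels`` order.
    """

    linkage: np.ndarray
    leaf_labels: list[int]

    def merges(self) -> pd.DataFrame:
        n = len(self.leaf_labels)
        return pd.DataFrame(
            {"node_a": self.linkage[:, 0].astype(int),
             "node_b": self.linkage[:, 1].astype(int),
             "height": self.linkage[:, 2],
             "size": self.linkage[:, 3].astype(int),
             "new_node": np.arange(n, n + self.linkage.shape[0])})


def hcluster(responses: ResponseMatrix, metric: str = "cityblock",
             method: str = "complete") -> DendrogramResult:
    """Agglomerative clustering of the samples on raw response means."""
    if responses.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    Z = hierarchy.linkage(responses.means, method=method, metric=metric)
    return DendrogramResult(linkage=Z,
                            leaf_labels=list(responses.sample_ids))


def cut_tree(dendrogram: DendrogramResult, k: int) -> dict[int, int]:
    """Cut the dendrogram into k groups (the k-1 highest merges).

    Returns sample_id -> cluster label (labels 1..k, renumbered in order of
    first appearance).
    """
    n = len(dendrogram.leaf_labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    flat = hierarchy.fcluster(dendrogram.linkage, t=k, criterion="maxclust")
    relabel, labels = {}, {}
    for sample, raw in zip(dendrogram.leaf_labels, flat):
        labels[sample] = relabel.setdefault(int(raw), len(relabel) + 1)
    return labels
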