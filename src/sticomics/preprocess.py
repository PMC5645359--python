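"""Normalization, log transform, variable-gene selection, Ward clustering.

Every expression analysis in the package runs on log-normalized values
produced here: median-of-ratios size factors (the standard RNA-seq
between-sample normalization), a log2(x/factor + 1) transform, selection of
the most variable genes, and agglomerative (Ward) clustering under Euclidean
or Pearson-correlation distance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix

__all__ = [
    "size_factors",
    "log_normalize",
    "total_count_factors",
    "select_most_variable",
    "ward_cluster",
    "WardClustering",
]


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a positive count in every sample; the
    factor for sample j is the median over reference genes of
    count_gj / geometric-mean_g(count).  Factors are rescaled to geometric
    mean 1 so normalized totals stay on the scale of the input.
    """
    if m.state != "raw_counts":
        raise ValueError("size factors are defined on raw counts")
    counts = m.to_numpy()
    ref = np.all(counts > 0, axis=1)
    if not ref.any():
        raise ValueError(
            "no reference genes (every gene has a zero count in some sample); "
            "consider filtering or adding a pseudocount before normalization"
        )
    refc = counts[ref]
    geomean = np.exp(np.mean(np.log(refc), axis=1, keepdims=True))
    factors = np.median(refc / geomean, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.samples, name="size_factor")


def total_count_factors(m: ExpressionMatrix) -> pd.Series:
    """Total-count scaling factors (used for low-abundance miRNA panels,
    where most genes carry zeros and the median-of-ratios reference set is
    unstable).  Rescaled to geometric mean 1."""
    if m.state != "raw_counts":
        raise ValueError("scaling factors are defined on raw counts")
    totals = m.to_numpy().sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("every sample needs a positive total count")
    factors = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(factors, index=m.samples, name="size_factor")


def log_normalize(m: ExpressionMatrix, factors: pd.Series) -> ExpressionMatrix:
    """log2(count / factor + 1); flips the state flag to log_normalized."""
    if m.state != "raw_counts":
        raise ValueError("log_normalize expects raw counts")
    if len(factors) != m.n_samples or not factors.index.equals(m.samples):
        raise ValueError("size factors do not match the matrix samples")
    if np.any(factors.to_numpy() <= 0):
        raise ValueError("size factors must be positive")
    vals = np.log2(m.to_numpy() / factors.to_numpy()[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.genes, columns=m.samples),
        state="log_normalized",
        annotations=m.annotations,
    )


def select_most_variable(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Restrict to the k genes with the largest across-sample variance.

    Requires log-normalized input (variance ranking on raw counts is
    confounded by scale).  Original gene order is preserved within the
    selection; variance ties break by gene id (lexicographic).
    """
    if m.state != "log_normalized":
        raise ValueError("variable-gene selection requires log-normalized values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m.n_genes:
        if k > m.n_genes:
            warnings.warn(
                f"k={k} exceeds the number of genes ({m.n_genes}); returning all",
                stacklevel=2,
            )
        return m
    var = m.values.var(axis=1, ddof=1)
    ranking = pd.DataFrame(
        {"var": var.to_numpy(), "gene": m.genes.astype(str)}
    ).sort_values(by=["var", "gene"], ascending=[False, True], kind="stable")
    keep = set(ranking["gene"].iloc[:k])
    selected = [g for g in m.genes if g in keep]
    return ExpressionMatrix(m.values.loc[selected], state=m.state, annotations=m.annotations)


class WardClustering:
    """Result of agglomerative clustering: scipy linkage matrix + helpers."""

    def __init__(self, linkage: np.ndarray, sample_ids: pd.Index, distance: str):
        self.linkage = linkage
        self.sample_ids = sample_ids
        self.distance = distance

    def cut(self, k: int) -> pd.Series:
        """Labels from cutting the merge tree into k clusters (1..k)."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def to_newick(self) -> str:
        """Nested-parenthesis (Newick) rendering of the merge tree."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node) -> str:
            if node.is_leaf():
                return str(self.sample_ids[node.id])
            return f"({render(node.left)},{render(node.right)})"

        return render(tree) + ";"


def ward_cluster(m: ExpressionMatrix, distance: str = "euclidean") -> WardClustering:
    """Ward's-method agglomerative clustering of samples.

    ``distance="euclidean"`` is classical Ward; ``distance="pearson"`` uses
    1 − Pearson correlation as the dissimilarity (Ward's variance-minimizing
    update applied to a non-Euclidean dissimilarity, as is common practice).
    """
    x = m.to_numpy().T  # samples × genes
    if x.shape[0] < 1:
        raise ValueError("need at least one sample")
    if x.shape[0] == 1:
        return WardClustering(np.empty((0, 4)), m.samples, distance)
    if distance == "euclidean":
        d = pdist(x, metric="euclidean")
    elif distance == "pearson":
        sd = x.std(axis=1)
        if np.any(sd == 0):
            bad = m.samples[np.where(sd == 0)[0]].tolist()
            raise ValueError(f"constant sample(s) under pearson distance: {bad[:5]}")
        corr = np.corrcoef(x)
        d = squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
    else:
        raise ValueError(f"unknown distance: {distance!r}")
    link = hierarchy.linkage(d, method="ward")
    return WardClustering(link, m.samples, distance)
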