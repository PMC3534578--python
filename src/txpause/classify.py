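"""Clustering and classification of pause-kinetics feature vectors.

Feature vectors (z-transformed, see :mod:`txpause.features`) are grouped
by agglomerative hierarchical clustering with a Manhattan (city-block)
distance and McQuitty/WPGMA linkage, and classified with a random-forest
classifier whose misclassification error is estimated by averaging over
bootstrap resamples of the data set.  A matrix of p-values of pairwise
feature-correlation tests quantifies how complementary the features are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "Dendrogram",
    "ClassificationResult",
    "hierarchical_cluster",
    "cut_clusters",
    "rf_classify",
    "feature_correlation_pvalues",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree (scipy linkage matrix plus provenance)."""

    linkage: np.ndarray
    metric: str
    method: str
    n_items: int

    def to_newick(self, labels=None) -> str:
        """Export the merge tree in Newick format (heights as branch lengths)."""
        if labels is None:
            labels = [str(i) for i in range(self.n_items)]
        tree = hierarchy.to_tree(self.linkage)

        def build(node) -> str:
            if node.is_leaf():
                return labels[node.id]
            left, right = node.get_left(), node.get_right()
            ln = max(node.dist - left.dist, 0.0)
            rn = max(node.dist - right.dist, 0.0)
            return f"({build(left)}:{ln:.6g},{build(right)}:{rn:.6g})"

        return build(tree) + ";"


def hierarchical_cluster(vectors, metric: str = "cityblock",
                         method: str = "weighted") -> Dendrogram:
    """Cluster feature vectors; the default is Manhattan + McQuitty (WPGMA).

    McQuitty's update rule d(k, i u j) = (d(k,i) + d(k,j)) / 2 is scipy's
    ``weighted`` linkage.  Height inversions are possible under this rule;
    only tree validity is guaranteed.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return Dendrogram(linkage=Z, metric=metric, method=method, n_items=X.shape[0])


def cut_clusters(dendrogram: Dendrogram, n_clusters: int) -> np.ndarray:
    """Flat cluster labels obtained by cutting the tree into n_clusters."""
    return hierarchy.fcluster(dendrogram.linkage, t=n_clusters, criterion="maxclust")


@dataclass(frozen=True)
class ClassificationResult:
    mean_error: float
    sd_error: float
    n_trees: int
    n_bootstrap: int
    confusion: np.ndarray  # classes x classes, summed over bootstrap rounds
    classes: tuple
    n_redrawn: int = 0


def rf_classify(vectors, labels, n_trees: int = 5000, n_bootstrap: int = 100,
                seed: int | None = None, n_jobs: int = 1) -> ClassificationResult:
    """Random-forest misclassification error averaged over bootstrap data sets.

    For each bootstrap round the data set is resampled with replacement,
    a forest is trained on the resample and evaluated on the held-out
    (out-of-resample) items; the mean and SD of the per-round error are
    reported.  A resample missing a class (or leaving a class with no
    held-out item) is redrawn and counted.
    """
    X = np.asarray(vectors, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError("need at least 2 vectors per class")
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    errors = np.empty(n_bootstrap)
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    class_index = {c: i for i, c in enumerate(classes)}
    n_redrawn = 0
    for b in range(n_bootstrap):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if (np.unique(y[idx]).size == classes.size) and oob.size > 0:
                break
            n_redrawn += 1
        forest = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt",
            random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=n_jobs)
        forest.fit(X[idx], y[idx])
        pred = forest.predict(X[oob])
        errors[b] = float(np.mean(pred != y[oob]))
        for truth, guess in zip(y[oob], pred):
            confusion[class_index[truth], class_index[guess]] += 1
    return ClassificationResult(
        mean_error=float(errors.mean()),
        sd_error=float(errors.std(ddof=1)) if n_bootstrap > 1 else 0.0,
        n_trees=n_trees, n_bootstrap=n_bootstrap,
        confusion=confusion, classes=tuple(classes), n_redrawn=n_redrawn)


def feature_correlation_pvalues(vectors) -> np.ndarray:
    """Symmetric matrix of p-values of zero-correlation tests between features.

    Entry (j, k) is the two-sided p-value of the t-transform test on the
    Pearson coefficient between features j and k; the diagonal is NaN
    (self-correlation is not of interest), and rows/columns of constant
    features are NaN-flagged.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 vectors")
    V = X.shape[1]
    out = np.full((V, V), np.nan)
    sd = X.std(axis=0)
    for j in range(V):
        for k in range(j + 1, V):
            if sd[j] == 0 or sd[k] == 0:
                continue
            p = stats.pearsonr(X[:, j], X[:, k]).pvalue
            out[j, k] = out[k, j] = float(p)
    return out
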