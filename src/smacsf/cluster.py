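"""Unsupervised structure: protein z-scaling, Ward-D2 clustering with a
two-cluster cut, and sample-level PCA.

Ward-D2 here means the variance-minimizing Ward criterion applied to
Euclidean distances with the squared-distance Lance-Williams update and a
final square root (``hclust(..., method="ward.D2")`` semantics); SciPy's
``linkage(X, method="ward")`` on raw observation vectors implements exactly
this, and merge heights are on the original distance scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import IntensityMatrix

__all__ = ["zscore_proteins", "ClusterAssignment", "ward_cluster_cut2", "pca_scores"]


def zscore_proteins(matrix: IntensityMatrix) -> IntensityMatrix:
    """Scale each protein to mean 0, sd 1 (population sd, so a two-value
    protein maps to exactly {-1, +1}).  Constant proteins are dropped with a
    warning."""
    vals = matrix.values
    if (vals.notna().sum(axis=1) < 2).any():
        raise ValueError("every protein needs at least 2 observations to z-score")
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    flat = sd <= 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance proteins before clustering")
        vals, mean, sd = vals.loc[~flat], mean[~flat], sd[~flat]
    return IntensityMatrix(vals.sub(mean, axis=0).div(sd, axis=0))


@dataclass
class ClusterAssignment:
    """Two-cluster partition of proteins with its linkage record."""

    labels: pd.Series  # protein -> 1 or 2
    linkage_matrix: np.ndarray = field(repr=False)
    up_cluster: int | None = None  # label of the cluster rising at T302

    def cluster_ids(self, label: int) -> list[str]:
        return sorted(self.labels.index[self.labels == label])

    @property
    def up_ids(self) -> list[str]:
        if self.up_cluster is None:
            raise ValueError("no paired-difference information was supplied")
        return self.cluster_ids(self.up_cluster)

    @property
    def down_ids(self) -> list[str]:
        if self.up_cluster is None:
            raise ValueError("no paired-difference information was supplied")
        return self.cluster_ids(3 - self.up_cluster)


def ward_cluster_cut2(
    matrix: IntensityMatrix, mean_paired_diff: pd.Series | None = None
) -> ClusterAssignment:
    """Ward-D2 clustering of protein profiles (rows) cut into two clusters.

    Proteins are sorted by ID before linkage so the result is invariant to
    input row order.  When per-protein mean paired differences are given,
    the cluster with the higher mean difference is labeled "up".
    """
    vals = matrix.values.sort_index()
    if len(vals) < 2:
        raise ValueError("need at least 2 proteins to cluster")
    X = vals.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("clustering requires a complete matrix")
    if np.allclose(X, X[0]):
        raise ValueError("all protein profiles identical; no cluster structure")
    Z = linkage(X, method="ward")
    labels = pd.Series(fcluster(Z, t=2, criterion="maxclust"), index=vals.index)
    up = None
    if mean_paired_diff is not None:
        means = {
            lab: float(mean_paired_diff.reindex(labels.index[labels == lab]).mean())
            for lab in (1, 2)
        }
        up = 1 if means[1] >= means[2] else 2
    return ClusterAssignment(labels=labels, linkage_matrix=Z, up_cluster=up)


def pca_scores(
    matrix: IntensityMatrix, dims: int = 3, scale: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on protein features.

    Returns per-sample coordinates for the leading ``dims`` components and
    the explained-variance shares.  Features are mean-centered; ``scale``
    additionally z-scores them.  Any pair of dimensions can then be plotted
    (separations often live beyond the first two).
    """
    from sklearn.decomposition import PCA

    X = matrix.values.to_numpy(float).T
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix")
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    rank = min(n - 1, p)
    if dims > rank:
        raise ValueError(f"requested {dims} dimensions but rank is {rank}")
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=dims)
    scores = pca.fit_transform(X)
    frame = pd.DataFrame(
        scores, index=matrix.sample_ids, columns=[f"PC{i + 1}" for i in range(dims)]
    )
    return frame, pca.explained_variance_ratio_
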