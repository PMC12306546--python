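"""Relationship structure from structured-SCV eigenvectors.

For each eigenvalue greater than 1 of a structured SCV covariance, the
corresponding eigenvector is supported (nonzero) exactly on the datasets of
one correlated block.  Concatenating the d̂_r leading eigenvectors of every
structured SCV column-wise yields a K x Σ d̂_r feature matrix whose *rows*
profile how each dataset participates across all blocks of all SCVs.  Ward
hierarchical clustering of these rows produces the dendrogram — the
relationship structure — and flat grouping labels at any cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_mutual_info_score

from .eigcount import CovEstimate

__all__ = [
    "FeatureMatrix",
    "RelationshipStructure",
    "build_features",
    "cluster",
    "extract_labels",
    "ami",
    "recovery_metrics",
    "to_newick",
]


@dataclass
class FeatureMatrix:
    """Eigenvector features: K rows (datasets), one column per counted block.

    ``provenance[j] = (scv_index, eigenvector_rank)`` records where column j
    came from.
    """

    F: np.ndarray
    provenance: list[tuple[int, int]]

    @property
    def K(self) -> int:
        return self.F.shape[0]


@dataclass
class RelationshipStructure:
    """Ward merge tree over datasets plus flat labels at a chosen cut."""

    linkage: np.ndarray          # (K-1, 4) scipy linkage table
    labels: np.ndarray           # K integer grouping labels
    n_clusters: int
    ami: float | None = None


def _fix_column_signs(F: np.ndarray) -> np.ndarray:
    """Orient each eigenvector so its largest-magnitude entry is positive.

    Block eigenvectors of a nonnegative matrix are nonnegative up to a global
    sign; this restores the all-nonnegative orientation.
    """
    idx = np.argmax(np.abs(F), axis=0)
    signs = np.sign(F[idx, np.arange(F.shape[1])])
    signs[signs == 0] = 1.0
    return F * signs


def build_features(
    covs: list[CovEstimate],
    d_hats: list[int],
    scv_indices: list[int] | None = None,
) -> FeatureMatrix:
    """Concatenate the d̂_r leading eigenvectors of each structured SCV.

    Parameters
    ----------
    covs : list of CovEstimate
        Covariance estimates of the *structured* SCVs only.
    d_hats : list of int
        Estimated block counts, one per entry of ``covs`` (each >= 1).
    scv_indices : optional list of int
        Original SCV indices, recorded in the provenance (defaults to
        positions within ``covs``).
    """
    if len(covs) == 0:
        raise ValueError("no structured SCVs; relationship structure undefined")
    if len(d_hats) != len(covs):
        raise ValueError("d_hats must match covs in length")
    if any(d < 1 for d in d_hats):
        raise ValueError("each structured SCV must have d_hat >= 1")
    if scv_indices is None:
        scv_indices = list(range(len(covs)))

    cols = []
    provenance = []
    for r, (cov, d) in zip(scv_indices, zip(covs, d_hats)):
        cols.append(cov.eigenvectors[:, :d])
        provenance.extend((r, j) for j in range(d))
    F = _fix_column_signs(np.hstack(cols))
    return FeatureMatrix(F=F, provenance=provenance)


def cluster(
    features: FeatureMatrix | np.ndarray,
    linkage_method: str = "ward",
    n_clusters: int | None = None,
    labels_true: np.ndarray | None = None,
) -> RelationshipStructure:
    """Agglomerative clustering of datasets on their eigenvector features.

    Euclidean distance between feature rows with Ward linkage (default).
    If ``n_clusters`` is omitted the cut maximising the merge-height gap is
    used.  When ground-truth labels are supplied the AMI of the flat labels
    is attached.
    """
    F = features.F if isinstance(features, FeatureMatrix) else np.asarray(features)
    if F.shape[0] < 2:
        raise ValueError("need at least 2 datasets to cluster")
    if not np.all(np.isfinite(F)):
        raise ValueError("feature matrix contains non-finite values")
    Z = hierarchy.linkage(F, method=linkage_method, metric="euclidean")
    rs = RelationshipStructure(linkage=Z, labels=np.empty(0, dtype=int), n_clusters=0)
    rs.labels = extract_labels(rs, n_clusters)
    rs.n_clusters = int(len(np.unique(rs.labels)))
    if labels_true is not None:
        rs.ami = ami(labels_true, rs.labels)
    return rs


def extract_labels(
    rs: RelationshipStructure, n_clusters: int | None = None
) -> np.ndarray:
    """Flat grouping labels from the merge tree.

    With ``n_clusters`` given, cut the tree to that many clusters.  Without
    it, cut at the largest gap between consecutive merge heights (a
    convenience heuristic — the tree itself is the primary output).
    """
    Z = rs.linkage
    K = Z.shape[0] + 1
    if n_clusters is None:
        heights = Z[:, 2]
        if K == 2:
            n_clusters = 2
        else:
            gaps = np.diff(heights)
            # cutting just below merge i+1 leaves K-1-i clusters
            n_clusters = int(K - 1 - np.argmax(gaps))
    if not 1 <= n_clusters <= K:
        raise ValueError(f"n_clusters must lie in 1..{K}")
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")


def ami(labels_true, labels_est) -> float:
    """Adjusted mutual information ("max" normalisation).

    1 for identical clusterings (up to relabelling), ~0 for independent
    ones; chance-corrected by the expected mutual information of random
    labelings with the same cluster sizes.
    """
    labels_true = np.asarray(labels_true)
    labels_est = np.asarray(labels_est)
    if labels_true.shape != labels_est.shape:
        raise ValueError("label vectors must have equal length")
    return float(
        adjusted_mutual_info_score(labels_true, labels_est, average_method="max")
    )


def recovery_metrics(
    d_hat_runs: np.ndarray, d_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo summary of block-count estimation per SCV.

    Parameters
    ----------
    d_hat_runs : (n_runs, R) array
        Estimated d̂ for each run and SCV.
    d_true : (R,) array
        Ground-truth block counts.

    Returns
    -------
    (P, mu) : pair of (R,) arrays
        P[r] — fraction of runs with d̂_r = d_r; mu[r] — mean d̂_r.
    """
    d_hat_runs = np.atleast_2d(np.asarray(d_hat_runs))
    d_true = np.asarray(d_true)
    if d_hat_runs.shape[1] != d_true.shape[0]:
        raise ValueError("d_hat_runs columns must match d_true length")
    P = (d_hat_runs == d_true[None, :]).mean(axis=0)
    mu = d_hat_runs.mean(axis=0)
    return P, mu


def to_newick(rs: RelationshipStructure, names: list[str] | None = None) -> str:
    """Export the merge tree as a Newick string with heights as branch lengths."""
    tree = hierarchy.to_tree(rs.linkage)
    K = rs.linkage.shape[0] + 1
    if names is None:
        names = [f"d{k + 1}" for k in range(K)]

    def _walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = _walk(node.left, node.dist)
        right = _walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return _walk(tree, tree.dist) + ";"
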