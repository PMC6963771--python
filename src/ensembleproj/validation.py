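"""Cluster detection in 2-D embeddings, cross-method validation, and
chi-square confidence ellipses.

The validation rule: clusters are credible only when the PCA embedding and
the random-projection embedding exhibit the same partition (chance-corrected
agreement above threshold AND equal cluster counts). A partition seen by PCA
alone is flagged as unvalidated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import chi2
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

__all__ = [
    "ClusterAssignment",
    "ClusterReport",
    "EllipseSpec",
    "detect_clusters",
    "cluster_agreement",
    "best_replicate_report",
    "confidence_ellipse",
    "flag_outliers",
]

OUTLIER = -1


@dataclass
class ClusterAssignment:
    """Labels in {0..m-1} plus -1 for outliers, with detector provenance."""

    labels: np.ndarray
    method: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = sorted(set(self.labels) - {OUTLIER})
        if uniq != list(range(len(uniq))):
            raise ValueError(f"labels must be contiguous 0..m-1 (plus -1); got {uniq}")

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels) - {OUTLIER})

    @property
    def n_outliers(self) -> int:
        return int(np.sum(self.labels == OUTLIER))


@dataclass
class ClusterReport:
    assignment_pca: ClusterAssignment
    assignment_random: ClusterAssignment
    agreement: float
    verdict: str  # "validated" | "unvalidated"
    threshold: float = 0.9


@dataclass
class EllipseSpec:
    """Chi-square confidence ellipse of a 2-D point cloud."""

    center: np.ndarray
    semi_axes: np.ndarray  # descending
    angle: float  # radians, in (-pi/2, pi/2]
    level: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points on or inside the ellipse."""
        pts = np.atleast_2d(points) - self.center
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = np.array([[c, s], [-s, c]])  # world -> ellipse frame
        local = pts @ rot.T
        return (local[:, 0] / self.semi_axes[0]) ** 2 + (
            local[:, 1] / self.semi_axes[1]
        ) ** 2 <= 1.0 + 1e-12


# --- detectors --------------------------------------------------------------


def _density_labels(points: np.ndarray, radius_factor: float, min_cluster_size: int):
    n = len(points)
    tree = cKDTree(points)
    nn_dist, _ = tree.query(points, k=2)
    radius = radius_factor * float(np.median(nn_dist[:, 1]))
    pairs = tree.query_pairs(radius, output_type="ndarray")
    labels = np.full(n, OUTLIER, dtype=int)
    if len(pairs) == 0:
        return labels, radius
    graph = csr_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, comp = connected_components(graph, directed=False)
    next_label = 0
    for comp_id in np.unique(comp):
        mask = comp == comp_id
        if mask.sum() >= min_cluster_size:
            labels[mask] = next_label
            next_label += 1
    return labels, radius


def _kmeans_labels(points: np.ndarray, max_k: int, silhouette_min: float, force_k):
    if force_k is not None:
        if force_k == 1:
            return np.zeros(len(points), dtype=int), None
        km = KMeans(n_clusters=force_k, n_init=10, random_state=0)
        return km.fit_predict(points), None
    best_score, best_labels = -np.inf, None
    for k in range(2, min(max_k, len(points) - 1) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=0)
        labels = km.fit_predict(points)
        score = silhouette_score(points, labels)
        if score > best_score:
            best_score, best_labels = score, labels
    if best_labels is None or best_score < silhouette_min:
        return np.zeros(len(points), dtype=int), best_score
    return best_labels, best_score


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Renumber clusters by order of first appearance; keep -1."""
    out = np.full_like(labels, OUTLIER)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab == OUTLIER:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def detect_clusters(
    scores: np.ndarray,
    method: str = "kmeans_silhouette",
    radius_factor: float = 3.0,
    min_cluster_size: int = 3,
    max_k: int = 5,
    silhouette_min: float = 0.5,
    force_k: int | None = None,
) -> ClusterAssignment:
    """Cluster a 2-D embedding.

    ``density``: connected components of the fixed-radius neighbor graph with
    radius = ``radius_factor`` × median nearest-neighbor distance; components
    smaller than ``min_cluster_size`` become outliers (-1). Three mutually
    distant points therefore form a single cluster when ``min_cluster_size``
    is 3 (they are each other's nearest neighbors), and are all outliers for
    larger minimum sizes.

    ``kmeans_silhouette``: best k in 2..``max_k`` by mean silhouette; a single
    cluster is declared when the best silhouette is below ``silhouette_min``.
    ``force_k`` bypasses model selection (used to probe over-splitting).
    """
    points = np.asarray(scores, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("scores must be N x 2")
    if len(points) < max(3, min_cluster_size):
        raise ValueError("fewer points than the minimum cluster size")

    if method == "density":
        labels, radius = _density_labels(points, radius_factor, min_cluster_size)
        params = {
            "radius_factor": radius_factor,
            "min_cluster_size": min_cluster_size,
            "radius": radius,
        }
    elif method == "kmeans_silhouette":
        labels, sil = _kmeans_labels(points, max_k, silhouette_min, force_k)
        params = {
            "max_k": max_k,
            "silhouette_min": silhouette_min,
            "force_k": force_k,
            "best_silhouette": sil,
        }
    else:
        raise ValueError(f"unknown method {method!r}")
    return ClusterAssignment(_relabel_contiguous(labels), method, params)


# --- agreement and verdict --------------------------------------------------


def cluster_agreement(
    a: ClusterAssignment, b: ClusterAssignment, threshold: float = 0.9
) -> ClusterReport:
    """Adjusted Rand index over points that are non-outlier in both
    assignments; verdict is ``validated`` only when the index reaches the
    threshold AND both methods report the same number of clusters."""
    if len(a.labels) != len(b.labels):
        raise ValueError("assignments cover different numbers of points")
    mask = (a.labels != OUTLIER) & (b.labels != OUTLIER)
    if mask.sum() == 0:
        agreement = 0.0
    else:
        agreement = float(adjusted_rand_score(a.labels[mask], b.labels[mask]))
    validated = agreement >= threshold and a.n_clusters == b.n_clusters
    return ClusterReport(
        assignment_pca=a,
        assignment_random=b,
        agreement=agreement,
        verdict="validated" if validated else "unvalidated",
        threshold=threshold,
    )


def best_replicate_report(
    assignment_pca: ClusterAssignment,
    random_assignments: Sequence[ClusterAssignment],
    threshold: float = 0.9,
) -> ClusterReport:
    """Verdict over several random-projection replicates.

    A random 2-frame can by chance lie nearly orthogonal to a real separation
    direction, so a single draw failing to show a cluster split is weak
    evidence of absence. Clusters are accepted when at least one replicate
    reproduces the PCA partition; the report returned is the best-agreeing
    replicate's.
    """
    if not random_assignments:
        raise ValueError("need at least one random-projection assignment")
    reports = [
        cluster_agreement(assignment_pca, rnd, threshold) for rnd in random_assignments
    ]
    for rep in reports:
        if rep.verdict == "validated":
            return rep
    return max(reports, key=lambda r: r.agreement)


# --- confidence ellipses and outliers ---------------------------------------


def _cloud_stats(points: np.ndarray):
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 points in 2-D")
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    if np.linalg.det(cov) <= 1e-300:
        raise ValueError("singular covariance (collinear points)")
    return pts, center, cov


def confidence_ellipse(points: np.ndarray, level: float) -> EllipseSpec:
    """Gaussian confidence ellipse: semi-axis i = sqrt(λ_i · q) with λ_i the
    sample-covariance eigenvalues and q the chi-square(2 df) quantile at
    ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    pts, center, cov = _cloud_stats(points)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = chi2.ppf(level, df=2)
    lead = eigvecs[:, 0]
    angle = np.arctan2(lead[1], lead[0])
    if angle <= -np.pi / 2:
        angle += np.pi
    elif angle > np.pi / 2:
        angle -= np.pi
    return EllipseSpec(
        center=center,
        semi_axes=np.sqrt(eigvals * q),
        angle=float(angle),
        level=level,
    )


def flag_outliers(scores: np.ndarray, level: float = 0.99) -> np.ndarray:
    """Flag points whose squared Mahalanobis distance from the cloud exceeds
    the chi-square(2 df) quantile at ``level``."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    pts, center, cov = _cloud_stats(scores)
    inv = np.linalg.inv(cov)
    diff = pts - center
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return d2 > chi2.ppf(level, df=2)
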