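"""Representation analyses for the cortical memory system.

Developing "cortical representations" are the settled activation patterns of
the cortical hidden layer.  Label-induced warping is quantified on those
patterns: prototypes of the 26 basic categories are pushed through the
network, and their hidden vectors are scored for separation by global
category (silhouette and a between/within distance ratio) in the full hidden
space.  A 2-D PCA projection is provided for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .network import DualMemoryModel, forward_settle
from .stimuli import StimulusSet


def extract_cortical_hidden(model: DualMemoryModel,
                            features: np.ndarray) -> np.ndarray:
    """Settled cortical hidden activations for one input (read-only)."""
    return forward_settle(model, features).h_cor


def prototype_representations(
    model: DualMemoryModel, sset: StimulusSet
) -> tuple[list[str], list[str], np.ndarray]:
    """Cortical hidden vectors of every basic-category prototype.

    Returns (basic categories, their global categories, hidden matrix),
    in the stimulus set's category order.
    """
    cats = list(sset.taxonomy)
    H = np.stack([extract_cortical_hidden(model, sset.prototypes[c]) for c in cats])
    return cats, [sset.taxonomy[c] for c in cats], H


def pca_project(vectors: np.ndarray, n_components: int = 2
                ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA projection with a fixed sign convention.

    Each component's sign is chosen so its largest-magnitude loading is
    positive, making projections reproducible across runs.  Returns the
    projected coordinates and the explained-variance ratios.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors to project")
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds vector dimension")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    comps = pca.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            coords[:, k] *= -1.0
    return coords, pca.explained_variance_ratio_


@dataclass
class SeparationMetrics:
    silhouette: float
    between_within_ratio: float
    degenerate: bool = False


def cluster_separation(vectors: np.ndarray, group_labels) -> SeparationMetrics:
    """Quantify how well points separate by group in the full space.

    ``silhouette`` is the mean silhouette coefficient (Euclidean); singleton
    groups contribute 0.  ``between_within_ratio`` is the mean pairwise
    distance between group centroids divided by the mean distance of points
    to their own centroid.  All-coincident points are a degenerate geometry:
    flagged, with silhouette 0 and ratio NaN.
    """
    X = np.asarray(vectors, dtype=float)
    labels = np.asarray(group_labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("vectors and group_labels length mismatch")
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least 2 groups")

    if X.shape[0] > 1 and np.max(pdist(X)) == 0.0:
        return SeparationMetrics(0.0, float("nan"), degenerate=True)

    sil = float(silhouette_score(X, labels, metric="euclidean"))

    centroids = np.stack([X[labels == g].mean(axis=0) for g in groups])
    between = float(np.mean(pdist(centroids)))
    within_dists = np.concatenate([
        np.linalg.norm(X[labels == g] - centroids[i], axis=1)
        for i, g in enumerate(groups)
    ])
    within = float(np.mean(within_dists))
    if within == 0.0:
        return SeparationMetrics(sil, float("inf"))
    return SeparationMetrics(sil, between / within)
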