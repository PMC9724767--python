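"""Classical multidimensional scaling and cluster-separation metrics.

Samples are embedded from their pairwise Euclidean distances over a probe
set via Torgerson double-centering (principal coordinates analysis):
``B = -1/2 J D^2 J`` with ``J = I - 11'/n``; coordinates are the top-k
eigenvectors of B scaled by the square root of their eigenvalues.  On
Euclidean-realizable input the embedding reproduces the distances exactly
at full rank.  The procedure is deterministic; signs are fixed so the
largest-magnitude entry of each coordinate column is positive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_samples


def euclidean_distances(beta_subset: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between samples (columns).

    Input is a probes x samples matrix restricted to the probe set of
    interest; missing values must be imputed first.
    """
    values = beta_subset.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing values; impute before MDS")
    d = squareform(pdist(values.T, metric="euclidean"))
    return pd.DataFrame(d, index=beta_subset.columns, columns=beta_subset.columns)


def classical_mds(distances: pd.DataFrame | np.ndarray, k: int = 2):
    """Torgerson/principal-coordinates embedding of a distance matrix.

    Returns ``(coordinates, eigenvalues)``: an n x k array (rows in input
    sample order) and ALL eigenvalues of the centered Gram matrix in
    descending order (negative ones signal non-Euclidean input).  Raises
    if fewer than k positive eigenvalues exist.
    """
    if isinstance(distances, pd.DataFrame):
        labels = distances.index
        d = distances.to_numpy(dtype=float)
    else:
        labels = None
        d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")

    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(1e-10, 1e-10 * abs(eigvals[0]) if n else 0.0)
    n_positive = int(np.sum(eigvals > tol))
    if k > n_positive:
        raise ValueError(
            f"requested k={k} but only {n_positive} positive eigenvalues; "
            f"maximum usable k is {n_positive}"
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    # sign convention: largest-magnitude entry of each column is positive
    for col in range(k):
        extreme = np.argmax(np.abs(coords[:, col]))
        if coords[extreme, col] < 0:
            coords[:, col] = -coords[:, col]
    if labels is not None:
        coords = pd.DataFrame(
            coords, index=labels, columns=[f"dim{i + 1}" for i in range(k)]
        )
    return coords, eigvals


class ClassicalMDS(BaseEstimator):
    """scikit-learn-style wrapper around classical (Torgerson) MDS.

    ``fit_transform(X)`` takes samples x features input, computes pairwise
    Euclidean distances and embeds into ``n_components`` dimensions.

    Attributes
    ----------
    embedding_ : ndarray or DataFrame, samples x n_components
    eigenvalues_ : all Gram eigenvalues, descending
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            dist = euclidean_distances(X.T)
        else:
            arr = np.asarray(X, dtype=float)
            dist = squareform(pdist(arr, metric="euclidean"))
        coords, eigvals = classical_mds(dist, self.n_components)
        self.embedding_ = coords
        self.eigenvalues_ = eigvals
        return coords


def separation_metrics(coordinates, labels) -> dict:
    """Cluster-separation summary of an embedding.

    Returns per-sample silhouette values, per-group and overall means,
    and a centroid-distance / within-spread ratio.  Groups with a single
    sample have undefined silhouette and are flagged, not scored.
    """
    if isinstance(coordinates, pd.DataFrame):
        sample_ids = list(coordinates.index.astype(str))
        coords = coordinates.to_numpy(dtype=float)
    else:
        coords = np.asarray(coordinates, dtype=float)
        sample_ids = [str(i) for i in range(len(coords))]
    labels = np.asarray(labels)
    if len(labels) != len(coords):
        raise ValueError("labels length must match number of samples")

    unique, counts = np.unique(labels, return_counts=True)
    flags = [f"group {g!r} has a single sample; silhouette undefined"
             for g, c in zip(unique, counts) if c < 2]
    if len(unique) < 2:
        return {"error": "need at least 2 groups for separation metrics",
                "flags": flags}

    scorable = np.isin(labels, unique[counts >= 2])
    result: dict = {"flags": flags}
    if len(np.unique(labels[scorable])) >= 2:
        sil = silhouette_samples(coords[scorable], labels[scorable])
        per_sample = dict(zip(np.asarray(sample_ids)[scorable], sil.round(6)))
        result["silhouette_per_sample"] = {k: float(v) for k, v in per_sample.items()}
        result["silhouette_mean"] = float(np.mean(sil))
        result["silhouette_by_group"] = {
            str(g): float(np.mean(sil[labels[scorable] == g]))
            for g in np.unique(labels[scorable])
        }
    # centroid separation vs within-group spread
    centroids = {g: coords[labels == g].mean(axis=0) for g in unique}
    spreads = [
        float(np.mean(np.linalg.norm(coords[labels == g] - centroids[g], axis=1)))
        for g in unique if (labels == g).sum() >= 2
    ]
    centroid_dists = [
        float(np.linalg.norm(centroids[a] - centroids[b]))
        for i, a in enumerate(unique) for b in unique[i + 1:]
    ]
    within = float(np.mean(spreads)) if spreads else float("nan")
    between = float(np.mean(centroid_dists))
    result["centroid_distance_mean"] = between
    result["within_spread_mean"] = within
    result["separation_ratio"] = between / within if within > 0 else float("inf")
    return result
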