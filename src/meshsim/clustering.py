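"""Clustering of document similarity matrices and NMI evaluation.

Three algorithms operate on the (symmetric, unit-diagonal) document
similarity matrix:

* spectral  — the matrix is used directly as a precomputed graph
  affinity (documents are vertices, similarities edge weights);
* agglomerative — average linkage on the derived distance matrix;
* kmeans    — each document embedded as its row of similarities.

Cluster quality against known labels is scored with normalized mutual
information using the sqrt normalisation

    NMI = sum_{h,l} n_hl log(n n_hl / (n_h n_l))
          / sqrt( [sum_h n_h log(n_h / n)] [sum_l n_l log(n_l / n)] )

where both bracketed sums are non-positive, so their product is
non-negative under the radical.  NMI lies in [0, 1] and is invariant to
label permutation and to the log base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering

from .aggregation import DocSimMatrix

ALGORITHMS = ("spectral", "agglomerative", "kmeans")


class ClusteringError(ValueError):
    """Raised for invalid clustering inputs."""


@dataclass
class ClusterLabels:
    """Integer cluster assignment aligned with a matrix's document order."""

    doc_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.doc_ids),):
            raise ClusteringError("labels must align with doc_ids")

    def as_dict(self) -> dict[str, int]:
        return {doc_id: int(lab) for doc_id, lab in zip(self.doc_ids, self.labels)}


def similarity_to_distance(sim: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Convert a similarity matrix to a dissimilarity matrix.

    Similarities above 1 (Resnik) are first rescaled by the matrix
    maximum; distances are ``max(0, 1 - sim)`` with an exactly zero
    diagonal and exact symmetry.
    """
    sim = np.asarray(sim, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ClusteringError(f"expected a square matrix, got shape {sim.shape}")
    if not np.isfinite(sim).all():
        raise ClusteringError("similarity matrix contains non-finite values")
    if not np.allclose(sim, sim.T, atol=atol):
        raise ClusteringError("similarity matrix is not symmetric")
    scaled = sim / sim.max() if sim.max() > 1.0 else sim
    dist = np.clip(1.0 - scaled, 0.0, None)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster(
    matrix: DocSimMatrix,
    algorithm: str,
    k: int,
    seed: int = 0,
) -> ClusterLabels:
    """Cluster a document similarity matrix into ``k`` groups.

    Deterministic at a fixed seed (spectral and k-means are stochastic;
    agglomerative ignores the seed).
    """
    if algorithm not in ALGORITHMS:
        raise ClusteringError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    n = matrix.n
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} must satisfy 1 <= k <= n={n}")
    sim = np.asarray(matrix.values, dtype=float)
    if algorithm == "spectral":
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            model = SpectralClustering(
                n_clusters=k, affinity="precomputed", random_state=seed, n_init=10
            )
            labels = model.fit_predict(sim)
    elif algorithm == "agglomerative":
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage="average")
        labels = model.fit_predict(similarity_to_distance(sim))
    else:  # kmeans on rows of the similarity matrix
        model = KMeans(n_clusters=k, random_state=seed, n_init=10)
        labels = model.fit_predict(sim)
    return ClusterLabels(doc_ids=list(matrix.doc_ids), labels=labels, k=k)


def nmi(true_labels: Sequence, pred_labels: Sequence) -> float:
    """Sqrt-normalised mutual information between two labelings.

    Zero-count cells contribute 0.  Term arrays are summed in sorted
    order, so the result is exactly invariant under label permutation.
    Returns ``nan`` when both labelings are single-class (the
    normalisation is undefined there).
    """
    a = np.asarray(true_labels)
    b = np.asarray(pred_labels)
    if a.ndim != 1 or a.shape != b.shape:
        raise ClusteringError("labelings must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ClusteringError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=float)
    np.add.at(contingency, (ai, bi), 1.0)
    n_h = contingency.sum(axis=1)
    n_l = contingency.sum(axis=0)

    nz_h, nz_l = np.nonzero(contingency)
    cells = contingency[nz_h, nz_l]
    num_terms = cells * np.log(n * cells / (n_h[nz_h] * n_l[nz_l]))
    numerator = float(np.sort(num_terms).sum())
    dh = float(np.sort(n_h * np.log(n_h / n)).sum())
    dl = float(np.sort(n_l * np.log(n_l / n)).sum())
    denominator = math.sqrt(dh * dl)
    if denominator == 0.0:
        return math.nan
    return numerator / denominator
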