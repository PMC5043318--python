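"""Phrase-type classification from onset point processes.

Phrases are compared as Gaussian-smoothed onset trains: the similarity of two
trains is the cosine of their smoothed versions, which for onset time sets
``a`` and ``b`` has the closed form

    K(a, b) = sum_ij exp(-(a_i - b_j)^2 / (4 sigma^2)),
    sim(a, b) = K(a, b) / sqrt(K(a, a) K(b, b)),

evaluated analytically (no binning error).  Trains are compared after
first-onset alignment, which the point-process representation already
guarantees; differing durations need no explicit padding in the analytic
form.  A similarity graph thresholded at the matrix median is then clustered
by modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frontend import PointProcessPhrase

__all__ = [
    "SimilarityMatrix",
    "ClusterAssignment",
    "spike_train_similarity",
    "build_similarity_matrix",
    "cluster_phrases",
]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise phrase similarity in [0, 1] with unit diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.abs(np.diag(v) - 1) > 1e-12):
            raise ValueError("diagonal must be 1")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusterAssignment:
    """Per-phrase cluster ids (contiguous from 1) and partition modularity."""

    labels: np.ndarray
    modularity: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(lab)
        if len(lab) and (uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, len(uniq) + 1))):
            raise ValueError("cluster ids must be contiguous from 1")
        object.__setattr__(self, "labels", lab)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max(initial=0))


def _onset_array(train) -> np.ndarray:
    if isinstance(train, PointProcessPhrase):
        return np.asarray(train.onset_times, dtype=float)
    return np.asarray(train, dtype=float)


def spike_train_similarity(a, b, sigma: float = 0.01) -> float:
    """Cosine similarity of two Gaussian-smoothed onset trains.

    ``a`` and ``b`` are :class:`PointProcessPhrase` objects or arrays of
    onset times (seconds), assumed first-onset aligned; ``sigma`` is the
    kernel s.d. in seconds.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ta, tb = _onset_array(a), _onset_array(b)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both trains must be non-empty")

    def inner(x: np.ndarray, y: np.ndarray) -> float:
        d = x[:, None] - y[None, :]
        return float(np.exp(-(d * d) / (4.0 * sigma * sigma)).sum())

    sim = inner(ta, tb) / np.sqrt(inner(ta, ta) * inner(tb, tb))
    return float(min(max(sim, 0.0), 1.0))


def build_similarity_matrix(
    phrases: Sequence, sigma: float = 0.01
) -> SimilarityMatrix:
    """All-pairs spike-train similarity."""
    if len(phrases) < 2:
        raise ValueError("need at least 2 phrases")
    n = len(phrases)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = spike_train_similarity(phrases[i], phrases[j], sigma=sigma)
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values=values)


def _otsu_threshold(values: np.ndarray) -> float:
    """Threshold maximizing between-class variance of a 1-D sample.

    Falls back to the median when the sample is (nearly) constant, so a
    degenerate all-equal similarity matrix keeps all its edges.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2 or v[-1] - v[0] < 1e-12:
        return float(np.median(v))
    cum = np.cumsum(v)
    best_var, thr = -1.0, float(v[0])
    for i in range(1, n):
        w0 = i / n
        m0 = cum[i - 1] / i
        m1 = (cum[-1] - cum[i - 1]) / (n - i)
        var = w0 * (1 - w0) * (m0 - m1) ** 2
        if var > best_var:
            best_var, thr = var, float(v[i - 1] + v[i]) / 2.0
    return thr


def _modularity_partition(
    W: np.ndarray, seed: int
) -> tuple[np.ndarray, float]:
    import igraph as ig
    import leidenalg

    n = W.shape[0]
    ii, jj = np.nonzero(np.triu(W, k=1))
    if len(ii) == 0:
        return np.arange(n, dtype=np.int64), 0.0
    weights = W[ii, jj].tolist()
    g = ig.Graph(n=n, edges=list(zip(ii.tolist(), jj.tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.ModularityVertexPartition, weights=weights, seed=seed
    )
    membership = np.asarray(part.membership, dtype=np.int64)
    q = g.modularity(membership.tolist(), weights=weights)
    return membership, float(q)


def cluster_phrases(
    S: SimilarityMatrix,
    seed: int = 0,
    threshold: float | None = None,
    refine: bool = False,
) -> ClusterAssignment:
    """Partition phrases by modularity maximization on the thresholded graph.

    Similarities below ``threshold`` are zeroed; the remaining weighted graph
    is clustered.  The default adaptive threshold is an Otsu split of the
    off-diagonal similarities (within-type and between-type similarities are
    typically bimodal; a plain median leaves too many cross-type edges).
    Cluster ids are renumbered in order of first appearance, so the
    assignment is stable under input reordering up to label renaming.
    ``refine`` runs a second clustering pass within each cluster.
    """
    W = S.values.copy()
    n = S.size
    off = W[~np.eye(n, dtype=bool)]
    thr = _otsu_threshold(off) if threshold is None else float(threshold)
    W[W < thr] = 0.0
    np.fill_diagonal(W, 0.0)

    membership, q = _modularity_partition(W, seed)

    if refine:
        refined = membership.copy()
        next_id = 0
        for c in np.unique(membership):
            members = np.flatnonzero(membership == c)
            if len(members) > 2:
                sub = W[np.ix_(members, members)]
                sub_m, _ = _modularity_partition(sub, seed)
            else:
                sub_m = np.zeros(len(members), dtype=np.int64)
            for s in np.unique(sub_m):
                refined[members[sub_m == s]] = next_id
                next_id += 1
        membership = refined

    # renumber in order of first appearance, 1-based
    relabel: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i, c in enumerate(membership):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels[i] = relabel[int(c)]
    return ClusterAssignment(labels=labels, modularity=q)
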