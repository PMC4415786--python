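"""Hybrid clinical/transcriptomic distances and the nearest-neighbor
predictor.

The distance between two samples combines a Euclidean distance on their
binary clinical attribute vectors and a Pearson correlation distance
(1 - r) on their expression vectors over the signature genes:

    dist(x1, x2) = rho * dist_E(phi(x1), phi(x2))
                 + (1 - rho) * dist_P(omega(x1), omega(x2))

with rho in [0, 1]: rho = 1 uses clinical attributes only, rho = 0
expression only. The two components are combined raw and unscaled.
Because clinical vectors are binary, clinical-only distances take few
values and ties are common; the neighbor set of a k-nearest-neighbor
query therefore includes every reference tied with the k-th distance, and
the expression component acts as a tie-breaker for rho just below 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HybridSample",
    "NeighborResult",
    "pearson_distance",
    "hybrid_distance",
    "knn_predict",
    "pearson_distance_matrix",
    "euclidean_distance_matrix",
    "hybrid_distance_matrix",
    "vote_from_distances",
]


@dataclass
class HybridSample:
    """One sample's view for classification: expression over the signature
    genes (omega), binary clinical attributes coded {0,1} (phi), and an
    optional diagnosis label."""

    sample_id: str
    expression: np.ndarray | None = None
    clinical: np.ndarray | None = None
    label: str | None = None
    activity: float | None = None
    criteria_flag: bool | None = None

    def __post_init__(self) -> None:
        if self.expression is not None:
            self.expression = np.asarray(self.expression, dtype=float)
        if self.clinical is not None:
            self.clinical = np.asarray(self.clinical, dtype=float)
            if self.clinical.size and not np.isin(self.clinical, [0.0, 1.0]).all():
                raise ValueError("clinical attributes must be coded {0, 1}")


@dataclass
class NeighborResult:
    """Outcome of one nearest-neighbor query: neighbors ordered by
    (distance, reference id), a flag per neighbor marking those included
    only through a tie with the k-th distance, vote counts per class and
    the predicted label."""

    query_id: str
    neighbor_ids: list[str]
    distances: list[float]
    included_by_tie: list[bool]
    predicted_label: str
    vote_counts: dict[str, int]


def pearson_distance(u, v) -> float:
    """Pearson correlation distance 1 - r, in [0, 2].

    Undefined (an error) when either vector is constant.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1 or len(u) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu = float(np.sqrt(uc @ uc))
    nv = float(np.sqrt(vc @ vc))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("Pearson distance undefined for a constant vector")
    r = float(np.clip((uc @ vc) / (nu * nv), -1.0, 1.0))
    return 1.0 - r


def _euclidean(u, v) -> float:
    d = np.asarray(u, dtype=float) - np.asarray(v, dtype=float)
    return float(np.sqrt(d @ d))


def hybrid_distance(x1: HybridSample, x2: HybridSample, rho: float) -> float:
    """rho-weighted combination of the clinical Euclidean distance and the
    expression Pearson distance (see module docstring)."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if rho == 0.0:
        return pearson_distance(x1.expression, x2.expression)
    if rho == 1.0:
        if x1.clinical is None or x2.clinical is None:
            raise ValueError("clinical attributes required at rho = 1")
        return _euclidean(x1.clinical, x2.clinical)
    if x1.clinical is None or x2.clinical is None:
        raise ValueError("clinical attributes required for 0 < rho < 1")
    if x1.expression is None or x2.expression is None:
        raise ValueError("expression required for 0 < rho < 1")
    return rho * _euclidean(x1.clinical, x2.clinical) + (1.0 - rho) * pearson_distance(
        x1.expression, x2.expression
    )


def pearson_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson distances between the rows of A and the rows of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    nA = np.sqrt((Ac**2).sum(axis=1, keepdims=True))
    nB = np.sqrt((Bc**2).sum(axis=1, keepdims=True))
    if (nA == 0).any() or (nB == 0).any():
        raise ValueError("Pearson distance undefined for a constant vector")
    r = np.clip((Ac / nA) @ (Bc / nB).T, -1.0, 1.0)
    return 1.0 - r


def euclidean_distance_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    d2 = (A**2).sum(axis=1)[:, None] + (B**2).sum(axis=1)[None, :] - 2.0 * A @ B.T
    return np.sqrt(np.clip(d2, 0.0, None))


def hybrid_distance_matrix(
    query_expr: np.ndarray | None,
    query_clin: np.ndarray | None,
    ref_expr: np.ndarray | None,
    ref_clin: np.ndarray | None,
    rho: float,
) -> np.ndarray:
    """Queries x references matrix of hybrid distances. The rho = 0 and
    rho = 1 endpoints use a single component, bit-identical to the pure
    Pearson / Euclidean computations."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if rho == 0.0:
        return pearson_distance_matrix(query_expr, ref_expr)
    if rho == 1.0:
        return euclidean_distance_matrix(query_clin, ref_clin)
    return rho * euclidean_distance_matrix(query_clin, ref_clin) + (
        1.0 - rho
    ) * pearson_distance_matrix(query_expr, ref_expr)


def vote_from_distances(
    distances: np.ndarray,
    ref_labels: np.ndarray,
    ref_ids: np.ndarray,
    n_neighbors: int,
) -> tuple[str, np.ndarray, float]:
    """Tie-inclusive k-nearest-neighbor vote on one query's distance row.

    Returns (predicted label, indices of the neighbor set ordered by
    (distance, reference id), k-th distance). The neighbor set is the
    ``n_neighbors`` closest references plus every reference exactly tied
    with the ``n_neighbors``-th distance. The majority class wins; vote
    ties are resolved by the smallest mean distance among tied classes,
    then lexicographic class name.
    """
    n_ref = len(distances)
    k = min(n_neighbors, n_ref)
    order = np.lexsort((ref_ids, distances))
    kth = distances[order[k - 1]]
    in_set = order[distances[order] <= kth]
    labels_in = ref_labels[in_set]
    dists_in = distances[in_set]
    classes, counts = np.unique(labels_in, return_counts=True)
    top = counts.max()
    tied = [c for c, n in zip(classes, counts) if n == top]
    if len(tied) == 1:
        winner = tied[0]
    else:
        winner = min(tied, key=lambda c: (float(dists_in[labels_in == c].mean()), c))
    return str(winner), in_set, float(kth)


def knn_predict(
    query: HybridSample,
    references: list[HybridSample],
    n_neighbors: int = 5,
    rho: float = 0.5,
) -> NeighborResult:
    """Predict the query's label by tie-inclusive nearest-neighbor vote.

    References sharing the query's sample id are excluded. References with
    missing expression are excluded (with a warning) whenever the expression
    component is in use. If fewer references than ``n_neighbors`` remain,
    all of them are used, with a warning.
    """
    refs = [r for r in references if r.sample_id != query.sample_id]
    if any(r.label is None for r in refs):
        raise ValueError("all references must be labelled")
    if rho < 1.0:
        missing = [r.sample_id for r in refs if r.expression is None]
        if missing:
            warnings.warn(
                f"excluding references with missing expression: {missing}",
                stacklevel=2,
            )
            refs = [r for r in refs if r.expression is not None]
    if not refs:
        raise ValueError("no usable references")
    if len(refs) < n_neighbors:
        warnings.warn(
            f"only {len(refs)} references for n_neighbors={n_neighbors}; using all",
            stacklevel=2,
        )
    d = np.array([hybrid_distance(query, r, rho) for r in refs])
    ids = np.array([r.sample_id for r in refs])
    labels = np.array([r.label for r in refs])
    winner, in_set, kth = vote_from_distances(d, labels, ids, n_neighbors)
    k = min(n_neighbors, len(refs))
    neighbor_ids = [str(ids[i]) for i in in_set]
    dists = [float(d[i]) for i in in_set]
    tie_flags = [pos >= k for pos in range(len(in_set))]
    votes: dict[str, int] = {}
    for i in in_set:
        votes[str(labels[i])] = votes.get(str(labels[i]), 0) + 1
    return NeighborResult(
        query_id=query.sample_id,
        neighbor_ids=neighbor_ids,
        distances=dists,
        included_by_tie=tie_flags,
        predicted_label=winner,
        vote_counts=votes,
    )
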