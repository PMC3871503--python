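"""K-means center placement for the RBF hidden layer.

Two modes are provided.  ``batch`` is standard Lloyd iteration: assign every
sample to its nearest center, recompute all centers, repeat.  ``online`` is
the sequential variant in which a randomly ordered stream of samples is
assigned one at a time and the receiving center is recomputed immediately;
the stream order is a seeded permutation of the data, one full pass per
epoch.  Both modes start from k distinct data rows sampled uniformly (an
axis-aligned bounding-box initialisation is available via ``init="box"``)
and stop when no center coordinate moves by ``tol`` or more.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, InfeasibleKError


@dataclass
class Centers:
    """Result of a k-means run: center rows, per-sample assignment, diagnostics."""

    mu: np.ndarray
    assignment: np.ndarray
    n_iterations: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return self.mu.shape[0]


def wcss(X: np.ndarray, mu: np.ndarray, assignment: np.ndarray) -> float:
    """Within-cluster sum of squared Euclidean distances."""
    return float(np.sum((X - mu[assignment]) ** 2))


def _nearest(X: np.ndarray, mu: np.ndarray) -> np.ndarray:
    # argmin breaks distance ties toward the lowest cluster index
    return np.argmin(cdist(X, mu, metric="sqeuclidean"), axis=1)


def _init_centers(X, k, rng, init):
    if init == "box":
        lo, hi = X.min(axis=0), X.max(axis=0)
        return rng.uniform(lo, hi, size=(k, X.shape[1]))
    distinct = np.unique(X, axis=0)
    rows = rng.choice(len(distinct), size=k, replace=False)
    return distinct[rows].astype(float).copy()


def _fix_empty(X, mu, assignment):
    """Re-seed each empty cluster with the sample farthest from its center."""
    for j in range(mu.shape[0]):
        if not np.any(assignment == j):
            sq = np.sum((X - mu[assignment]) ** 2, axis=1)
            far = int(np.argmax(sq))
            mu[j] = X[far]
            assignment[far] = j
    return mu, assignment


def kmeans(
    X,
    k: int,
    mode: str = "batch",
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: str = "data",
) -> Centers:
    """Cluster the rows of ``X`` into ``k`` groups.

    Requires ``k`` no larger than the number of distinct rows.  Returns the
    centers with every sample assigned to its nearest center and no cluster
    empty.  Fixing the seed fixes the result exactly, in both modes.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty 2-D sample matrix")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if mode not in ("batch", "online"):
        raise ValueError(f"mode must be 'batch' or 'online', got {mode!r}")
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise InfeasibleKError(
            f"k={k} exceeds the {n_distinct} distinct samples"
        )
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol < 0:
        raise ValueError("tol must be >= 0")

    rng = np.random.default_rng(seed)
    mu = _init_centers(X, k, rng, init)

    converged = False
    n_iter = 0
    if mode == "batch":
        for n_iter in range(1, max_iter + 1):
            assignment = _nearest(X, mu)
            mu, assignment = _fix_empty(X, mu, assignment)
            new_mu = np.vstack([
                X[assignment == j].mean(axis=0) for j in range(k)
            ])
            shift = np.max(np.abs(new_mu - mu))
            mu = new_mu
            if shift < tol:
                converged = True
                break
    else:
        assignment = _nearest(X, mu)
        mu, assignment = _fix_empty(X, mu, assignment)
        for n_iter in range(1, max_iter + 1):
            mu_before = mu.copy()
            order = rng.permutation(len(X))
            for i in order:
                j = int(np.argmin(np.sum((mu - X[i]) ** 2, axis=1)))
                assignment[i] = j
                members = assignment == j
                mu[j] = X[members].mean(axis=0)
            if np.max(np.abs(mu - mu_before)) < tol:
                converged = True
                break

    # Invariant repair: final assignment is nearest-center, no empty cluster.
    assignment = _nearest(X, mu)
    while any(not np.any(assignment == j) for j in range(k)):
        mu, assignment = _fix_empty(X, mu, assignment)
        assignment = _nearest(X, mu)
    return Centers(mu=mu, assignment=assignment, n_iterations=n_iter,
                   converged=converged)


def max_center_distance(centers) -> float:
    """Maximum pairwise Euclidean distance among the centers."""
    mu = centers.mu if isinstance(centers, Centers) else np.asarray(centers, float)
    if mu.shape[0] < 2:
        raise DegenerateGeometryError(
            "max center distance needs at least 2 centers"
        )
    return float(cdist(mu, mu).max())
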