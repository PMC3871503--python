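"""Gaussian radial-basis-function network with pseudoinverse output training.

The network maps a 16-dimensional clinical feature vector x through n hidden
Gaussian units

    phi_j(x) = exp(-||x - mu_j||^2 / (2 sigma^2)),

whose centers mu_j come from k-means and whose shared variance follows the
spread heuristic sigma^2 = eta * d^2 / 2, with d the maximum inter-center
distance and eta an empirical smoothness factor (0.6 by default).  The single
output is the affine combination y = w0 + sum_j w_j phi_j(x); the weight
vector is the least-squares solution of the hidden-layer design system
H W = y against -1/+1 treatment labels, i.e. the pseudoinverse solution
W = (H^T H)^{-1} H^T y when H^T H is nonsingular.  Raw scores are rescaled
to p = clip((y + 1)/2, 0, 1) so a probability-like cutoff in [0, 1] applies.

Binary task, one output node; all hidden units share one variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import Centers, kmeans, max_center_distance
from .errors import DegenerateGeometryError, NotFittedError

logger = logging.getLogger(__name__)


def spread(centers, eta: float) -> float:
    """Shared Gaussian variance sigma^2 = eta * d^2 / 2 from the center geometry."""
    if not eta > 0:
        raise ValueError(f"eta must be positive, got {eta}")
    d = max_center_distance(centers)
    if d == 0.0:
        raise DegenerateGeometryError("all centers coincide; spread undefined")
    return eta * d * d / 2.0


def activation(x, mu_j, sigma2: float) -> float:
    """Gaussian response of one hidden unit to one input."""
    x = np.asarray(x, dtype=float)
    mu_j = np.asarray(mu_j, dtype=float)
    if x.shape != mu_j.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {mu_j.shape}")
    if not sigma2 > 0:
        raise ValueError(f"sigma2 must be positive, got {sigma2}")
    return float(np.exp(-np.sum((x - mu_j) ** 2) / (2.0 * sigma2)))


@dataclass
class RBFNetwork:
    """A fitted (or under-construction) RBF classifier.

    ``weights`` is ordered bias-first: W = [w0, w1, ..., wn].  ``cutoff`` is
    the decision threshold on the rescaled score p, initialised to 0.5 and
    typically replaced by the ROC-optimal (Youden) cutoff downstream.
    """

    centers: np.ndarray
    sigma2: float
    eta: float
    weights: np.ndarray | None = None
    cutoff: float = 0.5

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_hidden + 1,):
                raise ValueError(
                    f"weights must have length n_hidden+1 = {self.n_hidden + 1}"
                )
        if not 0.0 <= self.cutoff <= 1.0:
            raise ValueError(f"cutoff must lie in [0, 1], got {self.cutoff}")

    @property
    def n_hidden(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features(self) -> int:
        return self.centers.shape[1]

    def _require_fitted(self) -> None:
        if self.weights is None:
            raise NotFittedError("network has no output weights yet")


def design_matrix(X, net: RBFNetwork) -> np.ndarray:
    """N x (n_hidden + 1) design matrix; column 0 is the all-ones bias column."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        return np.zeros((0, net.n_hidden + 1))
    if X.shape[1] != net.n_features:
        raise ValueError(
            f"samples have {X.shape[1]} features, network expects {net.n_features}"
        )
    sq = cdist(X, net.centers, metric="sqeuclidean")
    phi = np.exp(-sq / (2.0 * net.sigma2))
    return np.hstack([np.ones((X.shape[0], 1)), phi])


def fit_weights(H: np.ndarray, y) -> np.ndarray:
    """Least-squares output weights for the design system H W ~= y.

    Solved by a rank-revealing routine; identical to the explicit
    pseudoinverse (H^T H)^{-1} H^T y whenever H has full column rank, and the
    minimum-norm solution (with a logged warning) when it does not.
    """
    H = np.asarray(H, dtype=float)
    y = np.asarray(y, dtype=float)
    if H.shape[0] != y.shape[0]:
        raise ValueError("H and y disagree on the number of samples")
    w, _, rank, _ = np.linalg.lstsq(H, y, rcond=None)
    if rank < H.shape[1]:
        logger.warning(
            "design matrix is rank-deficient (rank %d < %d); "
            "returning the minimum-norm solution", rank, H.shape[1]
        )
    return w


def train(
    X,
    y,
    n_hidden: int,
    eta: float = 0.6,
    seed: int | None = None,
    kmeans_mode: str = "batch",
    tol: float = 1e-6,
    max_iter: int = 300,
    sigma2_override: float | None = None,
) -> RBFNetwork:
    """Full training pass: k-means centers, spread heuristic, weight solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_hidden < 2:
        raise ValueError(f"n_hidden must be >= 2, got {n_hidden}")
    if not set(np.unique(y)) <= {-1.0, 1.0}:
        raise ValueError("labels must be -1/+1")
    centers = kmeans(X, n_hidden, mode=kmeans_mode, seed=seed,
                     max_iter=max_iter, tol=tol)
    sigma2 = sigma2_override if sigma2_override is not None else spread(centers, eta)
    net = RBFNetwork(centers=centers.mu, sigma2=sigma2, eta=eta)
    H = design_matrix(X, net)
    net.weights = fit_weights(H, y)
    return net


def predict_score(net: RBFNetwork, X) -> np.ndarray:
    """Raw network output y = w0 + sum_j w_j phi_j(x), one value per row."""
    net._require_fitted()
    return design_matrix(X, net) @ net.weights


def predict_prob(net: RBFNetwork, X) -> np.ndarray:
    """Rescaled score p = clip((y + 1) / 2, 0, 1)."""
    return np.clip((predict_score(net, X) + 1.0) / 2.0, 0.0, 1.0)


def predict_class(net: RBFNetwork, X) -> np.ndarray:
    """Thresholded decision: +1 (operation) where p >= cutoff, else -1."""
    return np.where(predict_prob(net, X) >= net.cutoff, 1, -1)


# ---------------------------------------------------------------------------
# Flat-text model serialization (key: value lines; one line per center row).

def save_model(net: RBFNetwork, path) -> None:
    net._require_fitted()
    lines = [
        f"eta: {net.eta!r}",
        f"sigma2: {net.sigma2!r}",
        f"cutoff: {net.cutoff!r}",
        f"n_hidden: {net.n_hidden}",
        f"n_features: {net.n_features}",
        "weights: " + ",".join(repr(float(w)) for w in net.weights),
    ]
    for j, row in enumerate(net.centers):
        lines.append(f"center_{j}: " + ",".join(repr(float(v)) for v in row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> RBFNetwork:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            key, _, value = line.partition(":")
            kv[key.strip()] = value.strip()
    n_hidden = int(kv["n_hidden"])
    centers = np.array([
        [float(v) for v in kv[f"center_{j}"].split(",")] for j in range(n_hidden)
    ])
    return RBFNetwork(
        centers=centers,
        sigma2=float(kv["sigma2"]),
        eta=float(kv["eta"]),
        weights=np.array([float(v) for v in kv["weights"].split(",")]),
        cutoff=float(kv["cutoff"]),
    )
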