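import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from padrbf import clinical_data, synthetic_data
from padrbf import rbf_network as rbf

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def make_cohort():
    """Factory: synthetic cohort -> encoded (X, y) at a given separation."""

    def _make(effect: float, seed: int, **overrides):
        spec = dataclasses.replace(
            synthetic_data.default_spec(), class_effect=effect, seed=seed,
            **overrides,
        )
        records = synthetic_data.generate(spec)
        vectors = clinical_data.encode_cohort(records)
        return clinical_data.features_matrix(vectors)

    return _make


@pytest.fixture(scope="session")
def default_cohort_xy(make_cohort):
    return make_cohort(effect=0.5, seed=7)


@pytest.fixture(scope="session")
def rbf_mixture():
    """Factory for data drawn from a known Gaussian-RBF score function.

    Centers sit at the vertices of a rotated, scaled simplex (all pairwise
    distances equal), the shared variance follows the same spread heuristic
    the network uses, output weights are +/-1, and labels are the sign of
    the generating score.  Returns train and held-out splits together with
    the generating scores so recovery can be checked by correlation.
    """

    def _make(seed: int, n_centers: int = 5, n_per: int = 40,
              sep: float = 4.0, noise_sd: float = 0.3, eta: float = 0.6):
        rng = np.random.default_rng(seed)
        dim = n_centers
        q, _ = np.linalg.qr(rng.normal(size=(dim, dim)))
        centers = sep * np.eye(dim) @ q  # rotated simplex vertices
        sigma2 = rbf.spread(centers, eta)
        weights = np.array([1.0 if j % 2 == 0 else -1.0
                            for j in range(n_centers)])

        def draw(n_per_cluster, rng):
            assign = np.repeat(np.arange(n_centers), n_per_cluster)
            X = centers[assign] + rng.normal(scale=noise_sd,
                                             size=(len(assign), dim))
            return X

        def score(X):
            net = rbf.RBFNetwork(centers=centers, sigma2=sigma2, eta=eta)
            phi = rbf.design_matrix(X, net)[:, 1:]
            return phi @ weights

        X_train = draw(n_per, rng)
        X_test = draw(max(n_per // 2, 10), rng)
        f_train, f_test = score(X_train), score(X_test)
        return {
            "X_train": X_train,
            "y_train": np.where(f_train >= 0, 1.0, -1.0),
            "X_test": X_test,
            "f_train": f_train,
            "f_test": f_test,
            "centers": centers,
            "sigma2": sigma2,
            "weights": weights,
            "eta": eta,
            "n_centers": n_centers,
        }

    return _make
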