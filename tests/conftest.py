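import warnings

import numpy as np
import pytest

from scpareto.io_qc import pca_project
from scpareto.synthetic import make_truth, simulate_latent

# non-converged PCHA restarts are expected in scans/permutation nulls
warnings.filterwarnings("ignore", message="PCHA hit max_iter")


@pytest.fixture(scope="session")
def triangle_truth():
    """3 archetypes, 1000 genes, vertices in 5 latent dimensions."""
    return make_truth(3, 1000, 5, 0.3, seed=1)


@pytest.fixture(scope="session")
def triangle_latent(triangle_truth):
    """1000 cells as Dirichlet(0.3) mixtures of the 3 vertices in 5 dims with
    2% isotropic noise, plus their PC projection — the shared simplex
    recovery scenario."""
    X, W = simulate_latent(triangle_truth.vertex_coords, 1000, alpha=0.3,
                           noise_frac=0.02, seed=1)
    ps = pca_project(X.T, d=5)
    return {"X": X, "W": W, "pcs": ps, "truth": triangle_truth}


@pytest.fixture
def flat_triangle():
    """300 cells in the plane inside the triangle (0,0), (10,0), (0,10)."""
    V = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    rng = np.random.default_rng(11)
    W = rng.dirichlet([0.3, 0.3, 0.3], size=300)
    return W @ V, V, W
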