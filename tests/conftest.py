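import numpy as np
import pytest

import traitnet as tn


def block_kinship(n_families: int, family_size: int, within: float = 0.5) -> np.ndarray:
    """Idealized family-block kinship: ``within`` inside families, 0 between."""
    n = n_families * family_size
    K = np.kron(np.eye(n_families), within * np.ones((family_size, family_size)))
    K += (1.0 - within) * np.eye(n)
    return K


@pytest.fixture(scope="session")
def small_markers():
    return tn.simulate_markers(n_lines=120, n_markers=500, n_families=4, seed=11)


@pytest.fixture(scope="session")
def small_kinship(small_markers):
    return tn.kinship_from_markers(small_markers)


@pytest.fixture(scope="session")
def chain3_truth():
    """Fully recursive 3-trait structure, all coefficients 1, unit innovations."""
    d = 3
    lam = np.zeros((d, d))
    lam[1, 0] = lam[2, 0] = lam[2, 1] = 1.0
    return tn.SyntheticTruth(
        lambda_u=lam,
        lambda_e=np.zeros((d, d)),
        psi_u=np.ones(d),
        psi_e=np.ones(d),
        mu=np.zeros(d),
        seed=5,
    )


@pytest.fixture(scope="session")
def sparse5_truth():
    """Sparse 5-trait ground truth: 3 genomic and 3 residual arcs."""
    d = 5
    lam_u = np.zeros((d, d))
    lam_u[1, 0] = lam_u[2, 0] = lam_u[3, 2] = 0.7
    lam_e = np.zeros((d, d))
    lam_e[2, 1] = lam_e[3, 1] = lam_e[4, 3] = 0.6
    return tn.SyntheticTruth(
        lambda_u=lam_u,
        lambda_e=lam_e,
        psi_u=np.full(d, 0.5),
        psi_e=np.full(d, 0.5),
        mu=np.zeros(d),
        seed=7,
    )
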