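"""Decorrelation of the genomic component across genotypes.

Genomic values fitted by the multivariate mixed model are correlated
between genotypes through the kinship matrix K in addition to being
correlated between traits through G.  Bayesian-network learning assumes
independent samples, so before structure learning the genomic component is
premultiplied by L⁻¹, where K = LLᵀ is the Cholesky factorization: for
u ~ N(0, G⊗K), u* = (I_d ⊗ L⁻¹) u has Var(u*) = G ⊗ I — genotypes become
independent while the between-trait covariance G is preserved.  The
residual component already has Var(e) = R ⊗ I by model assumption and is
passed through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = ["CholeskyTransform", "cholesky_factor", "decorrelate", "repair_pd"]


@dataclass
class CholeskyTransform:
    """Lower-triangular factor L with (K + ridge·I) = LLᵀ."""

    L: np.ndarray
    ridge_used: float = 0.0

    @property
    def n(self) -> int:
        return self.L.shape[0]


def repair_pd(
    K: np.ndarray, ridge_start: float = 1e-8, ridge_cap: float = 1e-2
) -> tuple[np.ndarray, float]:
    """Return a Cholesky factor of K, adding a doubling ridge if needed.

    Realized kinship matrices are not guaranteed positive definite
    (pedigree-based ones are); a ridge δ·I with δ doubling from
    ``ridge_start`` repairs near-singular input.  Raises if the cap is
    reached, reporting the smallest eigenvalue.
    """
    K = np.asarray(K, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be square and symmetric")
    K = (K + K.T) / 2.0
    try:
        return cholesky(K, lower=True), 0.0
    except np.linalg.LinAlgError:
        pass
    ridge = ridge_start
    eye = np.eye(K.shape[0])
    while ridge <= ridge_cap:
        try:
            return cholesky(K + ridge * eye, lower=True), ridge
        except np.linalg.LinAlgError:
            ridge *= 2.0
    lam_min = float(np.linalg.eigvalsh(K)[0])
    raise np.linalg.LinAlgError(
        f"kinship not positive definite after ridge repair up to {ridge_cap}; "
        f"smallest eigenvalue {lam_min:.3e}"
    )


def cholesky_factor(
    kinship: np.ndarray, ridge_start: float = 1e-8, ridge_cap: float = 1e-2
) -> CholeskyTransform:
    """Cholesky factor of the (PD-repaired) kinship matrix."""
    L, ridge = repair_pd(kinship, ridge_start=ridge_start, ridge_cap=ridge_cap)
    return CholeskyTransform(L=L, ridge_used=ridge)


def decorrelate(U: np.ndarray, transform: CholeskyTransform) -> np.ndarray:
    """Apply u* = (I_d ⊗ L⁻¹) u to an n×d matrix of genomic values.

    Under trait-major vectorization this is a forward-substitution solve
    L x = column for every trait column; L is never inverted explicitly.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim == 1:
        U = U[:, None]
    if U.shape[0] != transform.n:
        raise ValueError(
            f"genomic matrix has {U.shape[0]} rows but transform is for "
            f"{transform.n} genotypes"
        )
    return solve_triangular(transform.L, U, lower=True)
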