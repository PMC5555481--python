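"""Shared Gibbs sampler for the multivariate trait model and its SEM variants.

Model:  y = μ⊗1ₙ + u + e  with (u, e) jointly Gaussian,
Var(u) = G⊗K (genomic values correlated across genotypes through kinship K)
and Var(e) = R⊗Iₙ (residuals independent across genotypes), under
trait-major vectorization.  μ carries a flat prior.  Each of G and R is
either unstructured with an inverse-Wishart prior, or structured as
(I−Λ)⁻¹ diag(Ψ) (I−Λ)⁻ᵀ with Gaussian priors on the free coefficients of Λ
and scaled-inverse-χ² priors on the innovation variances Ψ (the structural
equation model case).

Two exact reparametrizations make each sweep O(n·d²):

* the eigendecomposition K = Q D Qᵀ decouples genotypes — rotated rows of
  the genomic matrix are independent with covariance dᵢG;
* a simultaneous diagonalization A with A G Aᵀ = W (diagonal) and
  A R Aᵀ = I reduces the per-genotype d×d posterior solve for u to
  elementwise shrinkage factors w·dᵢ/(w·dᵢ + 1).

Full conditionals: μ ~ N(row-mean of Y−U, R/n);
G | U ~ W⁻¹(Σ_G + UᵀK⁻¹U, ν_G + n); R | E ~ W⁻¹(Σ_R + EᵀE, ν_R + n);
structured components update each child's free coefficients by a conjugate
Bayesian regression of that trait's component on its parents, then the
innovation variance from its scaled-inverse-χ² full conditional, and
rebuild G* (R*) for the next u (e) update.

The per-iteration deviance recorded for DIC is the conditional deviance
−2·log N(y | μ+u, R⊗I) — the data likelihood given the genomic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy import stats
from scipy.linalg import cho_solve, cholesky, eigh, solve_triangular

__all__ = ["IWPrior", "StructuredPrior", "GibbsState", "run_gibbs", "GibbsDraws"]


@dataclass
class IWPrior:
    """Inverse-Wishart prior W⁻¹(Σ, ν), density ∝ |X|^−(ν+d+1)/2 exp(−tr(ΣX⁻¹)/2)."""

    nu: float
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=float))
        d = self.Sigma.shape[0]
        if self.nu <= d - 1:
            raise ValueError(f"degrees of freedom {self.nu} must exceed d-1={d - 1}")


@dataclass
class StructuredPrior:
    """Recursive-structure prior: free Λ entries N(0, v₀), Ψ scaled-inv-χ²(ν₀, s₀)."""

    pattern: np.ndarray  # (d, d) bool, True where a coefficient is free
    coeff_prior_var: float
    psi_df: float = 4.0
    psi_scale: float = 3.0

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern, dtype=bool)
        if np.any(np.diag(self.pattern)):
            raise ValueError("structure pattern cannot have self-loops")
        if self.coeff_prior_var <= 0:
            raise ValueError("coefficient prior variance must be positive")
        # acyclicity: Λ pattern must be nilpotent
        d = self.pattern.shape[0]
        reach = self.pattern.astype(int)
        power = reach.copy()
        for _ in range(d):
            power = (power @ reach > 0).astype(int)
            if np.any(np.diag(power)):
                raise ValueError("structure pattern contains a cycle")


ComponentPrior = Union[IWPrior, StructuredPrior]


@dataclass
class GibbsDraws:
    """Raw output of the sampler: posterior means and retained draws."""

    mu_hat: np.ndarray
    U_hat: np.ndarray
    E_hat: np.ndarray
    G_hat: np.ndarray
    R_hat: np.ndarray
    G_samples: np.ndarray
    R_samples: np.ndarray
    deviance_draws: np.ndarray
    deviance_at_mean: float
    lambda_g_samples: np.ndarray | None = None
    psi_g_samples: np.ndarray | None = None
    lambda_r_samples: np.ndarray | None = None
    psi_r_samples: np.ndarray | None = None
    n_retained: int = 0


@dataclass
class GibbsState:
    mu: np.ndarray
    Util: np.ndarray  # genomic values in the K-eigenbasis (Qᵀ U)
    G: np.ndarray
    R: np.ndarray
    lambda_g: np.ndarray | None = None
    psi_g: np.ndarray | None = None
    lambda_r: np.ndarray | None = None
    psi_r: np.ndarray | None = None


def _structured_cov(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    d = lam.shape[0]
    binv = np.linalg.inv(np.eye(d) - lam)
    cov = binv @ np.diag(psi) @ binv.T
    return (cov + cov.T) / 2.0


def _draw_invwishart(
    nu: float, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    scale = (scale + scale.T) / 2.0
    try:
        draw = stats.invwishart.rvs(df=nu, scale=scale, random_state=rng)
    except np.linalg.LinAlgError:
        # numerically non-PD scale: jitter and retry (logged by caller policy)
        jitter = 1e-8 * np.trace(scale) / scale.shape[0]
        draw = stats.invwishart.rvs(
            df=nu, scale=scale + jitter * np.eye(scale.shape[0]), random_state=rng
        )
    return np.atleast_2d(draw)


def _update_structured(
    comp: np.ndarray,
    prior: StructuredPrior,
    lam: np.ndarray,
    psi: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One sweep of λ and Ψ conditionals given the component matrix (n×d, iid rows)."""
    n, d = comp.shape
    lam = lam.copy()
    psi = psi.copy()
    for k in range(d):
        parents = np.flatnonzero(prior.pattern[k])
        y = comp[:, k]
        if parents.size:
            X = comp[:, parents]
            prec = X.T @ X / psi[k] + np.eye(parents.size) / prior.coeff_prior_var
            cp = cholesky(prec, lower=True)
            mean = cho_solve((cp, True), X.T @ y / psi[k])
            coef = mean + solve_triangular(
                cp.T, rng.standard_normal(parents.size), lower=False
            )
            lam[k, parents] = coef
            resid = y - X @ coef
        else:
            resid = y
        rss = float(resid @ resid)
        shape = (prior.psi_df + n) / 2.0
        scale = (prior.psi_scale + rss) / 2.0
        psi[k] = stats.invgamma.rvs(a=shape, scale=scale, random_state=rng)
    return lam, psi, _structured_cov(lam, psi)


def run_gibbs(
    Y: np.ndarray,
    K: np.ndarray,
    genomic_prior: ComponentPrior,
    residual_prior: ComponentPrior,
    burn_in: int,
    n_iter: int,
    thin: int,
    seed: int,
    L: np.ndarray | None = None,
) -> GibbsDraws:
    """Run the Gibbs sampler; see module docstring for the update cycle.

    ``L`` is the (fixed) Cholesky factor of K used to decorrelate u before
    the structured genomic update; it is computed here if not supplied.
    """
    Y = np.asarray(Y, dtype=float)
    n, d = Y.shape
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotype matrix contains non-finite values")
    rng = np.random.default_rng(seed)

    evals, Q = eigh((K + K.T) / 2.0)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError(
            f"kinship not positive definite (min eigenvalue {evals[0]:.3e}); "
            "repair it before sampling"
        )
    Ytil = Q.T @ Y

    needs_L = isinstance(genomic_prior, StructuredPrior)
    if needs_L and L is None:
        L = cholesky(K + 1e-10 * np.eye(n), lower=True)

    # initialization: split the sample covariance evenly between G and R
    Sy = np.cov(Y, rowvar=False, ddof=1).reshape(d, d)
    state = GibbsState(
        mu=Y.mean(axis=0),
        Util=np.zeros((n, d)),
        G=Sy / 2.0 + 1e-6 * np.eye(d),
        R=Sy / 2.0 + 1e-6 * np.eye(d),
    )
    if isinstance(genomic_prior, StructuredPrior):
        state.lambda_g = np.zeros((d, d))
        state.psi_g = np.diag(Sy) / 2.0 + 1e-6
    if isinstance(residual_prior, StructuredPrior):
        state.lambda_r = np.zeros((d, d))
        state.psi_r = np.diag(Sy) / 2.0 + 1e-6

    total = burn_in + n_iter
    n_ret = n_iter // thin
    G_samples = np.empty((n_ret, d, d))
    R_samples = np.empty((n_ret, d, d))
    dev_draws = np.empty(n_ret)
    lam_g_s = np.empty((n_ret, d, d)) if state.lambda_g is not None else None
    psi_g_s = np.empty((n_ret, d)) if state.psi_g is not None else None
    lam_r_s = np.empty((n_ret, d, d)) if state.lambda_r is not None else None
    psi_r_s = np.empty((n_ret, d)) if state.psi_r is not None else None

    mu_sum = np.zeros(d)
    U_sum = np.zeros((n, d))
    G_sum = np.zeros((d, d))
    R_sum = np.zeros((d, d))
    ret = 0

    for it in range(total):
        # --- u | rest (in the K-eigenbasis, simultaneous diagonalization) ---
        CR = cholesky(state.R, lower=True)
        CRinvG = solve_triangular(CR, state.G, lower=True)
        Gtil = solve_triangular(CR, CRinvG.T, lower=True).T
        w, V = eigh((Gtil + Gtil.T) / 2.0)
        w = np.maximum(w, 0.0)
        A = V.T @ solve_triangular(CR, np.eye(d), lower=True)
        Ainv = np.linalg.inv(A)
        Ycen_til = Ytil - (Q.T.sum(axis=1))[:, None] * state.mu[None, :]
        Z = Ycen_til @ A.T
        wd = evals[:, None] * w[None, :]  # (n, d)
        shrink = wd / (wd + 1.0)
        T = shrink * Z + np.sqrt(shrink) * rng.standard_normal((n, d))
        state.Util = T @ Ainv.T
        U = Q @ state.Util
        if not np.all(np.isfinite(U)):
            raise FloatingPointError(f"divergent chain at iteration {it}")

        # --- μ | rest (flat prior) ---
        resid_mean = (Y - U).mean(axis=0)
        state.mu = resid_mean + cholesky(state.R / n, lower=True) @ rng.standard_normal(d)
        E = Y - state.mu[None, :] - U

        # --- G | u ---
        if isinstance(genomic_prior, IWPrior):
            S = state.Util.T @ (state.Util / evals[:, None])
            state.G = _draw_invwishart(
                genomic_prior.nu + n, genomic_prior.Sigma + S, rng
            )
        else:
            Ustar = solve_triangular(L, U, lower=True)
            state.lambda_g, state.psi_g, state.G = _update_structured(
                Ustar, genomic_prior, state.lambda_g, state.psi_g, rng
            )

        # --- R | e ---
        if isinstance(residual_prior, IWPrior):
            state.R = _draw_invwishart(
                residual_prior.nu + n, residual_prior.Sigma + E.T @ E, rng
            )
        else:
            state.lambda_r, state.psi_r, state.R = _update_structured(
                E, residual_prior, state.lambda_r, state.psi_r, rng
            )

        if it >= burn_in and (it - burn_in) % thin == 0 and ret < n_ret:
            mu_sum += state.mu
            U_sum += U
            G_sum += state.G
            R_sum += state.R
            G_samples[ret] = state.G
            R_samples[ret] = state.R
            dev_draws[ret] = _conditional_deviance(E, state.R)
            if lam_g_s is not None:
                lam_g_s[ret] = state.lambda_g
                psi_g_s[ret] = state.psi_g
            if lam_r_s is not None:
                lam_r_s[ret] = state.lambda_r
                psi_r_s[ret] = state.psi_r
            ret += 1

    if ret == 0:
        raise ValueError("no draws retained; increase n_iter or reduce thin")
    mu_hat = mu_sum / ret
    U_hat = U_sum / ret
    E_hat = Y - mu_hat[None, :] - U_hat
    R_hat = R_sum / ret
    return GibbsDraws(
        mu_hat=mu_hat,
        U_hat=U_hat,
        E_hat=E_hat,
        G_hat=G_sum / ret,
        R_hat=R_hat,
        G_samples=G_samples[:ret],
        R_samples=R_samples[:ret],
        deviance_draws=dev_draws[:ret],
        deviance_at_mean=_conditional_deviance(E_hat, R_hat),
        lambda_g_samples=None if lam_g_s is None else lam_g_s[:ret],
        psi_g_samples=None if psi_g_s is None else psi_g_s[:ret],
        lambda_r_samples=None if lam_r_s is None else lam_r_s[:ret],
        psi_r_samples=None if psi_r_s is None else psi_r_s[:ret],
        n_retained=ret,
    )


def _conditional_deviance(E: np.ndarray, R: np.ndarray) -> float:
    """−2·log N(y | μ+u, R⊗I) evaluated at the residual matrix E = Y−μ−U."""
    n, d = E.shape
    CR = cholesky((R + R.T) / 2.0, lower=True)
    half = solve_triangular(CR, E.T, lower=True)
    quad = float(np.sum(half * half))
    logdet = 2.0 * float(np.sum(np.log(np.diag(CR))))
    return n * d * np.log(2.0 * np.pi) + n * logdet + quad
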