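"""Structural equation models embedding learned trait networks.

Replaces the unstructured genomic and/or residual covariance of the
multivariate trait model by its recursive reconstruction
G* = (I−Λ)⁻¹ diag(Ψ) (I−Λ)⁻ᵀ, where Λ carries one freely varying
coefficient per learned arc (parent column → child row) and Ψ holds
diagonal innovation variances.  The Gibbs implementation extends the MTM
sampler: each sweep additionally transforms the current genomic draw to
u* = (I⊗L⁻¹)u (independent genotypes), draws the free coefficients of Λ
from their Gaussian full conditionals (a conjugate regression of each
child trait's component on its parents), draws Ψ from scaled-inverse-χ²
full conditionals, and rebuilds G* (R*) for the next u, e, μ updates.

Default priors: free coefficients N(0, 6.3) on the genomic side and
N(0, 0.07) on the residual side — chosen so twice the prior SD covers the
largest covariance components such models produce on standardized traits —
and scaled-inverse-χ²(4, 3) on every innovation variance (prior mode 0.5,
matching the multivariate model's trait-variance prior).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from traitnet._sampler import IWPrior, StructuredPrior, run_gibbs
from traitnet.dag import StructureMatrix
from traitnet.mtm import MCMCSettings, MTMHyperParams
from traitnet.simulate import TraitPanel
from traitnet.transform import repair_pd

__all__ = [
    "SEMSpec",
    "SEMPosterior",
    "reconstruct_covariance",
    "coefficient_prior_variance_bound",
    "count_parameters",
    "fit_sem",
]


def coefficient_prior_variance_bound(max_component: float) -> float:
    """Smallest N(0, v) prior variance covering a coefficient magnitude.

    A zero-mean normal prior "covers" the largest covariance component c
    seen in the unstructured fit when c lies within two prior SDs, i.e.
    v > (c/2)².  The defaults 6.3 and 0.07 come from components of 5.0
    (genomic) and 0.52 (residual) on standardized traits:
    (5/2)² = 6.25 and (0.52/2)² = 0.0676.
    """
    return (max_component / 2.0) ** 2


def reconstruct_covariance(Lambda: np.ndarray, Psi: np.ndarray) -> np.ndarray:
    """(I−Λ)⁻¹ diag(Ψ) (I−Λ)⁻ᵀ — always symmetric PD for positive Ψ."""
    Lambda = np.asarray(Lambda, dtype=float)
    Psi = np.asarray(Psi, dtype=float)
    if np.any(Psi <= 0):
        raise ValueError("innovation variances must be positive")
    d = Lambda.shape[0]
    binv = np.linalg.inv(np.eye(d) - Lambda)
    cov = binv @ np.diag(Psi) @ binv.T
    return (cov + cov.T) / 2.0


@dataclass
class SEMSpec:
    """Which components are structured, and the prior hyper-parameters.

    ``structure_genomic`` / ``structure_residual`` are
    :class:`~traitnet.dag.StructureMatrix` patterns or the string
    ``"unstructured"`` to keep the inverse-Wishart update for that
    component; at least one component must be structured.
    """

    structure_genomic: StructureMatrix | str = "unstructured"
    structure_residual: StructureMatrix | str = "unstructured"
    coeff_prior_var_genomic: float = 6.3
    coeff_prior_var_residual: float = 0.07
    psi_prior_df: float = 4.0
    psi_prior_scale: float = 3.0
    label: str = "SEM"

    def __post_init__(self) -> None:
        if self.genomic_structured is False and self.residual_structured is False:
            raise ValueError("at least one component must be structured")
        if self.coeff_prior_var_genomic <= 0 or self.coeff_prior_var_residual <= 0:
            raise ValueError("coefficient prior variances must be positive")

    @property
    def genomic_structured(self) -> bool:
        return isinstance(self.structure_genomic, StructureMatrix)

    @property
    def residual_structured(self) -> bool:
        return isinstance(self.structure_residual, StructureMatrix)


@dataclass
class SEMPosterior:
    """Posterior summaries of a fitted SEM."""

    mu_hat: np.ndarray
    U_hat: np.ndarray
    E_hat: np.ndarray
    G_star_hat: np.ndarray
    R_star_hat: np.ndarray
    G_samples: np.ndarray
    R_samples: np.ndarray
    lambda_genomic_hat: np.ndarray | None
    lambda_genomic_sd: np.ndarray | None
    lambda_residual_hat: np.ndarray | None
    lambda_residual_sd: np.ndarray | None
    psi_u_hat: np.ndarray | None
    psi_e_hat: np.ndarray | None
    deviance_draws: np.ndarray
    deviance_at_mean: float
    settings: MCMCSettings
    spec: SEMSpec
    trait_names: list[str] = field(default_factory=list)

    @property
    def model_label(self) -> str:
        return self.spec.label

    # aliases matching the unstructured posterior's field names, so the
    # assessment code can treat MTM and SEM posteriors interchangeably
    @property
    def G_hat(self) -> np.ndarray:
        return self.G_star_hat

    @property
    def R_hat(self) -> np.ndarray:
        return self.R_star_hat


def count_parameters(spec: SEMSpec, d: int) -> tuple[int, int, int, int]:
    """Connection and nonnull-parameter counts of a SEM specification.

    Returns (connections_genomic, connections_residual, nonnull_genomic,
    nonnull_residual).  Connections count the free entries of Λ; nonnull
    parameters count the structurally nonzero entries of the reconstructed
    covariance (upper triangle plus diagonal), obtained symbolically from
    the sparsity pattern: Σ_ij ≠ 0 iff traits i and j share an ancestor
    (every node is its own ancestor).  An unstructured component is fully
    recursive for counting: d(d−1)/2 connections and a dense covariance.
    """

    def counts(structure) -> tuple[int, int]:
        if not isinstance(structure, StructureMatrix):
            return d * (d - 1) // 2, d * (d + 1) // 2
        pat = structure.pattern.astype(int)
        # reachability closure of the pattern: B = (I - Λ)^-1 support
        reach = np.eye(d, dtype=int) | pat
        for _ in range(d):
            reach = (reach @ reach > 0).astype(int)
        support = (reach @ reach.T) > 0  # shared-ancestor indicator
        nonnull = int(np.triu(support).sum())
        return int(pat.sum()), nonnull

    cg, ng = counts(spec.structure_genomic)
    cr, nr = counts(spec.structure_residual)
    return cg, cr, ng, nr


def fit_sem(
    panel: TraitPanel,
    kinship: np.ndarray,
    spec: SEMSpec,
    mcmc: MCMCSettings | None = None,
    hyper: MTMHyperParams | None = None,
) -> SEMPosterior:
    """Gibbs-sample the SEM posterior on a trait panel.

    ``hyper`` supplies the inverse-Wishart prior for any component left
    unstructured.  The Cholesky factor of the (repaired) kinship used to
    decorrelate u inside the sampler is fixed, not resampled.
    """
    mcmc = mcmc or MCMCSettings()
    hyper = hyper or MTMHyperParams()
    d = panel.d
    if kinship.shape[0] != panel.n:
        raise ValueError("panel and kinship sizes disagree")
    L, _ = repair_pd(kinship)
    K = L @ L.T
    iw_g, iw_r = hyper.resolved(d)

    def prior_for(structure, coeff_var, iw):
        if isinstance(structure, StructureMatrix):
            if structure.d != d:
                raise ValueError("structure dimension disagrees with panel")
            return StructuredPrior(
                pattern=structure.pattern,
                coeff_prior_var=coeff_var,
                psi_df=spec.psi_prior_df,
                psi_scale=spec.psi_prior_scale,
            )
        return iw

    gp = prior_for(spec.structure_genomic, spec.coeff_prior_var_genomic, iw_g)
    rp = prior_for(spec.structure_residual, spec.coeff_prior_var_residual, iw_r)

    draws = run_gibbs(
        panel.values, K, gp, rp, mcmc.burn_in, mcmc.n_iter, mcmc.thin, mcmc.seed, L=L
    )

    def summarize(samples):
        if samples is None:
            return None, None
        return samples.mean(axis=0), samples.std(axis=0, ddof=1)

    lam_g, lam_g_sd = summarize(draws.lambda_g_samples)
    lam_r, lam_r_sd = summarize(draws.lambda_r_samples)
    return SEMPosterior(
        mu_hat=draws.mu_hat,
        U_hat=draws.U_hat,
        E_hat=draws.E_hat,
        G_star_hat=draws.G_hat,
        R_star_hat=draws.R_hat,
        G_samples=draws.G_samples,
        R_samples=draws.R_samples,
        lambda_genomic_hat=lam_g,
        lambda_genomic_sd=lam_g_sd,
        lambda_residual_hat=lam_r,
        lambda_residual_sd=lam_r_sd,
        psi_u_hat=None if draws.psi_g_samples is None else draws.psi_g_samples.mean(axis=0),
        psi_e_hat=None if draws.psi_r_samples is None else draws.psi_r_samples.mean(axis=0),
        deviance_draws=draws.deviance_draws,
        deviance_at_mean=draws.deviance_at_mean,
        settings=mcmc,
        spec=spec,
        trait_names=list(panel.trait_names),
    )
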