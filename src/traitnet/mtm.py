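"""Bayesian multivariate trait model (MTM): decomposition of phenotypes.

Fits  y = μ⊗1ₙ + u + e  with Var(u) = G⊗K and Var(e) = R⊗Iₙ by Gibbs
sampling.  G and R carry independent inverse-Wishart priors; the default
hyper-parameters ν = 8 and Σ = 7·I put the prior mode of every trait's
genomic and residual variance at 0.5 (appropriate for traits standardized
to unit variance, splitting the phenotypic variance evenly a priori) while
remaining weakly informative.  The inverse-Wishart parametrization is fixed
to density ∝ |G|^−(ν+d+1)/2 exp(−tr(ΣG⁻¹)/2), the same convention as
``scipy.stats.invwishart``, under which the mode is Σ/(ν+d+1).

The single-trait baseline uses the d=1 special case — a scaled-inverse-χ²
prior with 4 degrees of freedom and scale 3, whose mode 3/(4+2) = 0.5
matches the multivariate prior's marginal trait-variance mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traitnet._sampler import GibbsDraws, IWPrior, run_gibbs
from traitnet.simulate import TraitPanel
from traitnet.transform import repair_pd

__all__ = [
    "MTMHyperParams",
    "MCMCSettings",
    "MTMPosterior",
    "SingleTraitPosterior",
    "inverse_wishart_mode",
    "scaled_inv_chi2_mode",
    "fit_mtm",
    "fit_single_trait",
    "posterior_correlations",
]


def inverse_wishart_mode(nu: float, Sigma: np.ndarray, d: int) -> np.ndarray:
    """Mode Σ/(ν+d+1) of the inverse-Wishart distribution W⁻¹(Σ, ν)."""
    if nu <= d - 1:
        raise ValueError(f"need nu > d-1; got nu={nu}, d={d}")
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    if Sigma.shape != (d, d):
        raise ValueError(f"scale matrix must be {d}x{d}")
    return Sigma / (nu + d + 1.0)


def scaled_inv_chi2_mode(df: float, scale: float) -> float:
    """Mode S/(ν+2) of the scaled-inverse-χ² prior, the d=1 inverse-Wishart."""
    return float(inverse_wishart_mode(df, np.array([[scale]]), 1)[0, 0])


@dataclass
class MTMHyperParams:
    """Inverse-Wishart hyper-parameters for G and R."""

    nu_G: float = 8.0
    nu_R: float = 8.0
    Sigma_G: np.ndarray | None = None
    Sigma_R: np.ndarray | None = None

    def resolved(self, d: int) -> tuple[IWPrior, IWPrior]:
        sg = 7.0 * np.eye(d) if self.Sigma_G is None else np.asarray(self.Sigma_G)
        sr = 7.0 * np.eye(d) if self.Sigma_R is None else np.asarray(self.Sigma_R)
        return IWPrior(self.nu_G, sg), IWPrior(self.nu_R, sr)


@dataclass
class MCMCSettings:
    """Chain lengths; defaults mirror the long production run (tests scale down)."""

    burn_in: int = 30_000
    n_iter: int = 300_000
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1 or self.n_iter < 1 or self.burn_in < 0:
            raise ValueError("invalid MCMC settings")

    @property
    def n_retained(self) -> int:
        return self.n_iter // self.thin


@dataclass
class MTMPosterior:
    """Posterior means and retained covariance draws from the MTM."""

    mu_hat: np.ndarray
    U_hat: np.ndarray
    E_hat: np.ndarray
    G_hat: np.ndarray
    R_hat: np.ndarray
    G_samples: np.ndarray
    R_samples: np.ndarray
    deviance_draws: np.ndarray
    deviance_at_mean: float
    settings: MCMCSettings
    trait_names: list[str] = field(default_factory=list)
    model_label: str = "MTM"

    def export(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = self.trait_names or [f"T{k+1}" for k in range(len(self.mu_hat))]
        pd.DataFrame(self.U_hat, columns=names).to_csv(outdir / "U_hat.csv", index=False)
        pd.DataFrame(self.E_hat, columns=names).to_csv(outdir / "E_hat.csv", index=False)
        pd.DataFrame(self.G_hat, index=names, columns=names).to_csv(outdir / "G_hat.csv")
        pd.DataFrame(self.R_hat, index=names, columns=names).to_csv(outdir / "R_hat.csv")
        gc, gs, rc, rs = posterior_correlations(self)
        pd.DataFrame(gc, index=names, columns=names).to_csv(outdir / "genomic_corr.csv")
        pd.DataFrame(rc, index=names, columns=names).to_csv(outdir / "residual_corr.csv")


def fit_mtm(
    panel: TraitPanel,
    kinship: np.ndarray,
    hyper: MTMHyperParams | None = None,
    mcmc: MCMCSettings | None = None,
) -> MTMPosterior:
    """Gibbs-sample the MTM posterior on a trait panel.

    The kinship matrix is PD-repaired (doubling ridge) before its
    eigendecomposition.  Zero-variance trait columns are rejected up front:
    the model assumes standardized traits and a degenerate column would only
    return the prior.
    """
    hyper = hyper or MTMHyperParams()
    mcmc = mcmc or MCMCSettings()
    Y = panel.values
    sd = Y.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [panel.trait_names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance trait column(s): {bad}")
    if kinship.shape[0] != panel.n:
        raise ValueError("panel and kinship sizes disagree")
    L, ridge = repair_pd(kinship)
    K = L @ L.T  # repaired kinship
    gp, rp = hyper.resolved(panel.d)
    draws = run_gibbs(
        Y, K, gp, rp, mcmc.burn_in, mcmc.n_iter, mcmc.thin, mcmc.seed
    )
    return MTMPosterior(
        mu_hat=draws.mu_hat,
        U_hat=draws.U_hat,
        E_hat=draws.E_hat,
        G_hat=draws.G_hat,
        R_hat=draws.R_hat,
        G_samples=draws.G_samples,
        R_samples=draws.R_samples,
        deviance_draws=draws.deviance_draws,
        deviance_at_mean=draws.deviance_at_mean,
        settings=mcmc,
        trait_names=list(panel.trait_names),
    )


def posterior_correlations(
    posterior: MTMPosterior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Genomic and residual trait correlations with posterior SDs.

    Correlations are computed per retained draw and then averaged (the SDs
    are across draws, sample convention ddof=1); averaging correlations of
    draws rather than correlating averaged covariances keeps the estimate a
    proper posterior mean of the correlation.
    Returns (genomic_corr, genomic_sd, residual_corr, residual_sd).
    """
    if posterior.G_samples.shape[0] < 2:
        raise ValueError("need at least 2 retained draws")

    def per_draw(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = np.sqrt(np.einsum("tii->ti", samples))
        corr = samples / (sd[:, :, None] * sd[:, None, :])
        mean = corr.mean(axis=0)
        spread = corr.std(axis=0, ddof=1)
        np.fill_diagonal(mean, 1.0)
        np.fill_diagonal(spread, 0.0)
        return mean, spread

    gc, gs = per_draw(posterior.G_samples)
    rc, rs = per_draw(posterior.R_samples)
    return gc, gs, rc, rs


@dataclass
class SingleTraitPosterior:
    """Posterior means from the univariate genomic model (single-trait GBLUP)."""

    mu_hat: float
    u_hat: np.ndarray
    sigma_g2_hat: float
    sigma_e2_hat: float
    sigma_g2_samples: np.ndarray
    sigma_e2_samples: np.ndarray
    deviance_draws: np.ndarray
    deviance_at_mean: float
    settings: MCMCSettings


def fit_single_trait(
    y: np.ndarray,
    kinship: np.ndarray,
    mcmc: MCMCSettings | None = None,
    prior_df: float = 4.0,
    prior_scale: float = 3.0,
) -> SingleTraitPosterior:
    """Univariate Bayesian genomic model: the MTM restricted to d = 1.

    Genomic and residual variances carry scaled-inverse-χ² priors
    (default df 4, scale 3, mode 0.5), matching the marginal trait-variance
    prior of the multivariate model.
    """
    mcmc = mcmc or MCMCSettings()
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    L, _ = repair_pd(kinship)
    K = L @ L.T
    prior = IWPrior(prior_df, np.array([[prior_scale]]))
    draws = run_gibbs(y, K, prior, prior, mcmc.burn_in, mcmc.n_iter, mcmc.thin, mcmc.seed)
    return SingleTraitPosterior(
        mu_hat=float(draws.mu_hat[0]),
        u_hat=draws.U_hat[:, 0],
        sigma_g2_hat=float(draws.G_hat[0, 0]),
        sigma_e2_hat=float(draws.R_hat[0, 0]),
        sigma_g2_samples=draws.G_samples[:, 0, 0],
        sigma_e2_samples=draws.R_samples[:, 0, 0],
        deviance_draws=draws.deviance_draws,
        deviance_at_mean=draws.deviance_at_mean,
        settings=mcmc,
    )
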