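"""Model comparison: DIC, plug-in marginal likelihood, cross-validation.

* **DIC** — computed from the per-iteration conditional deviances
  D = −2·log N(y | μ+u, R⊗I): p_D = mean(D) − D(posterior means) and
  DIC = mean(D) + p_D.  Smaller is better; the effective-parameter count
  p_D is of the order of the dimension of the genomic-value vector.

* **Marginal log-likelihood** — a plug-in evaluation of the Gaussian
  log-density of y under N(μ̂⊗1, Ĝ⊗K + R̂⊗I) at the posterior means, via
  the eigendecomposition of K (O(n·d³)).  This is not a fully Bayesian
  evidence estimate; it is deterministic, cheap, and differences between
  models fitted to the same data are the quantity of interest.

* **Predictive ability** — replicated k-fold cross-validation (default 10
  replicates of 5 folds, the same 50 train/test splits for every model):
  each model is refitted on the training genotypes, held-out genotypes are
  predicted by the conditional multivariate normal given all training
  phenotypes (plug-in posterior-mean covariances and the cross-kinship
  block), and the per-trait correlation between observed and predicted
  values is averaged over splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, eigh

from traitnet.mtm import MCMCSettings, MTMHyperParams, fit_mtm, fit_single_trait
from traitnet.sem import SEMSpec, count_parameters, fit_sem
from traitnet.simulate import TraitPanel

__all__ = [
    "mcse",
    "FitMetrics",
    "CVResult",
    "compute_dic",
    "marginal_loglik",
    "cross_validate",
    "rank_models",
    "MTMModel",
    "SEMModel",
    "SingleTraitModel",
]


def mcse(draws: np.ndarray, n_batches: int = 30) -> np.ndarray:
    """Batch-means Monte-Carlo standard error of a chain's posterior mean.

    Accounts for autocorrelation by splitting the chain into ``n_batches``
    consecutive batches and using the spread of batch means.  ``draws`` may
    have any trailing shape; the first axis is the chain.
    """
    draws = np.asarray(draws, dtype=float)
    m = draws.shape[0]
    if m < 2 * n_batches:
        n_batches = max(2, m // 2)
    size = m // n_batches
    batches = draws[: n_batches * size].reshape(n_batches, size, *draws.shape[1:])
    means = batches.mean(axis=1)
    return means.std(axis=0, ddof=1) / np.sqrt(n_batches)


@dataclass
class FitMetrics:
    model_label: str
    dic: float
    p_d: float
    mean_deviance: float
    log_marginal: float = np.nan

    def __post_init__(self) -> None:
        # identity by construction: DIC = mean deviance + p_D
        assert abs(self.dic - (self.mean_deviance + self.p_d)) < 1e-6


def compute_dic(
    deviance_draws: np.ndarray, deviance_at_mean: float, model_label: str = ""
) -> FitMetrics:
    """DIC and effective parameter count from posterior deviance draws."""
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size < 2:
        raise ValueError("need at least 2 deviance draws")
    bad = np.flatnonzero(~np.isfinite(deviance_draws))
    if bad.size:
        raise ValueError(f"non-finite deviance at draw index {bad[0]}")
    if not np.isfinite(deviance_at_mean):
        raise ValueError("non-finite deviance at posterior mean")
    dbar = float(deviance_draws.mean())
    p_d = dbar - float(deviance_at_mean)
    return FitMetrics(model_label=model_label, dic=dbar + p_d, p_d=p_d, mean_deviance=dbar)


def marginal_loglik(posterior, panel: TraitPanel, kinship: np.ndarray) -> float:
    """Plug-in Gaussian log-density of the panel at the posterior means."""
    mu = np.asarray(posterior.mu_hat, dtype=float)
    G = np.atleast_2d(posterior.G_hat)
    R = np.atleast_2d(posterior.R_hat)
    Y = panel.values
    n, d = Y.shape
    evals, Q = eigh((kinship + kinship.T) / 2.0)
    Ytil = Q.T @ (Y - mu[None, :])
    total = 0.0
    for i in range(n):
        cov = evals[i] * G + R
        try:
            c, low = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"plug-in covariance not PD at eigenvalue {evals[i]:.3e}"
            ) from exc
        half = cho_solve((c, low), Ytil[i])
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        total += -0.5 * (d * np.log(2 * np.pi) + logdet + Ytil[i] @ half)
    return float(total)


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

class MTMModel:
    """Refittable multivariate trait model for cross-validation."""

    def __init__(self, hyper=None, mcmc=None, label="MTM"):
        self.hyper = hyper or MTMHyperParams()
        self.mcmc = mcmc or MCMCSettings()
        self.label = label

    def fit(self, panel: TraitPanel, kinship: np.ndarray):
        return fit_mtm(panel, kinship, self.hyper, self.mcmc)


class SEMModel:
    """Refittable SEM variant for cross-validation."""

    def __init__(self, spec: SEMSpec, hyper=None, mcmc=None, label=None):
        self.spec = spec
        self.hyper = hyper or MTMHyperParams()
        self.mcmc = mcmc or MCMCSettings()
        self.label = label or spec.label

    def fit(self, panel: TraitPanel, kinship: np.ndarray):
        return fit_sem(panel, kinship, self.spec, self.mcmc, self.hyper)


@dataclass
class _DiagonalPosterior:
    mu_hat: np.ndarray
    G_hat: np.ndarray
    R_hat: np.ndarray


class SingleTraitModel:
    """Univariate baseline: independent genomic models per trait.

    The per-trait posteriors assemble into diagonal Ĝ and R̂, so held-out
    predictions use only each trait's own training data — no information is
    borrowed across traits.
    """

    def __init__(self, mcmc=None, label="single-trait"):
        self.mcmc = mcmc or MCMCSettings()
        self.label = label

    def fit(self, panel: TraitPanel, kinship: np.ndarray):
        d = panel.d
        mu = np.empty(d)
        g = np.zeros((d, d))
        r = np.zeros((d, d))
        for k in range(d):
            settings = MCMCSettings(
                burn_in=self.mcmc.burn_in,
                n_iter=self.mcmc.n_iter,
                thin=self.mcmc.thin,
                seed=self.mcmc.seed + k,
            )
            post = fit_single_trait(panel.values[:, k], kinship, settings)
            mu[k] = post.mu_hat
            g[k, k] = post.sigma_g2_hat
            r[k, k] = post.sigma_e2_hat
        return _DiagonalPosterior(mu_hat=mu, G_hat=g, R_hat=r)


@dataclass
class CVResult:
    """Replicated k-fold predictive abilities, shared splits across models."""

    replicates: int
    folds: int
    trait_names: list[str]
    fold_assignments: np.ndarray  # (replicates, n) fold index per genotype
    ability_mean: pd.DataFrame  # model × trait
    ability_sd: pd.DataFrame
    seed: int = 0
    per_split: dict = field(default_factory=dict)  # label -> (splits, d)


def make_folds(n: int, replicates: int, folds: int, seed: int) -> np.ndarray:
    """Uniform random fold assignments: (replicates, n) array of fold ids."""
    if n < folds:
        raise ValueError("need at least one genotype per fold")
    rng = np.random.default_rng(seed)
    out = np.empty((replicates, n), dtype=int)
    base = np.arange(n) % folds  # fold sizes differ by at most one
    for r in range(replicates):
        out[r] = rng.permutation(base)
    return out


def _predict_conditional(mu, G, R, K, train, test, Y_train):
    """E[y_test | y_train] under N(μ⊗1, G⊗K + R⊗I) with plug-in moments."""
    d = len(mu)
    K_tt = K[np.ix_(train, train)]
    K_st = K[np.ix_(test, train)]
    Sigma_tt = np.kron(G, K_tt) + np.kron(R, np.eye(len(train)))
    Sigma_st = np.kron(G, K_st)  # residuals of held-out genotypes are independent
    resid = (Y_train - mu[None, :]).T.ravel()  # trait-major
    c, low = cho_factor(Sigma_tt, lower=True)
    pred = Sigma_st @ cho_solve((c, low), resid)
    return mu[None, :] + pred.reshape(d, len(test)).T


def cross_validate(
    panel: TraitPanel,
    kinship: np.ndarray,
    models: list,
    replicates: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Replicated k-fold cross-validation with splits shared across models.

    Every model in ``models`` (objects with ``label`` and
    ``fit(panel, kinship) -> posterior``) is refitted on each training set;
    held-out genotypes are predicted from the conditional multivariate
    normal given the training phenotypes of all traits.  Predictive ability
    is the per-trait correlation between observed and predicted values on
    the test set, averaged over the replicates × folds splits (SD across
    splits, ddof=1).
    """
    Y = panel.values
    n, d = Y.shape
    assignments = make_folds(n, replicates, folds, seed)
    names = list(panel.trait_names)
    per_split: dict[str, np.ndarray] = {
        m.label: np.full((replicates * folds, d), np.nan) for m in models
    }

    for r in range(replicates):
        for f in range(folds):
            test = np.flatnonzero(assignments[r] == f)
            train = np.flatnonzero(assignments[r] != f)
            if test.size < 2:
                raise ValueError(f"fold {f} of replicate {r} has <2 test genotypes")
            sub = TraitPanel(
                values=Y[train],
                trait_names=names,
                genotype_ids=[panel.genotype_ids[i] for i in train],
                family_ids=[panel.family_ids[i] for i in train],
                standardized=panel.standardized,
            )
            K_train = kinship[np.ix_(train, train)]
            for m in models:
                post = m.fit(sub, K_train)
                pred = _predict_conditional(
                    np.asarray(post.mu_hat, float),
                    np.atleast_2d(post.G_hat),
                    np.atleast_2d(post.R_hat),
                    kinship,
                    train,
                    test,
                    Y[train],
                )
                for k in range(d):
                    obs = Y[test, k]
                    if obs.std() == 0 or pred[:, k].std() == 0:
                        corr = 0.0
                    else:
                        corr = float(np.corrcoef(obs, pred[:, k])[0, 1])
                    per_split[m.label][r * folds + f, k] = corr

    mean = pd.DataFrame(
        {m.label: per_split[m.label].mean(axis=0) for m in models}, index=names
    ).T
    sd = pd.DataFrame(
        {m.label: per_split[m.label].std(axis=0, ddof=1) for m in models}, index=names
    ).T
    return CVResult(
        replicates=replicates,
        folds=folds,
        trait_names=names,
        fold_assignments=assignments,
        ability_mean=mean,
        ability_sd=sd,
        seed=seed,
        per_split=per_split,
    )


def rank_models(
    metrics: list[FitMetrics],
    cv: CVResult | None = None,
    counts: dict[str, tuple[int, int, int, int]] | None = None,
    reference: str = "MTM",
) -> pd.DataFrame:
    """Comparison table of DIC/p_D/logL differences relative to a reference.

    Mirrors the usual goodness-of-fit layout: one row per model with the
    deltas ΔDIC, Δp_D, ΔlogL against the reference model (typically the
    unstructured multivariate model), connection and nonnull-parameter
    counts where supplied, and mean cross-validated predictive ability.
    Rows are sorted by DIC (best first).
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 models to rank")
    by_label = {m.model_label: m for m in metrics}
    if reference not in by_label:
        raise ValueError(f"reference model {reference!r} not among metrics")
    ref = by_label[reference]
    rows = []
    for m in sorted(metrics, key=lambda m: m.dic):
        row = {
            "model": m.model_label,
            "delta_dic": m.dic - ref.dic,
            "delta_p_d": m.p_d - ref.p_d,
            "delta_logL": m.log_marginal - ref.log_marginal,
        }
        if counts and m.model_label in counts:
            cg, cr, ng, nr = counts[m.model_label]
            row["connections"] = cg + cr
            row["nonnull_parameters"] = ng + nr
        if cv is not None and m.model_label in cv.ability_mean.index:
            row["predictive_ability"] = float(
                cv.ability_mean.loc[m.model_label].mean()
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
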