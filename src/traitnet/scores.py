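"""Decomposable network scores for Gaussian Bayesian networks.

Both scores factorize over nodes given their parent sets and are computed
from the sample mean and centered scatter matrix only, so scoring a
candidate graph costs O(|pa|³) per node regardless of sample size.

* **BIC** — per node, the maximized Gaussian log-likelihood of the child
  regressed on its parents minus (k/2)·ln n, where k = |pa| + 2 counts the
  regression coefficients, the intercept, and the residual variance.
  Larger is better.

* **BGe** — the Bayesian Gaussian equivalent score: the log marginal
  likelihood of the data under a Normal-Wishart prior.  With prior mean set
  to the sample mean and scale matrix T = t·I, t = α_μ(α_w−d−1)/(α_μ+1),
  the local score is l(pa ∪ {x}) − l(pa) with

      l(Y) = −n·|Y|/2·ln(2π) + |Y|/2·ln(α_μ/(n+α_μ))
             + ln Γ_|Y|((n+α_w−d+|Y|)/2) − ln Γ_|Y|((α_w−d+|Y|)/2)
             + (α_w−d+|Y|)/2·ln|T_Y| − (n+α_w−d+|Y|)/2·ln|R_Y|,

  R = T + S (S the centered scatter).  Defaults α_μ = 1, α_w = d + 2.

Both scores assign equal values to Markov-equivalent DAGs (score
equivalence); for BGe this holds for any SPD T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import multigammaln

from traitnet.dag import DAGStructure

__all__ = ["BGeHyperParams", "GaussianSuffStats", "ScoreCache", "score_network"]

SCORES = ("bic", "bge")


@dataclass
class BGeHyperParams:
    """Imaginary sample sizes of the Normal-Wishart prior behind BGe."""

    alpha_mu: float = 1.0
    alpha_w: float | None = None  # defaults to d + 2

    def resolved_aw(self, d: int) -> float:
        return float(d + 2) if self.alpha_w is None else float(self.alpha_w)


class GaussianSuffStats:
    """Sample size, mean, and centered scatter of an n×d data matrix."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        self.n = data.shape[0]
        self.d = data.shape[1]
        self.mean = data.mean(axis=0)
        centered = data - self.mean
        self.scatter = centered.T @ centered

    @classmethod
    def from_moments(cls, n: int, mean: np.ndarray, scatter: np.ndarray):
        obj = cls.__new__(cls)
        obj.n = int(n)
        obj.d = len(mean)
        obj.mean = np.asarray(mean, float)
        obj.scatter = np.asarray(scatter, float)
        return obj


class ScoreCache:
    """Memoized local scores over (node, parent-set) pairs."""

    def __init__(
        self,
        data: np.ndarray,
        score: str = "bic",
        bge: BGeHyperParams | None = None,
    ):
        if score not in SCORES:
            raise ValueError(f"unknown score {score!r}; choose from {SCORES}")
        self.score = score
        self.stats = GaussianSuffStats(data)
        self.bge = bge or BGeHyperParams()
        self._local: dict[tuple[int, frozenset], float] = {}
        self._setscore: dict[frozenset, float] = {}
        if self.stats.n <= self.stats.d + 2:
            raise ValueError("need n > d + 2 observations to score networks")

    # ---- BIC ----
    def _bic_local(self, node: int, parents: frozenset) -> float:
        S = self.stats.scatter
        n = self.stats.n
        p = sorted(parents)
        skk = S[node, node]
        if p:
            spp = S[np.ix_(p, p)]
            spk = S[p, node]
            rss = skk - spk @ np.linalg.solve(spp, spk)
        else:
            rss = skk
        sigma2 = max(rss / n, 1e-300)  # MLE residual variance
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
        k = len(p) + 2  # coefficients + intercept + residual variance
        return loglik - 0.5 * k * np.log(n)

    # ---- BGe ----
    def _bge_setscore(self, subset: frozenset) -> float:
        if subset in self._setscore:
            return self._setscore[subset]
        if not subset:
            self._setscore[subset] = 0.0
            return 0.0
        idx = sorted(subset)
        k = len(idx)
        n, d = self.stats.n, self.stats.d
        am = self.bge.alpha_mu
        aw = self.bge.resolved_aw(d)
        t = am * (aw - d - 1.0) / (am + 1.0)
        # prior mean = sample mean, so the mean-shift term vanishes
        R = t * np.eye(k) + self.stats.scatter[np.ix_(idx, idx)]
        sign, logdet_R = np.linalg.slogdet(R)
        if sign <= 0:
            raise np.linalg.LinAlgError("posterior scale matrix not PD in BGe")
        val = (
            -0.5 * n * k * np.log(2.0 * np.pi)
            + 0.5 * k * np.log(am / (n + am))
            + multigammaln((n + aw - d + k) / 2.0, k)
            - multigammaln((aw - d + k) / 2.0, k)
            + 0.5 * (aw - d + k) * k * np.log(t)
            - 0.5 * (n + aw - d + k) * logdet_R
        )
        self._setscore[subset] = val
        return val

    def local(self, node: int, parents: frozenset) -> float:
        key = (node, parents)
        if key not in self._local:
            if self.score == "bic":
                val = self._bic_local(node, parents)
            else:
                val = self._bge_setscore(parents | {node}) - self._bge_setscore(parents)
            self._local[key] = val
        return self._local[key]

    def total(self, parent_sets: list[frozenset]) -> float:
        return sum(self.local(k, pa) for k, pa in enumerate(parent_sets))


def score_network(
    data: np.ndarray,
    dag: DAGStructure,
    score: str = "bic",
    bge: BGeHyperParams | None = None,
    cache: ScoreCache | None = None,
) -> float:
    """Score a fully directed acyclic network on data (larger is better)."""
    if not dag.is_fully_directed:
        raise ValueError("score_network requires a fully directed DAG")
    cache = cache or ScoreCache(data, score=score, bge=bge)
    names = list(dag.nodes)
    parent_sets = [
        frozenset(names.index(p) for p in dag.parents(node)) for node in names
    ]
    return cache.total(parent_sets)
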