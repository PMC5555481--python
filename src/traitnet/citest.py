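"""Marginal and conditional independence tests for Gaussian networks.

All four variants used by the constraint-based learner are built on the
partial correlation r of x and y given a conditioning set Z (computed by
regressing Z out of both variables):

* ``pearson_exact_t``            — exact Student t: t = r·√((n−|Z|−2)/(1−r²)),
                                   two-sided on n−|Z|−2 degrees of freedom;
* ``mutual_information_chi2``    — the Gaussian mutual-information statistic
                                   G² = −n·ln(1−r²) against χ²₁;
* ``pearson_permutation`` and ``mutual_information_permutation`` — Monte
  Carlo permutation tests: x's values are permuted (Z fixed) and the
  p-value is (1 + #{|stat_perm| ≥ |stat_obs|}) / (1 + n_permutations),
  never exactly zero by the +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["CITestConfig", "CITestResult", "ci_test", "partial_correlation"]

STATISTICS = (
    "pearson_exact_t",
    "pearson_permutation",
    "mutual_information_chi2",
    "mutual_information_permutation",
)


@dataclass
class CITestConfig:
    statistic: str = "mutual_information_chi2"
    alpha: float = 0.01
    n_permutations: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}; choose from {STATISTICS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if "permutation" in self.statistic and self.n_permutations < 1:
            raise ValueError("permutation tests need n_permutations >= 1")


@dataclass
class CITestResult:
    statistic: float
    p_value: float
    partial_corr: float
    df: int


def partial_correlation(
    data: np.ndarray, x: int, y: int, Z: Sequence[int]
) -> float:
    """Sample partial correlation of columns x and y given columns Z."""
    xv = data[:, x]
    yv = data[:, y]
    if Z:
        A = np.column_stack([np.ones(data.shape[0]), data[:, list(Z)]])
        xv = xv - A @ np.linalg.lstsq(A, xv, rcond=None)[0]
        yv = yv - A @ np.linalg.lstsq(A, yv, rcond=None)[0]
    else:
        xv = xv - xv.mean()
        yv = yv - yv.mean()
    denom = np.sqrt(xv @ xv) * np.sqrt(yv @ yv)
    if denom == 0:
        raise ValueError("constant column in partial-correlation computation")
    return float(np.clip((xv @ yv) / denom, -1.0, 1.0))


def _statistic(r: float, n: int, k: int, kind: str) -> float:
    if kind.startswith("pearson"):
        df = n - k - 2
        if abs(r) >= 1.0:
            return np.inf if r > 0 else -np.inf
        return r * np.sqrt(df / (1.0 - r * r))
    # mutual information (Gaussian): G² = −n·ln(1−r²)
    if abs(r) >= 1.0:
        return np.inf
    return -n * np.log1p(-r * r)


def ci_test(
    data: np.ndarray,
    x: int,
    y: int,
    Z: Sequence[int] = (),
    config: CITestConfig | None = None,
) -> CITestResult:
    """Test independence of columns x and y given Z; see module docstring."""
    config = config or CITestConfig()
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    Z = list(Z)
    if x == y:
        raise ValueError("x and y must differ")
    if x in Z or y in Z:
        raise ValueError("x and y cannot appear in the conditioning set")
    if len(Z) > n - 3:
        raise ValueError(f"conditioning set of size {len(Z)} too large for n={n}")

    r = partial_correlation(data, x, y, Z)
    k = len(Z)
    stat = _statistic(r, n, k, config.statistic)
    df = n - k - 2

    if config.statistic == "pearson_exact_t":
        if not np.isfinite(stat):
            p = 0.0
        else:
            p = 2.0 * stats.t.sf(abs(stat), df)
    elif config.statistic == "mutual_information_chi2":
        p = 0.0 if not np.isfinite(stat) else float(stats.chi2.sf(stat, 1))
    else:  # permutation variants
        if not np.isfinite(stat):
            p = 0.0
        else:
            rng = np.random.default_rng(config.seed)
            xcol = data[:, x]
            perm_data = data.copy()
            hits = 0
            for _ in range(config.n_permutations):
                perm_data[:, x] = rng.permutation(xcol)
                rp = partial_correlation(perm_data, x, y, Z)
                sp = _statistic(rp, n, k, config.statistic)
                if abs(sp) >= abs(stat):
                    hits += 1
            p = (1.0 + hits) / (1.0 + config.n_permutations)
    return CITestResult(statistic=float(stat), p_value=float(p), partial_corr=r, df=df)
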