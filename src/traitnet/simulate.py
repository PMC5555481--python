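"""Synthetic doubled-haploid panels with known genomic and residual networks.

The generator emulates a plant-breeding diversity panel: ~10 biparental
families of fully homozygous doubled-haploid (DH) lines genotyped at
biallelic markers (codes 0/2), a realized kinship matrix of simple-matching
coefficients, and d traits whose genomic and residual components follow
known recursive structure matrices.  Because the true structures (and the
covariance matrices they imply) are stored alongside the data, every
downstream stage — decomposition, decorrelation, structure learning, SEM —
can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MarkerMatrix",
    "SyntheticTruth",
    "TraitPanel",
    "simulate_markers",
    "kinship_from_markers",
    "simulate_panel",
    "standardize_panel",
]


@dataclass
class MarkerMatrix:
    """Biallelic homozygous genotypes coded {0, 2} for DH lines."""

    values: np.ndarray  # (n_lines, n_markers) int
    line_ids: list[str]
    family_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        codes = np.unique(self.values)
        if not np.all(np.isin(codes, (0, 2))):
            raise ValueError(f"DH marker codes must be in {{0, 2}}; saw {codes}")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class SyntheticTruth:
    """Ground-truth recursive structures generating a synthetic panel.

    ``lambda_u`` / ``lambda_e`` are strictly lower-triangular d×d structure
    matrices of the genomic and residual components; ``psi_u`` / ``psi_e``
    their diagonal innovation variances; ``mu`` the trait intercepts.  The
    covariance matrices they imply, (I−Λ)⁻¹ diag(Ψ) (I−Λ)⁻ᵀ, are exposed as
    ``implied_G`` and ``implied_R``.
    """

    lambda_u: np.ndarray
    lambda_e: np.ndarray
    psi_u: np.ndarray
    psi_e: np.ndarray
    mu: np.ndarray
    seed: int = 0
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lambda_u = np.asarray(self.lambda_u, dtype=float)
        self.lambda_e = np.asarray(self.lambda_e, dtype=float)
        self.psi_u = np.asarray(self.psi_u, dtype=float)
        self.psi_e = np.asarray(self.psi_e, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        d = self.d
        for name, lam in (("lambda_u", self.lambda_u), ("lambda_e", self.lambda_e)):
            if lam.shape != (d, d):
                raise ValueError(f"{name} must be {d}x{d}")
            if np.any(np.triu(lam) != 0):
                raise ValueError(f"{name} must be strictly lower triangular")
        if np.any(self.psi_u <= 0) or np.any(self.psi_e <= 0):
            raise ValueError("innovation variances must be positive")
        if not self.trait_names:
            self.trait_names = [f"T{k + 1}" for k in range(d)]

    @property
    def d(self) -> int:
        return len(self.mu)

    @property
    def implied_G(self) -> np.ndarray:
        return _structured_cov(self.lambda_u, self.psi_u)

    @property
    def implied_R(self) -> np.ndarray:
        return _structured_cov(self.lambda_e, self.psi_e)

    def to_yaml(self, path) -> None:
        payload = {
            "lambda_u": self.lambda_u.tolist(),
            "lambda_e": self.lambda_e.tolist(),
            "psi_u": self.psi_u.tolist(),
            "psi_e": self.psi_e.tolist(),
            "mu": self.mu.tolist(),
            "seed": int(self.seed),
            "trait_names": list(self.trait_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            lambda_u=np.array(payload["lambda_u"]),
            lambda_e=np.array(payload["lambda_e"]),
            psi_u=np.array(payload["psi_u"]),
            psi_e=np.array(payload["psi_e"]),
            mu=np.array(payload["mu"]),
            seed=payload.get("seed", 0),
            trait_names=payload.get("trait_names", []),
        )


def _structured_cov(lam: np.ndarray, psi: np.ndarray) -> np.ndarray:
    d = lam.shape[0]
    binv = np.linalg.inv(np.eye(d) - lam)
    cov = binv @ np.diag(psi) @ binv.T
    return (cov + cov.T) / 2.0


@dataclass
class TraitPanel:
    """n×d table of trait values with genotype and family labels.

    ``true_u`` / ``true_e`` hold the simulated genomic and residual
    components when the panel came from :func:`simulate_panel`; they are
    None for panels loaded from measured data.
    """

    values: np.ndarray  # (n, d)
    trait_names: list[str]
    genotype_ids: list[str]
    family_ids: list[str]
    standardized: bool = False
    true_u: np.ndarray | None = None
    true_e: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genotypes x traits)")
        if self.values.shape[1] != len(self.trait_names):
            raise ValueError("trait_names length must match number of columns")
        if self.values.shape[0] != len(self.genotype_ids):
            raise ValueError("genotype_ids length must match number of rows")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "family_id", self.family_ids)
        df.insert(0, "genotype_id", self.genotype_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, standardized: bool = False) -> "TraitPanel":
        df = pd.read_csv(path)
        meta = [c for c in ("genotype_id", "family_id") if c in df.columns]
        traits = [c for c in df.columns if c not in meta]
        return cls(
            values=df[traits].to_numpy(float),
            trait_names=traits,
            genotype_ids=[str(g) for g in df.get("genotype_id", df.index)],
            family_ids=[str(f) for f in df.get("family_id", ["F1"] * len(df))],
            standardized=standardized,
        )


def simulate_markers(
    n_lines: int, n_markers: int, n_families: int, seed: int
) -> MarkerMatrix:
    """Simulate homozygous marker genotypes for a multi-family DH panel.

    Family-level allele frequencies are drawn from Beta(2, 2) and line
    genotypes Bernoulli within each family, which produces the
    block-structured kinship such panels exhibit (elevated within-family
    allele sharing) without modeling meiosis.  Monomorphic markers are
    dropped, mirroring the usual polymorphism filter.

    Raises ``ValueError`` if more than half of the simulated markers are
    monomorphic after filtering (a sign the allele-frequency settings are
    degenerate for this panel size).
    """
    if min(n_lines, n_markers, n_families) < 1:
        raise ValueError("n_lines, n_markers and n_families must all be >= 1")
    if n_families > n_lines:
        raise ValueError("cannot have more families than lines")
    rng = np.random.default_rng(seed)
    fam_sizes = np.full(n_families, n_lines // n_families)
    fam_sizes[: n_lines % n_families] += 1
    fam_freq = rng.beta(2.0, 2.0, size=(n_families, n_markers))
    blocks, families = [], []
    for f, size in enumerate(fam_sizes):
        blocks.append(rng.random((size, n_markers)) < fam_freq[f])
        families += [f"F{f + 1}"] * int(size)
    geno = 2 * np.concatenate(blocks).astype(np.int8)
    poly = (geno.min(axis=0) == 0) & (geno.max(axis=0) == 2)
    n_dropped = int(n_markers - poly.sum())
    if poly.sum() == 0:
        raise ValueError(
            "all markers monomorphic after filtering; Beta(2,2) family "
            f"frequencies with {n_lines} lines in {n_families} families "
            "cannot sustain polymorphism at this size"
        )
    if n_dropped > n_markers / 2:
        raise ValueError(
            f"{n_dropped}/{n_markers} markers monomorphic after filtering "
            "(>50%); Beta(2,2) family allele frequencies are degenerate for "
            f"{n_lines} lines in {n_families} families"
        )
    return MarkerMatrix(
        values=geno[:, poly],
        line_ids=[f"L{i + 1:04d}" for i in range(n_lines)],
        family_ids=families,
    )


def kinship_from_markers(markers: MarkerMatrix) -> np.ndarray:
    """Realized kinship as simple-matching coefficients.

    K[i, j] is the proportion of markers at which lines i and j carry the
    same genotype code; the diagonal is exactly 1.  For homozygous lines
    coded 0/2 this is computed from the 0/1 indicator matrix X as
    (X Xᵀ + (1−X)(1−X)ᵀ) / m.
    """
    if markers.n_markers < 2:
        raise ValueError("need at least 2 polymorphic markers for kinship")
    x = (markers.values == 2).astype(float)
    m = markers.n_markers
    k = (x @ x.T + (1.0 - x) @ (1.0 - x).T) / m
    np.fill_diagonal(k, 1.0)
    return (k + k.T) / 2.0


def kinship_to_csv(K: np.ndarray, genotype_ids: list[str], path) -> None:
    pd.DataFrame(K, index=genotype_ids, columns=genotype_ids).to_csv(path)


def kinship_from_csv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(float), [str(g) for g in df.index]


def simulate_panel(
    truth: SyntheticTruth,
    kinship: np.ndarray,
    n: int | None = None,
    seed: int | None = None,
    genotype_ids: list[str] | None = None,
    family_ids: list[str] | None = None,
    standardize: bool = False,
) -> TraitPanel:
    """Draw a trait panel y = μ⊗1 + u + e from known recursive structures.

    The genomic component has vec-covariance G⊗K (correlated across
    genotypes through the Cholesky factor of K); the residual component has
    R⊗I.  G and R are the covariances implied by the truth's structure
    matrices.  The realized u and e are stored on the panel for recovery
    testing.
    """
    kinship = np.asarray(kinship, dtype=float)
    n_k = kinship.shape[0]
    if n is None:
        n = n_k
    if n != n_k:
        raise ValueError(f"kinship is {n_k}x{n_k} but n={n}")
    if seed is None:
        seed = truth.seed
    d = truth.d
    from traitnet.transform import cholesky_factor

    transform = cholesky_factor(kinship)
    # substreams: genomic and residual innovations drawn independently
    ss_u, ss_e = np.random.SeedSequence(seed).spawn(2)
    rng_u = np.random.default_rng(ss_u)
    rng_e = np.random.default_rng(ss_e)

    b_u = np.linalg.inv(np.eye(d) - truth.lambda_u) @ np.diag(np.sqrt(truth.psi_u))
    b_e = np.linalg.inv(np.eye(d) - truth.lambda_e) @ np.diag(np.sqrt(truth.psi_e))
    u = transform.L @ rng_u.standard_normal((n, d)) @ b_u.T
    e = rng_e.standard_normal((n, d)) @ b_e.T
    y = truth.mu[None, :] + u + e

    if genotype_ids is None:
        genotype_ids = [f"L{i + 1:04d}" for i in range(n)]
    if family_ids is None:
        family_ids = ["F1"] * n
    panel = TraitPanel(
        values=y,
        trait_names=list(truth.trait_names),
        genotype_ids=list(genotype_ids),
        family_ids=list(family_ids),
        true_u=u,
        true_e=e,
    )
    return standardize_panel(panel) if standardize else panel


def standardize_panel(panel: TraitPanel) -> TraitPanel:
    """Family-mean center each trait, then scale to unit sample variance.

    Centering within family removes population (family) effects so that the
    analysis focuses on within-family allelic variation; scaling uses the
    overall sample standard deviation (ddof=1) of the centered column.
    Idempotent up to floating-point round-off.
    """
    values = panel.values.copy()
    fam = np.asarray(panel.family_ids)
    for f in np.unique(fam):
        rows = fam == f
        values[rows] -= values[rows].mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [panel.trait_names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance trait(s) after centering: {bad}")
    values /= sd
    return TraitPanel(
        values=values,
        trait_names=list(panel.trait_names),
        genotype_ids=list(panel.genotype_ids),
        family_ids=list(panel.family_ids),
        standardized=True,
        true_u=panel.true_u,
        true_e=panel.true_e,
    )
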