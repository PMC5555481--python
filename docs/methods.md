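# Methods

## Model

Phenotypes of n genotypes on d traits are stacked trait-major into
y = μ⊗1ₙ + u + e with

    (u, e) ~ N( 0, blockdiag(G⊗K, R⊗Iₙ) ),

where K is a realized kinship matrix, G the between-trait genomic
covariance, and R the between-trait residual covariance. μ carries a flat
prior; G and R carry independent inverse-Wishart priors under the
parametrization with density ∝ |G|^−(ν+d+1)/2 exp(−tr(ΣG⁻¹)/2), whose mode
is Σ/(ν+d+1) (identical to `scipy.stats.invwishart`). The defaults ν = 8,
Σ = 7·I at d = 5 put the prior mode of every trait's genomic and residual
variance at 0.5 — the natural split for traits standardized to unit
variance — while staying weakly informative. The univariate special case
is a scaled-inverse-χ² prior with mode S/(ν+2); the default (df 4, scale 3,
mode 0.5) is used for the single-trait baseline and the SEM innovation
variances so the two model families share their marginal trait-variance
prior.

## Gibbs sampler

The full conditionals are standard: μ | · ~ N(rowmean(Y−U), R/n);
G | u ~ W⁻¹(Σ_G + UᵀK⁻¹U, ν_G + n); R | e ~ W⁻¹(Σ_R + EᵀE, ν_R + n); and u
is multivariate Gaussian. Two exact reparametrizations make the u-update
O(n·d²) per sweep rather than an nd×nd solve:

* the eigendecomposition K = QDQᵀ (computed once) decouples genotypes —
  rows of QᵀU are independent with covariance dᵢG;
* per sweep, a simultaneous diagonalization A with A G Aᵀ = W (diagonal)
  and A R Aᵀ = I turns each rotated row's posterior into elementwise
  shrinkage w·dᵢ/(w·dᵢ+1) of the rotated data.

Both steps are exact; no approximation is involved. Residuals are defined
by subtraction, so E = Y − 1μᵀ − U holds at every draw and at the posterior
mean to machine precision. Kinship matrices that fail a Cholesky test are
repaired with a ridge δ·I, δ doubling from 1e−8 up to a cap of 1e−2
(realized kinship, unlike pedigree kinship, is not guaranteed positive
definite); the ridge actually used is recorded.

Chain defaults mirror a production run (burn-in 30 000, 300 000 draws,
thinning 2). The test suite and examples use scaled-down chains (burn-in
500–1000, 4000–6000 draws), sized so the whole suite runs in a few minutes
on one CPU; posterior-mean Monte-Carlo error at those lengths is tracked
with a batch-means estimator (`traitnet.assess.mcse`).

Posterior trait correlations are computed per retained draw and then
averaged, with SDs across draws (denominator n−1). The alternative —
correlating the averaged covariance — gives nearly identical point
estimates but no spread; the per-draw route is the one that treats the
correlation as the estimand.

## Decorrelation

Bayesian-network learning assumes independent observations. Residuals are
independent across genotypes by model assumption and pass through
untouched; genomic values are not, so u* = (I_d⊗L⁻¹)u with K = LLᵀ is
applied column-wise by forward substitution (L is never inverted). Then
Var(u*) = G⊗Iₙ: genotypes decouple, the between-trait covariance G is
intact.

## Structure learning

Six settings, all assuming a Gaussian network over the d component
columns:

* **GS 1–4** — Grow-Shrink with four conditional-independence tests built
  on the partial correlation r of x, y given Z: exact Student t
  (t = r√((n−|Z|−2)/(1−r²))), Gaussian mutual information
  (G² = −n·ln(1−r²) vs χ²₁), and Monte-Carlo permutation versions of both
  (default 450 permutations; p = (1+hits)/(1+B), never exactly zero).
  Default α = 0.01. Markov blankets are estimated by grow/shrink phases
  with an AND-symmetry correction, resolved to direct neighbours by
  testing against all subsets of the smaller blanket, v-structures are
  oriented from recorded separating sets, and Meek's rules close the
  orientation. Orientations that would close a directed cycle (possible
  when noisy tests produce contradictory colliders) are skipped — the edge
  stays undirected. Output may be partially directed (a CPDAG).
* **TABU 1–2** — tabu search over DAGs (add/delete/reverse moves, tabu
  list of reversals, aspiration on the best score, stop after tabu-length
  non-improving moves) under BIC or BGe. BIC per node is the maximized
  Gaussian regression log-likelihood minus (|pa|+2)/2·ln n (coefficients +
  intercept + residual variance); BGe is the Normal-Wishart marginal
  likelihood with imaginary sample sizes α_μ = 1 and α_w = d+2, prior mean
  at the sample mean and prior scale t·I with t = α_μ(α_w−d−1)/(α_μ+1) —
  common reference defaults, configurable. Both scores are computed from
  the sample mean and centred scatter only and are score-equivalent
  (verified by exhaustive enumeration in the tests). The exact BGe
  hyper-parameters of any particular historical analysis are not
  published; the defaults above are the package's own choice.

**Bootstrap averaging.** Genotypes are resampled jointly across columns;
the learner runs per replicate (default B = 500); each unordered pair gets
a *strength* (fraction of replicate networks containing it, counting
either direction) and each orientation a *direction fraction* (undirected
occurrences count ½ each way). The significance threshold treats
strengths as noisy observations of ideal values in {0,1}: the flat level c
on [0,1) minimizing the L1 distance to the empirical strength CDF is the
length-weighted median of the CDF's levels, and edges strictly above the
c-quantile are kept. Kept edges are oriented by majority direction (exact
ties toward the earlier trait in canonical order); cycles arising from
combining majorities are broken by removing the weakest arc — both
deterministic and logged.

**Structure matrices.** Each arc parent→child becomes a free coefficient
at (child row, parent column) of Λ; a topological order makes the pattern
strictly lower triangular. A partially directed result is first replaced
by a deterministic equivalence-class representative (the consistent
extension whose sorted arc list is lexicographically first); any member of
the class yields the same fit metrics, so the choice only fixes which
coefficients are reported.

## Structural equation models

A structured component replaces its covariance by
G* = (I−Λ)⁻¹diag(Ψ)(I−Λ)⁻ᵀ — positive definite for any finite coefficients
and positive Ψ. Free coefficients carry N(0, 6.3) priors on the genomic
side and N(0, 0.07) on the residual side: on standardized traits the
largest genomic (residual) covariance components such models produce are
about 5.0 (0.52), and a zero-mean normal prior covers those within two SDs
once its variance exceeds (5/2)² = 6.25 ((0.52/2)² = 0.0676). Innovation
variances carry scaled-inverse-χ²(4, 3) priors (mode 0.5, matching the
MTM's marginal trait-variance prior). The model is homoscedastic: one Ψ
for all genotypes, no feedback loops.

The Gibbs cycle extends the MTM sampler: per sweep, the current u is
transformed to u* with the *fixed* Cholesky factor of the input kinship,
each child's free coefficients are drawn from their conjugate Gaussian
regression conditionals given Ψ, Ψ from its scaled-inverse-χ² conditionals
given Λ, and the rebuilt G* (R*) replaces G (R) in the u, e, μ updates.
This conditioning scheme — Λ, Ψ | u rather than any collapsed variant — is
one valid Gibbs realization of the hierarchy; it keeps every full
conditional in closed form. Structural zeros are never sampled and remain
exactly zero in all summaries. Variants with only the genomic, only the
residual, or both components structured are selected by `SEMSpec`.

Parameter counting is symbolic: connections are the free entries of Λ;
nonnull covariance parameters are the structurally nonzero entries of G*
(upper triangle + diagonal), obtained from the reachability closure of the
pattern — traits share a nonzero covariance iff they share an ancestor. A
fully recursive structure at d = 5 gives 10 connections and 15 nonnull
parameters per component, the same count as the unstructured matrix.

## Model assessment

* **DIC** uses the conditional deviance −2·log N(y | μ+u, R⊗I) per draw:
  p_D = mean(D) − D(posterior means), DIC = mean(D) + p_D. The conditional
  (rather than marginal) deviance makes p_D scale with the dimension of
  the genomic-value vector, which is the regime in which these models are
  usually compared.
* **Marginal log-likelihood** is a plug-in evaluation of
  log N(y | μ̂⊗1, Ĝ⊗K + R̂⊗I) at posterior means via the eigendecomposition
  of K. This is *not* a fully Bayesian evidence estimate; it is
  deterministic, cheap, and model *differences* on the same data are the
  quantity reported.
* **Predictive ability**: replicated k-fold cross-validation (default 10×5)
  with fold assignments drawn once per replicate (uniform, seeded, sizes
  differing by at most one) and shared bit-exactly by every model,
  including the single-trait baseline. Each model refits on the training
  genotypes; held-out genotypes are predicted by the conditional
  multivariate normal given the training phenotypes of all traits with
  plug-in posterior-mean covariances and the cross-kinship block — this
  joint conditioning is what gives multi-trait models their advantage.
  Ability is the per-trait test-set correlation, averaged over splits.

The comparison table reports ΔDIC, Δp_D, ΔlogL against the unstructured
MTM plus connection/nonnull counts and mean predictive ability, sorted by
DIC.

## Synthetic panels

The generator emulates a doubled-haploid diversity panel: family-level
allele frequencies drawn from Beta(2, 2), line genotypes Bernoulli within
family, markers coded {0, 2} (DH lines are fully homozygous), monomorphic
markers dropped (error if more than half vanish). Kinship is the raw
simple-matching proportion; any affine rescaling of K would only rescale
the genomic variance estimates, so no rescaling is applied. Trait panels
draw u through the Cholesky factor of K and e independently, each via
(I−Λ)⁻¹ applied to scaled innovations, from known strictly-lower-triangular
Λᵤ, Λₑ with diagonal Ψ; the realized u and e are stored for recovery
testing. Standardization follows the field convention: family-mean
centring first, then division by the overall sample SD (idempotent). One
master seed spawns independent substreams per stage.

Default study conditions: two panels of ~800 lines in 10 families, ~1500–
2000 markers, d = 5 traits, sparse truths with 3 arcs per component
(coefficients 0.7 genomic, 0.6 residual, Ψ = 0.5 — heritabilities around
0.5, the regime the methodology targets). What the generator does *not*
emulate: meiosis/recombination and linkage maps, genotype-by-environment
structure, testcross evaluation, missing data. Passing tests therefore
demonstrate correctness of the machinery under the stated Gaussian
recursive model, not robustness to those real-data features.

## Numerical choices and known limitations

* Inverse-Wishart draws with a numerically non-PD scale get a relative
  1e−8 jitter; divergent chains abort with the iteration index.
* The tabu tie-break and the averaging tie-breaks are deterministic under
  canonical trait order, so all learners are reproducible bit-for-bit
  given seeds.
* Constraint-based edge sets are *not* monotone in α (a property of
  Grow-Shrink, not of this implementation); determinism per α is the
  guarantee tested.
* Score-based settings overfit by construction at moderate n: BIC's
  ln(n)/2 penalty corresponds to a ≈2.6σ cut on a null partial
  correlation, so the score-optimal DAG carries a borderline extra edge in
  a nontrivial fraction of data realizations, and such a data-level fluke
  is stable across bootstrap replicates (strengths 0.5–0.7) and survives
  any empirical strength threshold. Constraint-based settings at α = 0.01
  are cleaner. This asymmetry is visible in the test suite's recovery
  rates and mirrors the general experience that score-based learners
  select more edges.
* The saturated (fully recursive) SEM is a reparametrization of the MTM
  with a *different* prior (normal coefficients + scaled-inverse-χ²
  innovations vs inverse-Wishart); the two posteriors agree within about
  one posterior SD at n = 800 but not within Monte-Carlo error — the
  residual gap is prior-driven O(1/n), not a sampler defect.
* The plug-in marginal likelihood and the conditional-deviance DIC are
  explicit substitutes for estimators that have no single canonical
  definition in this model family; both are deterministic given the
  posterior means and clearly labelled in the output.
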