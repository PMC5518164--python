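# Methods

## Model

A quantitative trait `y` is influenced by an additive polygenic
background and one biallelic major gene with reference-allele
frequency `p` (`q = 1 − p`) in the base population and substitution
effect `α` (trait units per allele copy).  Writing `z` for the gene
content (0/1/2 copies) and centring at the base mean `2p`, the total
additive value decomposes exactly as `u_y = ε + (z − 2p)α` with
`Var(ε) = A σ²ε`, where `A` is the numerator relationship matrix.
Gene content itself behaves as a quantitative trait with heritability
one: `Var(u_z) = A·2pq` and, because `Cov(ε, z) = 0` in the base
population, `Cov(u_y, u_z) = A·2pq·α`.  Stacking the two "traits"
gives the per-animal genetic covariance

    G0 = [[σ²ε + 2pq α², 2pq α],
          [2pq α,         2pq ]],      Cov(u) = G0 ⊗ A,

with the closed-form inverse `[[1/σ²ε, −α/σ²ε], [−α/σ²ε,
(σ²ε + 2pq α²)/(2pq σ²ε)]]`.  Records enter Henderson's mixed-model
equations with independent residuals for the two traits; the
gene-content residual `σ²ez` is a small nominal constant (default
0.001 in absolute units) whose only purpose is to keep the equations
well posed — at that value the "heritability" of observed content is
2pq/(2pq + σ²ez) ≈ 0.998 rather than exactly 1.  Observed genotypes
are therefore reproduced essentially exactly, while non-genotyped
animals receive fractional expected contents informed by *both* the
genotypes and the phenotypes of their relatives; that use of phenotype
information is what distinguishes the joint analysis from imputation
pipelines.  Missing records are handled by dropping rows of the
incidence matrices, which is valid when the missingness pattern does
not depend on the unobserved values (genotyping the sick would violate
this).

For a gene with n alleles, the vector of per-allele contents is twice
a multinomial draw, with singular covariance `2(diag(p) − pp′)`; one
(by convention the last listed) allele is dropped as reference, its
effect absorbed into the model mean, and `G0` becomes `n × n` with the
leading `(n−1) × (n−1)` content block.

For an X-linked gene the Kronecker structure breaks because X-linked
contents follow their own relationship matrix `S` (males carry one
maternal copy; `Cov(z_i, z_j) = S_ij · 2pq`, founder females
`S_ii = 1`, any male `S_ii = 0.5`).  `xlinked_gcmtblup` uses the exact
reparameterization `u_y = ε + u_z α` with independent `ε ~ A σ²ε` and
`u_z ~ S·2pq`, which yields ordinary mixed-model equations; gene
parameters must be supplied (no X-linked REML).  The `S` recursion was
validated against Monte-Carlo gene dropping (the defining object).

## Estimation

`GeneContentREML` maximizes the restricted likelihood over
`(G0, σ²ey)` with `σ²ez` held fixed: the content residual sits on the
boundary of the parameter space (content heritability is one by
construction) and is not estimable.  Updates are EM-type, built from
the mixed-model solutions plus a *selected inverse* of the sparse
coefficient matrix (Takahashi recurrences over the symbolic pattern of
an LDL' factorization under a minimum-degree ordering; entries of
C⁻¹ are needed at the sparsity pattern of A⁻¹ for the genetic
quadratic forms and at the record incidences for prediction-error
variances).  Plain EM is available (`accelerate="none"`), but on the
study's missingness structure — genotyped animals without phenotypes
and vice versa — the likelihood is nearly flat and plain EM needs
thousands of iterations.  The default is therefore parameter-expanded
EM: the breeding values are expanded as `u = (Λ ⊗ I)v`, the M-step
estimates `Λ` by a small weighted regression of each trait's records
on the current BLUPs of all traits (fixed effects kept integrated out,
as REML requires), and the reduction `G0 ← Λ (S/N) Λ′` follows.  PX-EM
retains EM's monotone restricted log-likelihood — asserted on every
path in the tests — and was verified to reach the same optimum as
plain EM and as a derivative-free direct maximization of the
restricted likelihood on a common dataset.  Convergence is declared
when the largest relative parameter change drops below `tol`
(default 1e-8, capped at `max_iter` = 1000).

From `Ĝ0`: `α̂ = σ̂_uzy/σ̂²_uz`; `p̂` either from `b̂_z = 2p̂` or from
`σ̂²_uz = 2p̂(1−p̂)` (root ≤ 0.5, orientation resolved against the
mean-based estimate).  The gene effect is tested by a likelihood-ratio
test against a model re-estimated with the trait–content covariance
fixed at zero; since a covariance is unbounded, the statistic is
referred to χ² with one degree of freedom without boundary
corrections (type-I error verified by simulation).  Standard errors
use the observed information obtained by central finite differences of
the restricted log-likelihood at convergence (step 1e-4 relative);
the delta method converts the component covariance into a confidence
interval for the ratio `α̂`.  Likelihood constants are included so
statistics are comparable across models.

A negative decomposed polygenic variance (`σ̂²uy < σ̂²uz α̂²`) is
reported with a warning, never silently truncated; BLUP refuses a
non-positive-definite `G0`.

## Numerical kernels

* `A⁻¹` by Henderson's rules with Meuwissen–Luo inbreeding (Mendelian
  sampling variances `d_i`), giving `log|A| = Σ log d_i` for the
  likelihood; validated against dense inversion on random pedigrees.
* Mixed-model systems are assembled once as index/value arrays and
  re-valued per REML iterate; equations are ordered fixed effects
  first, then traits within animal (this makes the worked example's
  printed system directly comparable).  Extra categorical fixed
  effects for the trait use treatment coding (level 0 absorbed into
  the general mean).  A fixed effect with no records is pinned to zero
  with a unit diagonal.  Zero-valued coefficients (e.g. the
  trait–content block of the no-covariance model) are kept as
  structural entries because the selected inverse must address those
  positions.
* The factorization is an up-looking sparse LDL' (elimination-tree
  symbolic analysis; numba-compiled) rather than a general LU: LU
  codes prune entries that cancel to exact zero, which silently breaks
  the closure property the Takahashi recurrences rely on.  A symmetric
  minimum-degree ordering is harvested from SuperLU's MMD(A′+A).
* Solvers: direct (LDL') or Jacobi-preconditioned conjugate gradients
  with an explicit relative-residual check.

## Simulator

`simulate_scenario` emulates a progeny-tested population with discrete
cohorts of constant size (exactly half male), only females phenotyped
(cohorts 1 … G−1), Hardy–Weinberg founders and fair meiosis at the
gene, and an infinitesimal polygenic part (offspring = parent average
+ Mendelian sampling `N(0, σ²ε/2)`; no inbreeding adjustment — the
pedigrees are shallow).  Phenotype = `μ + ε + (z − 2p₀)α + e`, so true
breeding values decompose exactly.  Sire selection is a rolling
progeny test: each cohort a set of randomly chosen young "test" males
and the best quarter of the previous test cohort — ranked on their
daughters' mean phenotype — act as sires.  The daughters-per-sire
range (default 10–20) is the binding design constraint: every sire
produces about twice that many offspring, which fixes the number of
sires a cohort can support (≈ N/30 per generation, ≈ 86 at the
full-scale setting, `n_sires` acting only as an upper cap).  The final
cohort — the selection candidates — is sired entirely by repeat
(proven) sires ranked on their phenotyped daughters, as candidates in
a progeny-test scheme are sons of proven bulls; this matters for the
accuracy comparisons, since a candidate's parent-average prediction
leans on its sire's daughter information.
Animals ever used as sires form the genotyped set; final-cohort males
are the selection candidates, genotyped or not per scenario.  The two
stock designs: selected trait with h² = 0.05 and unselected trait with
h² = 0.5, both with half the genetic variance from a p₀ = 0.5 gene
(α = 0.226 and 0.707 at phenotypic variance 1).

What the simulator does *not* reproduce: overlapping herd/year
structures, heterogeneous variances, genotyping errors, linked
markers, and the exact mating design of the original large-scale
study, whose progeny-test details are not fully specified — the
selection criterion used here (daughter-mean ranking, 1-in-4 proven
selection) is this package's own choice.  Passing simulation tests
therefore demonstrate internal consistency of estimator and generator
under ignorable missingness and this selection scheme, not performance
on real data.

## Problem sizes and tolerances

The replicated comparisons are run at 400 animals × 12 cohorts
(acceptance script, 24 replicates; test suite, 6 replicates),
preserving the 10–20 daughters per sire of the full-scale
design so that progeny-test information — the main driver of
prediction accuracy — is comparable.  Replicate spread of effect
estimates scales roughly with the square root of population size, so
reference bands are widened by `sqrt(2600/N)` relative to the
published spreads.  REML runs in the replicated studies use
`tol = 1e-5`, `max_iter = 300` (estimates change by < 1e-3 relative to
`tol = 1e-6`).  At these sizes drift at the gene is substantial
relative to the selection response, and the upward bias of the
imputation pipelines under selection — which re-emerges when the
population is enlarged — is largely buried in replicate noise; the
scaled-down comparisons therefore check the effect-estimate *levels*
within the widened bands and the accuracy *orderings*, which are
structural.  Plain pedigree BLUP's candidate accuracy also sits
slightly below its full-scale value at this population size (about
0.23 rather than 0.30), a scale effect of the small sire cohorts.

## Known limitations

* Single quantitative trait, single gene for REML (the BLUP machinery
  is written for 1 + m contents; multiallelic REML estimates an
  unstructured G0 through the same EM code but has seen less use).
* Iterative peeling is exact only on loop-free pedigrees and
  genotype-only (no trait likelihood in the peeling itself);
  inconsistent genotype configurations raise an error naming the
  animal rather than locating every conflicting trio.
* No Gibbs sampling, no single-step genomic extension, no dominance
  decomposition, no unknown-parent groups or metafounders.
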