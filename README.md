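# gcmtblup

Genetic evaluation of a quantitative trait influenced by polygenes and
a major gene when only part of the population is genotyped.

In pedigreed livestock populations a known major gene (the *DGAT1*
fat-content variant in dairy cattle, prolificacy genes in sheep, casein
variants in goats) should enter the genetic evaluation — but fitting
the genotype as a covariate requires every animal to be genotyped, and
in practice only sires or selection candidates are.  This package
treats **gene content** — the number of copies `z ∈ {0, 1, 2}` of the
reference allele — as a second *trait* correlated with the quantitative
trait `y`.  Because the genetic covariance between the two "traits" is
a simple function of the substitution effect `α` and the base allele
frequency `p`,

```
         ⎡ σ²ε + 2pq·α²   2pq·α ⎤
    G0 = ⎢                      ⎥ ,   Cov(u) = G0 ⊗ A,
         ⎣ 2pq·α          2pq   ⎦
```

standard multi-trait BLUP/REML machinery handles any pattern of
missing genotypes or phenotypes:

* **gene-content multi-trait BLUP** (`GeneContentBLUP`): total breeding
  values `u_y` (major gene included), gene-content breeding values
  `u_z` — i.e. predicted genotypes `ẑ = b_z + u_z` that use the trait
  phenotypes of relatives — and the polygenic part `ε = u_y − u_z α`;
* **gene-content multi-trait REML** (`GeneContentREML`): EM-type
  estimation of `G0` and the residual variance, from which
  `α̂ = cov̂(u_z, u_y)/var̂(u_z)`, a likelihood-ratio test of the gene
  effect (χ², 1 df) and two base-frequency estimators
  (`2p̂ = b̂_z` and `2p̂(1−p̂) = var̂(u_z)`) follow;
* the benchmark two-step pipelines — linear gene-content imputation
  (`GenglerImputation`) or iterative peeling (`IterativePeeling`)
  followed by a fixed-covariate animal model (`CovariateModel`);
* pedigree utilities (numerator relationship matrix, its sparse
  inverse with inbreeding, an X-chromosomal relationship matrix),
  multiallelic covariance structures, a forward simulator of
  progeny-tested populations, and evaluation helpers
  (accuracy = cor(TBV, EBV), dispersion slope = reg. of TBV on EBV).

The estimators follow scikit-learn conventions (`fit`, fitted
attributes with trailing underscores, `get_params`/`set_params`); thin
module-level functions (`gcmtblup`, `gcmtreml`, `gengler_impute`, ...)
wrap them.

## Worked example

The five-animal textbook example — two founders and three full sibs,
phenotypes `(NA, 15, 7, NA, 12)`, genotypes `(AB, NA, NA, BB, AA)`,
`G0 = [[0.05, 0.11], [0.11, 0.5]]`, residual variances `(0.95, 0.001)`:

```python
>>> import numpy as np
>>> from gcmtblup import GeneContentBLUP, table1_fixture
>>> ped, records, g0, resid = table1_fixture()
>>> est = GeneContentBLUP(g0=g0, sigma2_ey=resid.sigma2_ey).fit(ped, records)
>>> np.round(est.solution_, 2)
array([11.42,  1.05, -0.06, -0.05,  0.06,  0.05, -0.11, -0.25,  0.21,
        0.94, -0.22, -1.05])
>>> np.round(est.predict_gene_content(), 2)
array([1.  , 1.11, 0.8 , 2.  , 0.  ])
```

The first two solutions are the trait and gene-content means: `b̂_z =
1.05` estimates twice the base frequency of the B allele.  Predicted
gene contents reproduce the observed genotypes (1, 2, 0) for the three
genotyped animals and give fractional dosages for the two animals known
only through pedigree and phenotype.

A command-line interface covers the same ground on files
(`gcmtblup simulate | blup | reml | impute | experiment | evaluate`;
see `gcmtblup --help`).

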