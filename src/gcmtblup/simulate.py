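"""Forward simulation of a polygenic trait with one biallelic major gene.

The simulator emulates a progeny-tested livestock population: discrete
generations of constant size, only females phenotyped, a limited number
of sires per generation, and selection of sires on the mean phenotype
of their daughters (or random sire choice for an unselected trait).
The major gene segregates by fair meiosis from Hardy-Weinberg founders;
the polygenic part follows the infinitesimal model (offspring value =
parent average + Mendelian sampling with variance ``sigma2_eps / 2``,
no inbreeding adjustment — the pedigrees here are shallow).

Phenotypes are ``mu + eps + (z - 2 p0) alpha + e`` so the total
breeding value decomposes exactly as ``TBV = eps + (z - 2 p0) alpha``.

Two stock configurations reproduce the study designs: a selected trait
of heritability 0.05 and an unselected trait of heritability 0.5, in
both cases with half the genetic variance due to the gene and base
allele frequency 0.5 (hence ``alpha = sqrt(h2/2 * sigmaP2 / (2 p0 q0))``,
0.226 and 0.707 at phenotypic variance 1).

Sire selection works on a rolling progeny test: each generation, half
the sire slots go to randomly chosen young "test" males and half to
"proven" sires — the best of the previous round's test males ranked by
their daughters' mean phenotype.  Family sizes are drawn uniformly in
``daughters_range`` and rescaled so cohorts have the configured size
(about 13 offspring per sire slot at the stock settings).  Animals that
ever serve as sires are the genotyped set; final-generation males are
the selection candidates, genotyped or not depending on the scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genecov import GeneTraitCovariance
from .mme import RecordSet, ResidualSpec
from .pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "ScenarioConfig",
    "SimulatedPopulation",
    "simulate_scenario",
    "low_h2_scenario",
    "high_h2_scenario",
    "table1_fixture",
    "write_population",
]


@dataclass
class ScenarioConfig:
    """Simulation settings; defaults follow the low-heritability design."""

    n_generations: int = 11
    animals_per_generation: int = 2600
    n_sires: int = 200
    daughters_range: tuple = (10, 20)
    h2_total: float = 0.05
    gene_variance_fraction: float = 0.5
    p0: float = 0.5
    phenotypic_variance: float = 1.0
    mu: float = 0.0
    selection: str = "progeny_test"  # or "none"
    genotype_sires: bool = True
    genotype_candidates: bool = True
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.gene_variance_fraction <= 1.0:
            raise ValueError("gene_variance_fraction must be in [0, 1]")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be in (0, 1)")
        if self.h2_total < 0 or self.phenotypic_variance <= 0:
            raise ValueError("variances must be nonnegative")
        if self.n_sires > self.animals_per_generation // 2:
            raise ValueError("more sire slots than males per generation")
        if self.selection not in ("progeny_test", "none"):
            raise ValueError("selection must be 'progeny_test' or 'none'")

    # -- derived quantities -------------------------------------------------

    @property
    def het0(self) -> float:
        return 2.0 * self.p0 * (1.0 - self.p0)

    @property
    def sigma2_gene(self) -> float:
        return self.h2_total * self.gene_variance_fraction * self.phenotypic_variance

    @property
    def alpha(self) -> float:
        """Substitution effect implied by the variance split."""
        return float(np.sqrt(self.sigma2_gene / self.het0))

    @property
    def sigma2_eps(self) -> float:
        return self.h2_total * (1.0 - self.gene_variance_fraction) * self.phenotypic_variance

    @property
    def sigma2_e(self) -> float:
        return self.phenotypic_variance * (1.0 - self.h2_total)

    def g0(self) -> GeneTraitCovariance:
        h = self.het0
        a = self.alpha
        return GeneTraitCovariance(
            [[self.sigma2_eps + h * a**2, h * a], [h * a, h]]
        )

    def residuals(self, sigma2_ez: float = 0.001) -> ResidualSpec:
        return ResidualSpec(self.sigma2_e, sigma2_ez)


def low_h2_scenario(**overrides) -> ScenarioConfig:
    """Selected, lowly heritable trait (h2 = 0.05, half genic)."""
    return ScenarioConfig(**overrides)


def high_h2_scenario(**overrides) -> ScenarioConfig:
    """Unselected, highly heritable trait (h2 = 0.5, half genic)."""
    overrides.setdefault("h2_total", 0.5)
    overrides.setdefault("selection", "none")
    return ScenarioConfig(**overrides)


@dataclass
class SimulatedPopulation:
    """Simulated pedigree with genotypes, breeding values and phenotypes."""

    config: ScenarioConfig
    pedigree: Pedigree
    alleles: np.ndarray  # (n, 2) 0/1; 1 = reference (B) allele
    polygenic: np.ndarray
    phenotype: np.ndarray  # NaN where not recorded
    genotyped: np.ndarray  # bool: in the genotyped set (sires)
    sire_usage: np.ndarray  # bool: ever used as sire

    @property
    def z(self) -> np.ndarray:
        return self.alleles.sum(axis=1).astype(float)

    @property
    def tbv(self) -> np.ndarray:
        cfg = self.config
        return self.polygenic + (self.z - 2.0 * cfg.p0) * cfg.alpha

    @property
    def tbv_gene(self) -> np.ndarray:
        """True (centred) gene content, the target of content prediction."""
        return self.z - 2.0 * self.config.p0

    @property
    def sex(self) -> np.ndarray:
        return self.pedigree.sex

    @property
    def generation(self) -> np.ndarray:
        return self.pedigree.generation

    def candidates(self) -> np.ndarray:
        """Final-generation males (the selection candidates)."""
        return np.flatnonzero(
            (self.generation == self.config.n_generations) & (self.sex == MALE)
        )

    def phenotyped_females(self) -> np.ndarray:
        """Females of the last phenotyped generation."""
        return np.flatnonzero(
            (self.generation == self.config.n_generations - 1)
            & (self.sex == FEMALE)
        )

    def records(self, include_candidate_genotypes: bool | None = None) -> RecordSet:
        """Observed data as a :class:`RecordSet`.

        ``include_candidate_genotypes`` overrides the configured
        genotyping of final-generation candidates.
        """
        gt = self.genotyped.copy()
        cand = self.candidates()
        if include_candidate_genotypes is None:
            include_candidate_genotypes = self.config.genotype_candidates
        if include_candidate_genotypes:
            gt[cand] = True
        else:
            gt[cand] = self.sire_usage[cand]
        z = np.where(gt, self.z, np.nan)
        return RecordSet(y=self.phenotype.copy(), z=z)


def simulate_scenario(cfg: ScenarioConfig, seed=None) -> SimulatedPopulation:
    """Run the forward simulation (see module docstring)."""
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    N = cfg.animals_per_generation
    G = cfg.n_generations
    s_eps = np.sqrt(cfg.sigma2_eps)
    s_ms = np.sqrt(cfg.sigma2_eps / 2.0)
    s_e = np.sqrt(cfg.sigma2_e)

    sires: list[int] = []
    dams: list[int] = []
    sex: list[str] = []
    gen: list[int] = []
    alleles: list[np.ndarray] = []
    poly: list[float] = []
    pheno: list[float] = []

    def add_animal(s, d, g, sx, al, pg):
        sires.append(s)
        dams.append(d)
        gen.append(g)
        sex.append(sx)
        alleles.append(al)
        poly.append(pg)
        recorded = sx == FEMALE and 1 <= g <= G - 1
        pheno.append(
            cfg.mu + pg + (al.sum() - 2 * cfg.p0) * cfg.alpha + rng.normal(0, s_e)
            if recorded
            else np.nan
        )
        return len(sires) - 1

    def cohort_sexes(size):
        # exactly half of each cohort is male (odd animal female)
        sx = np.array([MALE] * (size // 2) + [FEMALE] * (size - size // 2))
        rng.shuffle(sx)
        return sx

    # founders (generation 0): Hardy-Weinberg, unphenotyped
    for sx in cohort_sexes(N):
        add_animal(
            -1, -1, 0, sx,
            (rng.random(2) < cfg.p0).astype(np.int8),
            rng.normal(0.0, s_eps),
        )
    cohort = np.arange(N)
    sire_usage: set[int] = set()
    prev_test: list[int] = []
    prev_sires: list[int] = []

    for g in range(1, G + 1):
        sexarr = np.array([sex[i] for i in cohort])
        males = cohort[sexarr == MALE]
        females = cohort[sexarr == FEMALE]
        if males.size == 0 or females.size == 0:  # pragma: no cover
            raise RuntimeError("a cohort ran out of one sex")
        # the daughters-per-sire range is the binding constraint: each
        # sire produces about 2 x U(daughters_range) offspring, which
        # fixes how many sires a cohort can support
        d_mean = 0.5 * (cfg.daughters_range[0] + cfg.daughters_range[1])
        n_test = int(min(cfg.n_sires, males.size,
                         max(2, round(0.8 * N / (2.0 * d_mean)))))
        if cfg.selection == "none" or not prev_sires:
            test = rng.choice(males, size=n_test, replace=False)
            proven = np.empty(0, dtype=int)
        elif g == G:
            # final transition: selection candidates are sons of proven
            # bulls — every sire of the candidate cohort is a repeat
            # sire with phenotyped daughters, ranked on their mean
            test = np.empty(0, dtype=int)
            ranked = sorted(
                prev_sires, key=lambda s: _daughter_mean(s, sires, sex, pheno),
                reverse=True,
            )
            proven = np.array(ranked[: max(2, round(N / (2.0 * d_mean)))],
                              dtype=int)
        else:
            # rolling progeny test: young test males sire most of the
            # generation; the best quarter of the previous test cohort,
            # ranked on their daughters' mean phenotype, returns as
            # proven sires
            test = rng.choice(males, size=n_test, replace=False)
            n_proven = max(1, n_test // 4)
            ranked = sorted(
                prev_test, key=lambda s: _daughter_mean(s, sires, sex, pheno),
                reverse=True,
            )
            proven = np.array(ranked[:n_proven], dtype=int)
        slot_sires = np.concatenate([np.asarray(test, dtype=int), proven])
        sire_usage.update(int(s) for s in slot_sires)
        prev_test = [int(s) for s in test]
        prev_sires = [int(s) for s in slot_sires]
        # family sizes ~ 2 x U(daughters_range), rescaled to the cohort
        raw = rng.uniform(*cfg.daughters_range, size=slot_sires.size) * 2.0
        sizes = np.floor(raw * N / raw.sum()).astype(int)
        short = N - sizes.sum()
        if short > 0:
            np.add.at(sizes, rng.choice(sizes.size, size=short, replace=True), 1)
        new_cohort = []
        offsex = cohort_sexes(int(sizes.sum()))
        k = 0
        for s, fam in zip(slot_sires, sizes):
            for _ in range(fam):
                d = int(rng.choice(females))
                al = np.array(
                    [
                        alleles[s][rng.integers(2)],
                        alleles[d][rng.integers(2)],
                    ],
                    dtype=np.int8,
                )
                pg = 0.5 * (poly[s] + poly[d]) + rng.normal(0.0, s_ms)
                new_cohort.append(add_animal(int(s), d, g, offsex[k], al, pg))
                k += 1
        cohort = np.array(new_cohort)

    n = len(sires)
    ids = list(range(1, n + 1))
    ped = Pedigree.from_parents(
        ids,
        [0 if s < 0 else s + 1 for s in sires],
        [0 if d < 0 else d + 1 for d in dams],
        sex=sex,
        generation=gen,
    )
    # Pedigree preserves insertion order here (parents precede offspring)
    order = ped.indices_of(ids)
    inv = np.argsort(order)
    genotyped = np.zeros(n, dtype=bool)
    usage = np.zeros(n, dtype=bool)
    usage[list(sire_usage)] = True
    if cfg.genotype_sires:
        genotyped |= usage
    return SimulatedPopulation(
        cfg,
        ped,
        np.array(alleles, dtype=np.int8)[inv],
        np.array(poly)[inv],
        np.array(pheno)[inv],
        genotyped[inv],
        usage[inv],
    )


def _daughter_mean(s, sires, sex, pheno):
    vals = [
        pheno[i]
        for i, si in enumerate(sires)
        if si == s and sex[i] == FEMALE and not np.isnan(pheno[i])
    ]
    return float(np.mean(vals)) if vals else -np.inf


# -- the printed worked example -------------------------------------------


def table1_fixture():
    """The five-animal worked example: pedigree, records, G0, residuals.

    Two founders and three full sibs; phenotypes (NA, 15, 7, NA, 12),
    gene contents (1, NA, NA, 2, 0); ``G0 = [[0.05, 0.11], [0.11, 0.5]]``
    (heritability 0.05, half genic, p = 0.5) and residual variances
    (0.95, 0.001).
    """
    ped = Pedigree.from_parents([1, 2, 3, 4, 5], [0, 0, 1, 1, 1], [0, 0, 2, 2, 2])
    rec = RecordSet(
        y=np.array([np.nan, 15.0, 7.0, np.nan, 12.0]),
        z=np.array([1.0, np.nan, np.nan, 2.0, 0.0]),
    )
    g0 = GeneTraitCovariance([[0.05, 0.11], [0.11, 0.5]])
    return ped, rec, g0, ResidualSpec(0.95, 0.001)


# -- plain-text writers -----------------------------------------------------


def write_population(pop: SimulatedPopulation, prefix):
    """Write pedigree/phenotype/genotype/truth files for the CLI.

    ``<prefix>.ped``: animal sire dam sex generation;
    ``<prefix>.phe``: animal phenotype; ``<prefix>.gen``: animal
    gene-content for genotyped animals; ``<prefix>.tru``: animal TBV,
    true content, polygenic value.
    """
    ped = pop.pedigree
    ids = np.asarray(ped.ids)
    pd.DataFrame(
        {
            "animal": ids,
            "sire": [0 if s < 0 else ids[s] for s in ped.sire],
            "dam": [0 if d < 0 else ids[d] for d in ped.dam],
            "sex": ped.sex,
            "generation": ped.generation,
        }
    ).to_csv(f"{prefix}.ped", sep=" ", index=False, header=False)
    obs = ~np.isnan(pop.phenotype)
    pd.DataFrame(
        {"animal": ids[obs], "phenotype": pop.phenotype[obs]}
    ).to_csv(f"{prefix}.phe", sep=" ", index=False, header=False)
    rec = pop.records()
    gobs = ~np.isnan(rec.z[:, 0])
    pd.DataFrame(
        {"animal": ids[gobs], "content": rec.z[gobs, 0].astype(int)}
    ).to_csv(f"{prefix}.gen", sep=" ", index=False, header=False)
    pd.DataFrame(
        {
            "animal": ids,
            "tbv": pop.tbv,
            "true_content": pop.z,
            "polygenic": pop.polygenic,
        }
    ).to_csv(f"{prefix}.tru", sep=" ", index=False, header=False)
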