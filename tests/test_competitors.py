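import itertools

import numpy as np
import pytest

from gcmtblup.competitors import (
    CovariateModel,
    GenglerImputation,
    GenotypeProbabilityTable,
    IterativePeeling,
    MendelianInconsistencyError,
    expected_gene_content,
    gengler_impute,
    iterative_peeling,
    write_genotype_probabilities,
)
from gcmtblup.genecov import GeneParams, GeneTraitCovariance
from gcmtblup.gcmt import GeneContentBLUP
from gcmtblup.mme import RecordSet, animal_model_blup
from gcmtblup.pedigree import Pedigree

from conftest import gene_drop, random_pedigree


def exact_genotype_marginals(ped, z, p):
    """Brute-force enumeration of the joint genotype distribution."""
    n = ped.n
    prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])
    gam = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            for a in range(2):
                for b in range(2):
                    T[gs, gd, a + b] += gam[gs, a] * gam[gd, b]
    unknown = [i for i in range(n) if np.isnan(z[i])]
    post = np.zeros((n, 3))
    total = 0.0
    for combo in itertools.product(range(3), repeat=len(unknown)):
        g = np.where(np.isnan(z), 0, z).astype(int)
        for i, gi in zip(unknown, combo):
            g[i] = gi
        lik = 1.0
        for i in range(n):
            s, d = ped.sire[i], ped.dam[i]
            lik *= prior[g[i]] if s < 0 or d < 0 else T[g[s], g[d], g[i]]
            if lik == 0:
                break
        if lik > 0:
            total += lik
            for i in range(n):
                post[i, g[i]] += lik
    return post / total


class TestGenglerImputation:
    def test_genotyped_animal_keeps_its_content(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_generations=2,
                              per_generation=20)
        z = gene_drop(ped, 0.5, rng)
        zobs = np.where(rng.random(ped.n) < 0.6, z, np.nan)
        zhat, bz = gengler_impute(ped, zobs)
        obs = ~np.isnan(zobs)
        assert np.abs(zhat[obs] - z[obs]).max() < 0.01

    def test_offspring_of_aa_by_aa_founders(self):
        ped = Pedigree.from_parents([1, 2, 3], [0, 0, 1], [0, 0, 2])
        zhat, _ = gengler_impute(ped, np.array([0.0, 0.0, np.nan]))
        assert abs(zhat[2]) < 0.05

    def test_equals_decoupled_gcmtblup_content_prediction(self, rng):
        """Gengler BLUP == GCMTBLUP with zero trait-content covariance."""
        ped = random_pedigree(rng, n_founders=12, n_generations=2,
                              per_generation=24)
        z = gene_drop(ped, 0.4, rng)
        zobs = np.where(rng.random(ped.n) < 0.5, z, np.nan)
        imp = GenglerImputation().fit(ped, zobs)
        het = 2 * imp.p_hat_ * (1 - imp.p_hat_)
        g0 = GeneTraitCovariance([[1.0, 0.0], [0.0, het]])
        est = GeneContentBLUP(g0=g0, sigma2_ey=1.0).fit(
            ped, RecordSet(y=np.full(ped.n, np.nan), z=zobs)
        )
        assert np.abs(imp.z_hat_ - est.predict_gene_content()).max() < 1e-6

    def test_constant_genotypes_warn(self):
        ped = Pedigree.from_parents([1, 2], [0, 0], [0, 0])
        with pytest.warns(UserWarning, match="degenerate"):
            GenglerImputation().fit(ped, np.array([1.0, 1.0]))


class TestCovariateModel:
    def test_zero_contents_reduce_to_plain_blup(self, rng):
        ped = random_pedigree(rng, n_founders=8, n_generations=2,
                              per_generation=16)
        y = rng.normal(size=ped.n)
        # constant covariate is inestimable; drop it instead and compare
        with pytest.raises(np.linalg.LinAlgError):
            CovariateModel(0.4, 0.6).fit(ped, y, np.zeros(ped.n))
        b, u, _ = animal_model_blup(ped, y, 0.4, 0.6)
        assert u.shape == (ped.n,)

    def test_recovers_substitution_effect_on_large_unselected_data(self, rng):
        ped = random_pedigree(rng, n_founders=150, n_generations=2,
                              per_generation=350)
        params = GeneParams(alpha=0.5, p=0.5, sigma2_eps=0.2)
        z = gene_drop(ped, params.p, rng)
        y = (z - 1.0) * params.alpha + rng.normal(0, np.sqrt(0.8), ped.n)
        fit = CovariateModel(params.sigma2_eps, 0.8).fit(ped, y, z)
        assert fit.alpha_ == pytest.approx(params.alpha, abs=3 * fit.alpha_se_)
        assert fit.u_y_ == pytest.approx(
            fit.epsilon_ + (z - z.mean()) * fit.alpha_
        )


class TestIterativePeeling:
    def test_genotyped_animals_get_indicator_probabilities(self, rng):
        ped = random_pedigree(rng, n_founders=6, n_generations=2,
                              per_generation=10)
        z = gene_drop(ped, 0.5, rng)
        zobs = np.where(rng.random(ped.n) < 0.5, z, np.nan)
        tab = iterative_peeling(ped, zobs, founder_freq=0.5)
        for i in np.flatnonzero(~np.isnan(zobs)):
            assert tab.probabilities[i, int(zobs[i])] == pytest.approx(1.0)

    def test_aa_by_aa_parents_force_offspring_aa(self):
        ped = Pedigree.from_parents([1, 2, 3], [0, 0, 1], [0, 0, 2])
        tab = iterative_peeling(
            ped, np.array([0.0, 0.0, np.nan]), founder_freq=0.5
        )
        assert tab.probabilities[2] == pytest.approx([1.0, 0.0, 0.0])
        # the linear imputation cannot honor this hard zero in general
        zhat, _ = gengler_impute(
            Pedigree.from_parents([1, 2, 3, 4], [0, 0, 1, 1], [0, 0, 2, 2]),
            np.array([0.0, 0.0, np.nan, 1.0]),
        )
        assert zhat[2] > 1e-3  # pulled up by the AB sib, impossible under peeling

    def test_mendelian_inconsistency_raises(self):
        ped = Pedigree.from_parents([1, 2, 3], [0, 0, 1], [0, 0, 2])
        with pytest.raises(MendelianInconsistencyError):
            iterative_peeling(ped, np.array([0.0, 0.0, 2.0]), founder_freq=0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exact_enumeration_on_loop_free_pedigree(self, seed):
        """Iterative peeling against the brute-force joint distribution."""
        rng = np.random.default_rng(seed)
        # founders 1, 2, 5, 8; sibs 3, 4; grandchildren 6, 7 from an
        # outbred mating: tree-structured (no loops)
        ped = Pedigree.from_parents(
            [1, 2, 3, 4, 5, 6, 7, 8],
            [0, 0, 1, 1, 0, 3, 3, 0],
            [0, 0, 2, 2, 0, 5, 5, 0],
        )
        z = np.full(8, np.nan)
        z[0] = float(rng.integers(0, 3))
        z[6] = float(rng.integers(0, 3))
        p = 0.35
        try:
            tab = iterative_peeling(ped, z, founder_freq=p, tol=1e-12)
        except MendelianInconsistencyError:
            pytest.skip("drawn configuration inconsistent")
        exact = exact_genotype_marginals(ped, z, p)
        assert np.abs(tab.probabilities - exact).max() < 1e-6

    def test_default_founder_freq_comes_from_linear_estimate(self, rng):
        ped = random_pedigree(rng, n_founders=10, n_generations=1,
                              per_generation=10)
        z = gene_drop(ped, 0.3, rng)
        zobs = np.where(rng.random(ped.n) < 0.7, z, np.nan)
        est = IterativePeeling().fit(ped, zobs)
        _, bz = gengler_impute(ped, zobs)
        assert est.founder_freq_ == pytest.approx(np.clip(bz / 2, 0.01, 0.99))


class TestExpectedContent:
    def test_values_and_linearity(self):
        tab = GenotypeProbabilityTable(
            np.array([[0.25, 0.5, 0.25], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        )
        ez = expected_gene_content(tab)
        assert ez == pytest.approx([1.0, 2.0, 0.0])
        assert np.all((ez >= 0) & (ez <= 2))

    def test_probability_validation(self):
        with pytest.raises(ValueError, match="sum"):
            GenotypeProbabilityTable(np.array([[0.5, 0.1, 0.1]]))


def test_probability_writer(tmp_path, rng):
    import pandas as pd

    ped = Pedigree.from_parents([1, 2, 3], [0, 0, 1], [0, 0, 2])
    tab = iterative_peeling(ped, np.array([0.0, 1.0, np.nan]), founder_freq=0.4)
    out = tmp_path / "probs.txt"
    write_genotype_probabilities(out, ped, tab)
    df = pd.read_csv(out, sep=" ")
    assert list(df.columns) == ["animal", "p_aa", "p_ab", "p_bb", "e_content"]
    assert df.shape == (3, 5)
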