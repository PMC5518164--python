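"""Benchmark methods: linear gene-content imputation and iterative peeling.

Both competitors impute gene content for non-genotyped animals first
and then feed the imputed contents, treated as known, to an animal
model with the content as a fixed covariate.  Unlike the joint
multi-trait analysis, neither uses the quantitative-trait phenotypes to
inform the genotype prediction.

* Gengler-style imputation: single-trait pedigree BLUP of gene content
  (heritability ~ 1), which is linear and ignores the discreteness of
  genotypes (an AA x AA mating can get a nonzero imputed B dosage).
* Iterative peeling: propagation of genotype probabilities through the
  pedigree with exact Mendelian transmission rules, iterated to a fixed
  point; exact on loop-free pedigrees, approximate otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .mme import animal_model_blup
from .pedigree import Pedigree, RelationshipMatrix, UNKNOWN

__all__ = [
    "GenotypeProbabilityTable",
    "MendelianInconsistencyError",
    "GenglerImputation",
    "CovariateModel",
    "IterativePeeling",
    "gengler_impute",
    "covariate_model_fit",
    "iterative_peeling",
    "expected_gene_content",
    "write_genotype_probabilities",
]

GENOTYPE_CONTENT = np.array([0.0, 1.0, 2.0])  # AA, AB, BB -> B-allele count


class MendelianInconsistencyError(ValueError):
    """Observed genotypes impossible under Mendelian transmission."""


@dataclass
class GenotypeProbabilityTable:
    """Per-animal posterior probabilities over genotypes (AA, AB, BB)."""

    probabilities: np.ndarray  # (n, 3)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 3:
            raise ValueError("probabilities must be (n, 3)")
        if np.any(p < -1e-9):
            raise ValueError("negative genotype probability")
        s = p.sum(axis=1)
        if np.any(np.abs(s - 1.0) > 1e-6):
            raise ValueError("genotype probabilities must sum to 1 per animal")
        self.probabilities = p / s[:, None]

    @property
    def expected_content(self) -> np.ndarray:
        return self.probabilities @ GENOTYPE_CONTENT


def expected_gene_content(probs: GenotypeProbabilityTable) -> np.ndarray:
    """``E[z] = P(AB) + 2 P(BB)`` per animal."""
    return probs.expected_content


class GenglerImputation(BaseEstimator):
    """Gene content predicted as a quantitative trait by pedigree BLUP.

    Fits ``z = mu + u + e`` with ``Var(u) = A * 2 p q`` and a small
    residual, iterating the base frequency ``p = mu / 2`` to a fixed
    point.  Fitted attributes: ``z_hat_`` (= b + u for every animal),
    ``b_z_``, ``u_z_``, ``p_hat_``.
    """

    def __init__(self, sigma2_ez=0.001, max_iter=10, tol=1e-6):
        self.sigma2_ez = sigma2_ez
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, pedigree: Pedigree, z: np.ndarray,
            ainv: RelationshipMatrix | None = None):
        z = np.asarray(z, dtype=float)
        obs = np.flatnonzero(~np.isnan(z))
        if obs.size == 0:
            raise ValueError("need at least one genotyped animal")
        if np.ptp(z[obs]) == 0:
            warnings.warn(
                "all genotyped animals carry the same content: degenerate "
                "gene-content variance"
            )
        p = float(np.clip(z[obs].mean() / 2.0, 0.02, 0.98))
        for _ in range(self.max_iter):
            het = 2.0 * p * (1.0 - p)
            b, u, _ = animal_model_blup(
                pedigree, z, genetic_variance=het,
                residual_variance=self.sigma2_ez, ainv=ainv,
            )
            p_new = float(np.clip(b[0] / 2.0, 0.02, 0.98))
            done = abs(p_new - p) < self.tol
            p = p_new
            if done:
                break
        self.b_z_ = float(b[0])
        self.u_z_ = u
        self.z_hat_ = b[0] + u
        self.p_hat_ = p
        return self


def gengler_impute(ped: Pedigree, z, sigma2_ez: float = 0.001, ainv=None):
    """Impute gene contents by single-trait BLUP; returns ``(z_hat, b_z)``."""
    est = GenglerImputation(sigma2_ez=sigma2_ez).fit(ped, z, ainv=ainv)
    return est.z_hat_, est.b_z_


class CovariateModel(BaseEstimator):
    """Animal model with gene content as a fixed covariate.

    ``y = mu + z alpha + eps + e`` with polygenic ``Var(eps) = A
    sigma2_eps``; ``z`` must be known (observed or imputed) for every
    phenotyped animal.  Total breeding values are rebuilt as
    ``u_y = eps_hat + (z - mean(z)) alpha_hat``.  Variance components
    are inputs (typically those of the generating process or a prior
    REML run).
    """

    def __init__(self, sigma2_eps=None, sigma2_e=None, alpha=None,
                 z_center=None):
        self.sigma2_eps = sigma2_eps
        self.sigma2_e = sigma2_e
        self.alpha = alpha  # None: estimate; number: known effect (offset)
        # base gene-content mean 2p; default: mean of the supplied z.
        # Breeding values are reported against this base, so two models
        # agree exactly only when they share it.
        self.z_center = z_center

    def fit(self, pedigree: Pedigree, y: np.ndarray, z: np.ndarray,
            ainv: RelationshipMatrix | None = None):
        if self.sigma2_eps is None or self.sigma2_e is None:
            raise ValueError("sigma2_eps and sigma2_e are required")
        y = np.asarray(y, dtype=float)
        z = np.asarray(z, dtype=float)
        center = np.nanmean(z) if self.z_center is None else self.z_center
        zc = z - center
        if self.alpha is None:
            b, eps, cinv = animal_model_blup(
                pedigree, y, genetic_variance=self.sigma2_eps,
                residual_variance=self.sigma2_e, covariates=zc[:, None],
                ainv=ainv,
            )
            self.alpha_ = float(b[1])
            self.alpha_se_ = float(np.sqrt(max(cinv[1, 1], 0.0)))
        else:
            b, eps, _ = animal_model_blup(
                pedigree, y - zc * self.alpha,
                genetic_variance=self.sigma2_eps,
                residual_variance=self.sigma2_e, ainv=ainv,
            )
            self.alpha_ = float(self.alpha)
            self.alpha_se_ = 0.0
        self.b_y_ = float(b[0])
        self.epsilon_ = eps
        self.u_y_ = eps + zc * self.alpha_
        return self


def covariate_model_fit(ped, y, z, sigma2_eps, sigma2_e, ainv=None):
    """Fit the fixed-covariate animal model; returns ``(alpha_hat, u_y)``."""
    est = CovariateModel(sigma2_eps, sigma2_e).fit(ped, y, z, ainv=ainv)
    return est.alpha_, est.u_y_


# -- iterative peeling ------------------------------------------------------


def _transmission() -> np.ndarray:
    """T[gs, gd, go]: P(offspring go | sire gs, dam gd), genotypes AA/AB/BB."""
    gam = np.array([[1.0, 0.0], [0.5, 0.5], [0.0, 1.0]])  # P(transmit B) rows
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            for a in range(2):  # sire gamete (0 = A, 1 = B)
                for b in range(2):
                    T[gs, gd, a + b] += gam[gs, a] * gam[gd, b]
    return T


_T = _transmission()


class IterativePeeling(BaseEstimator):
    """Iterative peeling of genotype probabilities on a pedigree.

    Maintains, per animal, an anterior probability (information from
    ancestors and sibs) and, per mating in which the animal is a
    parent, a posterior probability (information from that family's
    descendants).  One round updates anteriors in topological order and
    posteriors in reverse order; rounds repeat until the maximum change
    in any genotype probability is below ``tol``.  On loop-free
    pedigrees the fixed point equals the exact Bayesian marginals.

    ``founder_freq`` is the base-population frequency of the B allele;
    if omitted it is taken from the linear (Gengler) estimate ``b_z/2``.
    """

    def __init__(self, founder_freq=None, tol=1e-8, max_rounds=100):
        self.founder_freq = founder_freq
        self.tol = tol
        self.max_rounds = max_rounds

    def fit(self, pedigree: Pedigree, z: np.ndarray):
        z = np.asarray(z, dtype=float)
        n = pedigree.n
        p = self.founder_freq
        if p is None:
            obs = ~np.isnan(z)
            if not obs.any():
                raise ValueError("need genotypes or an explicit founder_freq")
            _, bz = gengler_impute(pedigree, z)
            p = float(np.clip(bz / 2.0, 0.01, 0.99))
        prior = np.array([(1 - p) ** 2, 2 * p * (1 - p), p * p])

        pen = np.ones((n, 3))
        for i in np.flatnonzero(~np.isnan(z)):
            pen[i] = 0.0
            pen[i, int(z[i])] = 1.0

        sire, dam = pedigree.sire, pedigree.dam
        fam_of: dict[tuple, list[int]] = {}
        for i in range(n):
            if sire[i] != UNKNOWN and dam[i] != UNKNOWN:
                fam_of.setdefault((int(sire[i]), int(dam[i])), []).append(i)
        families = list(fam_of.items())
        fams_of_parent: dict[int, list[int]] = {}
        child_fam = np.full(n, -1)
        for f, ((s, d), kids) in enumerate(families):
            fams_of_parent.setdefault(s, []).append(f)
            fams_of_parent.setdefault(d, []).append(f)
            for c in kids:
                child_fam[c] = f

        ant = np.tile(prior, (n, 1))
        post = np.ones((len(families), 2, 3))  # per family: to sire, to dam

        def post_all(i):
            out = np.ones(3)
            for f in fams_of_parent.get(i, ()):
                s, d = families[f][0]
                out = out * post[f, 0 if i == s else 1]
            return out

        def u_excl(i, f_excl):
            out = ant[i] * pen[i]
            for f in fams_of_parent.get(i, ()):
                if f == f_excl:
                    continue
                s, d = families[f][0]
                out = out * post[f, 0 if i == s else 1]
            tot = out.sum()
            if tot <= 0.0:
                s, d = (pedigree.ids[x] if x >= 0 else None
                        for x in (sire[i], dam[i]))
                raise MendelianInconsistencyError(
                    f"zero-probability genotype configuration at animal "
                    f"{pedigree.ids[i]!r} (sire {s!r}, dam {d!r})"
                )
            return out / tot

        def child_factor(c):
            # sum over child genotype of penetrance x descendant info,
            # as a function of the parent-pair genotypes: (3, 3)
            w = pen[c] * post_all(c)
            return _T @ w  # (gs, gd)

        marg_prev = np.tile(prior, (n, 1))
        for _round in range(self.max_rounds):
            # anterior sweep (topological order = index order)
            for i in range(n):
                f = child_fam[i]
                if f < 0:
                    continue
                (s, d), kids = families[f]
                us = u_excl(s, f)
                ud = u_excl(d, f)
                sib = np.ones((3, 3))
                for c in kids:
                    if c != i:
                        sib = sib * child_factor(c)
                joint = np.outer(us, ud) * sib  # (gs, gd)
                ant[i] = np.einsum("st,sto->o", joint, _T)
                tot = ant[i].sum()
                if tot <= 0:
                    raise MendelianInconsistencyError(
                        f"zero-probability genotype configuration at animal "
                        f"{pedigree.ids[i]!r}"
                    )
                ant[i] /= tot
            # posterior sweep (reverse order over families)
            for f in range(len(families) - 1, -1, -1):
                (s, d), kids = families[f]
                prod = np.ones((3, 3))
                for c in kids:
                    prod = prod * child_factor(c)
                ud = u_excl(d, f)
                post[f, 0] = np.clip(prod @ ud, 1e-300, None)
                post[f, 0] /= post[f, 0].sum()
                us = u_excl(s, f)
                post[f, 1] = np.clip(prod.T @ us, 1e-300, None)
                post[f, 1] /= post[f, 1].sum()
            marg = np.empty((n, 3))
            for i in range(n):
                m = ant[i] * pen[i] * post_all(i)
                tot = m.sum()
                if tot <= 0:
                    raise MendelianInconsistencyError(
                        f"zero-probability genotype configuration at animal "
                        f"{pedigree.ids[i]!r}"
                    )
                marg[i] = m / tot
            delta = np.abs(marg - marg_prev).max()
            marg_prev = marg
            if delta < self.tol:
                break
        self.n_rounds_ = _round + 1
        self.converged_ = delta < self.tol
        self.founder_freq_ = p
        self.probabilities_ = GenotypeProbabilityTable(marg)
        self.expected_content_ = self.probabilities_.expected_content
        return self


def iterative_peeling(ped: Pedigree, z, founder_freq=None, tol=1e-8,
                      max_rounds=100) -> GenotypeProbabilityTable:
    """Run iterative peeling; returns a :class:`GenotypeProbabilityTable`."""
    est = IterativePeeling(founder_freq=founder_freq, tol=tol,
                           max_rounds=max_rounds).fit(ped, z)
    return est.probabilities_


def write_genotype_probabilities(path, ped: Pedigree,
                                 probs: GenotypeProbabilityTable):
    """Delimited output: animal P(AA) P(AB) P(BB) E[z]."""
    import pandas as pd

    p = probs.probabilities
    pd.DataFrame(
        {
            "animal": ped.ids,
            "p_aa": p[:, 0],
            "p_ab": p[:, 1],
            "p_bb": p[:, 2],
            "e_content": probs.expected_content,
        }
    ).to_csv(path, sep=" ", index=False)
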